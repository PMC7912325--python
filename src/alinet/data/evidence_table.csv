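exposure,exposure_state,outcome,adverse_state,measure,value,cutoff,source
dhea,Q1,metabolic_syndrome,yes,RRQ,1,1.44 umol/L,"Chen et al., 2010"
dhea,Q2,metabolic_syndrome,yes,RRQ,1.66,2.31 umol/L,"Chen et al., 2010"
dhea,Q3,metabolic_syndrome,yes,RRQ,1,3.4 umol/L,"Chen et al., 2010"
dhea,Q4,metabolic_syndrome,yes,RRQ,2.68,13.5 umol/L,"Chen et al., 2010"
crp,elevated,stroke_recovery,adverse,RR,1.36,<=8 mg/L,"Rigaud et al., 2001"
il6,elevated,stroke_recovery,adverse,RR,1.97,,"Rigaud et al., 2001"
systolic_bp,elevated,stroke_recovery,adverse,RR,1.18,,"Rigaud et al., 2001"
il6,elevated,mortality_8yr,yes,RR,1.49,<=1.8 pg/mL,"Li et al., 2017; Lee et al., 2012"
bmi,obese,postoperative_complications,yes,RR,1.6,18.5-24.9 kg/m^2,"Barone et al., 2017; Lee et al., 2012"
crp,elevated,postoperative_complications,yes,RR,1.4,,"Barone et al., 2017; Lee et al., 2012"
hdl_c,low,stroke,yes,RR,1.24,Boolean,"Sacco et al., 2001; Bruckert et al., 2006; Boix et al., 2006"
metabolic_syndrome,yes,type2_diabetes,yes,RR,4.42,Boolean,"Sattar et al., 2008"
bmi,obese,type2_diabetes,yes,RR,6.76,Boolean,"Lee et al., 2012"
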