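variable,state,probability,provenance,source
dhea,Q1,0.25,default-assumption,population quartiles are equiprobable by construction
dhea,Q2,0.25,default-assumption,population quartiles are equiprobable by construction
dhea,Q3,0.25,default-assumption,population quartiles are equiprobable by construction
dhea,Q4,0.25,default-assumption,population quartiles are equiprobable by construction
bmi,obese,0.25,default-assumption,obesity prevalence assumed for a >60y population
crp,elevated,0.25,default-assumption,elevated CRP (>8 mg/L) assumed for a >60y population
il6,elevated,0.40,default-assumption,elevated IL-6 (>1.8 pg/mL) assumed for a >60y population
systolic_bp,elevated,0.50,default-assumption,systolic hypertension assumed for a >60y population
hdl_c,low,0.35,default-assumption,low HDL-C assumed for a >60y population
metabolic_syndrome,yes,0.20,default-assumption,metabolic syndrome marginal risk assumed for a >60y population
type2_diabetes,yes,0.10,default-assumption,type II diabetes marginal risk assumed for a >60y population
stroke,yes,0.05,default-assumption,stroke incidence assumed for a >60y population
stroke_recovery,adverse,0.04,default-assumption,adverse six-week recovery risk conditional on stroke=yes
postoperative_complications,yes,0.10,default-assumption,marginal postoperative-complication risk assumed for a >60y population
mortality_8yr,yes,0.15,default-assumption,8-year all-cause mortality risk assumed for a >60y population
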