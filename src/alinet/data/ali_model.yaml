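# Frozen structure of the elderly allostatic-load network (ALI^E).
# The first listed state of every variable is its reference state.
# Statistical edges (which exposure drives which outcome, and with what
# published ratio) live in evidence_table.csv; marginal prevalences live in
# prevalences.csv.  This file fixes the node list, the context-specific
# determinism (stroke recovery is trivially 'positive' when no stroke
# occurred) and the deterministic aggregation defining the load node.
variables:
  - name: dhea
    states: [Q1, Q2, Q3, Q4]
  - name: bmi
    states: [normal, obese]
  - name: crp
    states: [normal, elevated]
  - name: il6
    states: [normal, elevated]
  - name: systolic_bp
    states: [normal, elevated]
  - name: hdl_c
    states: [normal, low]
  - name: metabolic_syndrome
    states: ["no", "yes"]
  - name: type2_diabetes
    states: ["no", "yes"]
  - name: stroke
    states: ["no", "yes"]
  - name: stroke_recovery
    states: [positive, adverse]
  - name: postoperative_complications
    states: ["no", "yes"]
  - name: mortality_8yr
    states: ["no", "yes"]
  - name: allostatic_load
    states: [stable, disturbed]

gates:
  stroke_recovery:
    variable: stroke
    state: "no"
    forces: positive

aggregation:
  allostatic_load:
    - [mortality_8yr, "yes"]
    - [postoperative_complications, "yes"]
    - [type2_diabetes, "yes"]
    - [stroke_recovery, adverse]
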