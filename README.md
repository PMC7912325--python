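# alinet — a probabilistic allostatic-load model for the elderly

Allostatic load is the cumulative physiological "wear and tear" that
repeated or chronic stress leaves on an organism. In people over 60 it is a
candidate summary of deteriorating health, but most biomarkers used in
allostatic-load indices lose their natural variance with age, and no raw
cohort exists that links the surviving markers to outcomes in one dataset.
What the literature *does* provide are summary statistics: prevalences,
risk ratios (RR), odds ratios (OR) and per-quartile risks, each tying one
biomarker to one medical outcome in an elderly population.

`alinet` turns those published statistics into a working probability model.
It compiles them — "bottom-up", one node at a time — into the conditional
probability tables of a discrete Bayesian belief network, runs exact
inference on it, and returns for any individual's biomarker states a
personalised probability that their allostasis is **disturbed** rather than
**stable**. It is aimed at biostatisticians and modellers who want a
self-contained, inspectable alternative to building such networks in a GUI.

## The model

Thirteen nodes. Six biomarkers enter as root variables: DHEA (population
quartiles Q1–Q4), BMI (normal / obese), C-reactive protein, interleukin-6
and systolic blood pressure (normal / elevated), HDL-cholesterol (normal /
low). Six medical outcomes depend on them through published ratios:

| exposure → outcome | statistic |
|---|---|
| DHEA quartiles → metabolic syndrome | RR 1, 1.66, 1, 2.68 |
| metabolic syndrome → type II diabetes | RR 4.42 |
| BMI → type II diabetes | RR 6.76 |
| BMI → postoperative complications | RR 1.6 |
| CRP → postoperative complications | RR 1.4 |
| IL-6 → 8-year mortality | RR 1.49 |
| HDL-C → stroke | RR 1.24 |
| CRP / IL-6 / systolic BP → adverse stroke recovery | RR 1.36 / 1.97 / 1.18 |

A published (q = exposure prevalence, p = outcome risk, RR = r) triple pins
down the two conditional risks exactly:

    P(outcome | reference) = p / (1 − q + r·q),      P(outcome | exposed) = r · P(outcome | reference)

For an OR the exposed risk is `o·x / (1 + (o−1)·x)` and the marginal
constraint becomes a quadratic in `x` with a single admissible root.
Several RRs acting on one outcome combine multiplicatively on the risk
scale, with the baseline solved from the marginal constraint; quartile
records are the same construction with priors of ¼ each. Stroke recovery is
context-specific: with no stroke, recovery is "positive" with probability 1.
The binary `allostatic_load` node (stable / disturbed) is a deterministic OR
over the adverse terminal outcomes {mortality = yes, postoperative
complications = yes, type II diabetes = yes, stroke recovery = adverse}.

The published sources print the ratios but **not** the marginal
prevalences; the packaged parameter file supplies defaults, each flagged
`default-assumption`. Ratio round-trips and the structural conditional
cells are exact regardless of these defaults; end-to-end marginal
percentages are reproducible only up to them (see `docs/methods.md`).

## Worked example

```python
from alinet import build_ali_network, allostatic_score, eliminate

net, report = build_ali_network()          # packaged statistics + defaults
print(eliminate(net, "allostatic_load", {}).as_dict())
# {'stable': 0.6891, 'disturbed': 0.3109}

lean  = allostatic_score(net, {"bmi": "normal", "metabolic_syndrome": "no"})
obese = allostatic_score(net, {"bmi": "obese",  "metabolic_syndrome": "no"})
print(lean.p_stable, obese.p_stable)
# 0.7557 0.6102
```

With no evidence the model assigns this synthetic reference population a
31% probability of disturbed allostasis. Observing an obese BMI (RR 6.76 on
diabetes, 1.6 on postoperative complications) while metabolic syndrome is
known absent drops the probability of a stable state from 0.756 to 0.610 —
the direction is forced by the printed ratios, the magnitudes depend on the
default prevalences.

The same pipeline from the shell:

```
$ ali tornado
node    state     reversed_state  p_with    p_reversed  span
bmi     obese     normal          0.527970  0.742813    0.214843
il6     elevated  normal          0.658640  0.709410    0.050770
dhea    Q1        Q4              0.700254  0.668228    0.032027
crp     elevated  normal          0.668483  0.695975    0.027493
hdl_c   low       normal          0.688906  0.689208    0.000301
systolic_bp elevated normal       0.688990  0.689214    0.000225
```

Each span is the change in P(load = stable) when the observed state is
reversed; BMI and IL-6 lead the ranking of the measurable biomarkers.
Other subcommands: `ali build` (compilation report, optional `--export-xdsl`
for cross-checking in GeNIe), `ali query`, `ali profile` (conditional
profile given an observed load state), `ali simulate` and `ali recover`
(synthetic-cohort parameter recovery).

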