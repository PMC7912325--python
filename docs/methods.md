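# Methods

## Model

The network is a discrete Bayesian belief network over thirteen variables:
six biomarker roots (DHEA in quartiles; BMI, CRP, IL-6, systolic blood
pressure, HDL-C dichotomised at the cutoffs of the source studies), six
medical outcomes, and a binary allostatic-load node. Each variable's state
list is ordered and the first state is its reference state. All
probabilities are stored linearly; the joint has at most 2^12 · 4
configurations and every factor product involves a handful of terms, so
log-space arithmetic would add complexity without numerical benefit.

### Compiling tables from summary statistics

Published sources report (exposure prevalence q, outcome risk p, ratio)
rather than conditional risks. The compiler inverts these exactly:

* **Risk ratio r.** `risk_ref = p / (1 − q + r·q)`, `risk_exposed = r ·
  risk_ref`. Both the marginal constraint and the ratio are reproduced to
  1e-12; an implied risk above 1 raises an "infeasible statistic" error
  naming the record. Errors, never clipping: silent clipping would destroy
  the round-trip property that re-deriving the ratio from the table returns
  the published value.
* **Odds ratio o.** With x = risk_ref, the exposed risk is
  `o·x / (1 + (o−1)·x)` and the marginal constraint is the quadratic
  `(1−q)(o−1)x² + [qo + (1−q) − p(o−1)]x − p = 0`, solved by the
  numerically stable quadratic formula; exactly one root lies in (0, 1).
  As p → 0 the OR and RR inversions agree (rare-outcome limit), which the
  tests check at p = 1e-6.
* **Several exposures on one outcome.** The sources give three independent
  RRs on adverse stroke recovery and single RRs elsewhere, but no
  combination rule. We combine multiplicatively on the risk scale:
  `P(adverse | config) = b · Π_j r_j(state_j)` with the baseline `b` solved
  from `E_priors[b · Π_j r_j] = p`. This is the natural generalisation of
  the single-RR inversion (the single-parent case reduces to it exactly).
  A noisy-OR combination was rejected because the inputs are published
  relative risks, not causal activation probabilities.
* **Quartile records.** A four-state exposure with per-quartile RRs
  (reference quartile ratio 1, priors ¼ each) is the multiplicative
  builder with one four-state parent; quartile-to-quartile ratios are
  reproduced exactly. The DHEA ratios (1, 1.66, 1, 2.68) are non-monotonic
  and are implemented exactly as published, not smoothed.
* **Context-specific determinism.** Stroke recovery is only defined after a
  stroke; the compiled table is gated: when stroke = no, recovery is
  "positive" with probability 1, and the statistical rows (and the adverse
  prevalence parameter, 0.04 by default) are conditional on stroke = yes.
* **Load aggregation.** `allostatic_load = disturbed` iff any of
  {mortality = yes, postoperative complications = yes, type II diabetes =
  yes, stroke recovery = adverse} holds. This aggregation is a modelling
  choice, not a published formula: a deterministic OR over exactly these
  four states is the reading under which observing a stable load forces 0%
  mortality, 0% diabetes, 0% complications and 100% positive recovery,
  while stroke and metabolic syndrome stay possible under "stable". Those
  cells are
  *structural*: they hold for every strictly positive parameter file, which
  the tests verify over 100 random files.

### Inference

Two exact paths: `posterior` marginalises the enumerated joint (the
reference implementation) and `eliminate` runs variable elimination with a
greedy min-degree ordering. They agree to 1e-9 on every fixture and on
random DAGs (property-tested); the profile and score APIs accept either as
a backend. Zero-probability evidence raises an explicit inconsistent-
evidence error rather than yielding NaNs — in a decision-support setting an
impossible observation is a modelling error the caller must see. Tables
read from files are renormalised when a row sums to within 1e-6 of 1
(published statistics are rounded) and rejected otherwise; validation
checks rows to 1e-9.

## Parameters

The ratio statistics are fixed by the source table. The marginal
prevalences are **not** published; the packaged defaults (all flagged
`default-assumption` in `prevalences.csv`) are: DHEA quartiles 0.25 each
(by construction), BMI obese 0.25, CRP elevated 0.25, IL-6 elevated 0.40,
systolic BP elevated 0.50, HDL-C low 0.35, metabolic syndrome 0.20,
type II diabetes 0.10, stroke 0.05, adverse recovery 0.04 (conditional on
stroke), postoperative complications 0.10, 8-year mortality 0.15 — values
a reader would accept as plausible for a generally healthy over-60
population, chosen once and fixed. Consequences that depend on them (the
unconditional load marginal of ~0.31, the exact tornado spans, the
non-structural profile cells) are calibration-level outputs, not
reproductions of published percentages; consequences that do not (ratio
round-trips, structural cells, orderings forced by all ratios exceeding 1)
are exact.

## Sensitivity analysis

One-way tornado: for each candidate node, observe a state, read
P(target | context + state), reverse the state, read again; the span is the
absolute difference, candidates are ranked by span (ties lexicographic).
This matches the bar semantics of a tornado plot; derivative-based
sensitivity measures used by GUI tools are not replicated. Intermediate
medical outcomes are excluded from the default candidate set because
observing them directly short-circuits the biomarker question. DHEA's four
states have no unique reversal; the documented convention compares Q1
against Q4, and any other multi-state node requires an explicit pair.
Under the packaged defaults the ranking is BMI (span 0.215) before IL-6
(0.051) before DHEA and CRP, with systolic BP and HDL-C negligible — the
ordinal finding the tests assert.

## Synthetic cohorts

No raw cohort underlies the model, so recovery experiments draw one from
the compiled network itself: ancestral sampling in topological order,
vectorised over individuals, with `numpy.random.default_rng` (PCG64) and an
explicit seed. Identical seed and parameters give an identical cohort in
this implementation; bit-identity across other PRNGs is not promised, only
statistical equivalence. The generator emulates exactly the model's
assumptions — independent biomarker roots, outcomes conditionally
independent given their listed parents, a deterministic load — and none of
the features real elderly cohorts would add (correlated biomarkers,
selection into surgery, censoring, measurement error). Passing recovery
tests therefore validates the compiler/sampler round trip, not the model's
fit to any real population.

Estimation is by 2×2 tables: RR = (a/(a+b)) / (c/(c+d)) with
SE(log RR) = √(1/a − 1/(a+b) + 1/c − 1/(c+d)); zero cells yield flagged
degenerate estimates, not exceptions. Stroke-recovery ratios are estimated
on the stroke = yes stratum, the conditional the published ratios describe.
At n = 100,000 every generating ratio is recovered within 3 standard
errors and empirical conditional rows sit within 0.02 of the generating
tables wherever ≥500 observations exist; the 3-SE band keeps the seeded
stochastic tests well under a 1% flake rate at these sizes. Per-individual
scores are computed from root states only (cached per distinct
configuration); their decile-binned calibration against observed outcomes
is tested at n = 20,000.

## Problem sizes and determinism

Property tests run on random DAGs of at most 6 nodes and 4 states;
equivalence and structural checks on the 13-node network enumerate its
16,384-configuration joint directly. Recovery experiments use n = 100,000
individuals (seconds, one core); unit-level sampling checks use
n = 20,000. All stochastic tests fix seeds; the tornado and profile
computations are seedless and deterministic.

## Known limitations

* The model is cross-sectional: it scores instantaneous disturbance
  probability and says nothing about allostatic dynamics over time.
* Single-study statistics per edge; no meta-analytic pooling, no
  uncertainty intervals on the published ratios are propagated.
* The multiplicative multi-parent rule and the deterministic-OR load
  aggregation are reconstructions of under-specified parts of the source
  model; both are isolated behind single builders so alternatives could be
  swapped in.
* Default prevalences are assumptions; any downstream marginal should be
  read as conditional on them. The compilation report and every CLI report
  carry the per-entry provenance flags and parameter-file hash so that
  substituted parameter files are visible in the output.
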