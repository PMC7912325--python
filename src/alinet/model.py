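"""The packaged elderly allostatic-load network (ALI^E) and its reports.

The network has thirteen nodes: six biomarkers observed on an individual
(DHEA in population quartiles; BMI, CRP, IL-6, systolic blood pressure and
HDL-cholesterol each dichotomised at the cutoffs of the source studies),
six medical outcomes driven by those biomarkers through published risk
ratios (metabolic syndrome, type II diabetes, stroke, six-week stroke
recovery, postoperative complications, 8-year mortality), and a binary
``allostatic_load`` node (stable / disturbed) defined as a deterministic OR
over the adverse terminal outcomes {mortality = yes, postoperative
complications = yes, type II diabetes = yes, stroke recovery = adverse}.

The deterministic-OR reading of the load node is a reconstruction: the
source literature reports the conditional profile of the model (with 0%
mortality / 0% diabetes / 0% complications / 100% positive recovery under
an observed "stable" load) but not the aggregation rule itself, and exactly
that pattern of structural zeros is what a deterministic OR over those four
states produces for any strictly positive parameterisation upstream.

Published statistics pin down ratios, not marginals: the biomarker
prevalences and baseline outcome risks are NOT printed in the sources, so
the packaged parameter file carries defaults flagged ``default-assumption``.
Conditional profiles and scores therefore reproduce published end-to-end
percentages only up to those inputs; ratio round-trips and the structural
cells are exact regardless.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import io as alio
from .cpt import CompilationReport, ModelSpec, compile_network
from .network import (
    Distribution,
    Evidence,
    Network,
    NetworkError,
    eliminate,
    validate_network,
)

LOAD = "allostatic_load"
BIOMARKERS = ("dhea", "bmi", "crp", "il6", "systolic_bp", "hdl_c")
INTERMEDIATES = (
    "metabolic_syndrome",
    "type2_diabetes",
    "stroke",
    "stroke_recovery",
    "postoperative_complications",
    "mortality_8yr",
)

#: frozen parent sets of the ALI^E structure
EXPECTED_PARENTS: dict[str, frozenset[str]] = {
    "dhea": frozenset(),
    "bmi": frozenset(),
    "crp": frozenset(),
    "il6": frozenset(),
    "systolic_bp": frozenset(),
    "hdl_c": frozenset(),
    "metabolic_syndrome": frozenset({"dhea"}),
    "type2_diabetes": frozenset({"metabolic_syndrome", "bmi"}),
    "stroke": frozenset({"hdl_c"}),
    "stroke_recovery": frozenset({"stroke", "crp", "il6", "systolic_bp"}),
    "postoperative_complications": frozenset({"bmi", "crp"}),
    "mortality_8yr": frozenset({"il6"}),
    LOAD: frozenset(
        {"mortality_8yr", "postoperative_complications", "type2_diabetes", "stroke_recovery"}
    ),
}


def default_files() -> dict[str, Path]:
    """Paths of the packaged model, statistics and parameter files."""
    data = resources.files("alinet") / "data"
    return {
        "model": Path(str(data / "ali_model.yaml")),
        "evidence": Path(str(data / "evidence_table.csv")),
        "params": Path(str(data / "prevalences.csv")),
    }


def load_ali_spec(
    model_path: str | Path | None = None,
    evidence_path: str | Path | None = None,
    params_path: str | Path | None = None,
) -> ModelSpec:
    files = default_files()
    return alio.load_model_spec(
        model_path or files["model"],
        evidence_path or files["evidence"],
        params_path or files["params"],
    )


def build_ali_network(
    params_path: str | Path | None = None,
    *,
    model_path: str | Path | None = None,
    evidence_path: str | Path | None = None,
) -> tuple[Network, CompilationReport]:
    """Compile the ALI^E network; deterministic given the three files.

    Raises if the compiled network fails validation or if any published
    statistic is infeasible under the supplied prevalences.
    """
    spec = load_ali_spec(model_path, evidence_path, params_path)
    net, report = compile_network(spec)
    diags = validate_network(net)
    if diags:
        raise NetworkError("compiled network failed validation: " + "; ".join(diags))
    return net, report


# -- conditional profile (outcome-observed report) -------------------------


def conditional_profile(
    net: Network,
    method: Callable[..., Distribution] = eliminate,
) -> pd.DataFrame:
    """P(variable = state | load = stable) and | load = disturbed), per state.

    One row per (variable, state) for every non-load variable, in network
    declaration order.  Structural facts hold for any strictly positive
    parameter file: conditioning on a stable load forces every aggregated
    adverse outcome to probability 0 (and its benign state to 1).
    """
    rows = []
    for name, var in net.variables.items():
        if name == LOAD:
            continue
        d_stable = method(net, name, {LOAD: "stable"})
        d_dist = method(net, name, {LOAD: "disturbed"})
        for s in var.states:
            rows.append(
                {
                    "variable": name,
                    "state": s,
                    "P_given_stable": d_stable[s],
                    "P_given_disturbed": d_dist[s],
                }
            )
    return pd.DataFrame(rows)


def percent_half_up(p: float) -> int:
    """Render a probability as a whole percent, rounding half-up."""
    return int(Decimal(repr(p * 100.0)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def render_profile_percent(profile: pd.DataFrame) -> pd.DataFrame:
    """Whole-percent view of a conditional profile (report rendering only)."""
    out = profile.copy()
    for col in ("P_given_stable", "P_given_disturbed"):
        out[col] = out[col].map(lambda p: f"{percent_half_up(p)}%")
    return out


# -- per-individual scoring ------------------------------------------------


@dataclass(frozen=True)
class AllostaticScore:
    """A personalised probability of disturbed allostasis, evidence echoed."""

    evidence: tuple[tuple[str, str], ...]
    p_disturbed: float

    @property
    def p_stable(self) -> float:
        return 1.0 - self.p_disturbed


def allostatic_score(
    net: Network,
    individual: Evidence,
    method: Callable[..., Distribution] = eliminate,
) -> AllostaticScore:
    """P(load = disturbed | the individual's observed states).

    Evidence may cover biomarkers and intermediate outcomes but not the
    load node itself.
    """
    if LOAD in individual:
        raise NetworkError("evidence on the load node itself is not a score query")
    net.check_evidence(individual)
    dist = method(net, LOAD, individual)
    return AllostaticScore(
        evidence=tuple(sorted(individual.items())),
        p_disturbed=dist["disturbed"],
    )


# -- structure check -------------------------------------------------------


def check_structure(net: Network) -> list[str]:
    """Diagnostics for deviations from the frozen ALI^E parent sets."""
    diags = []
    expected_nodes = set(EXPECTED_PARENTS)
    actual_nodes = set(net.variables)
    for extra in sorted(actual_nodes - expected_nodes):
        diags.append(f"unexpected node {extra!r}")
    for missing in sorted(expected_nodes - actual_nodes):
        diags.append(f"missing node {missing!r}")
    for name in sorted(expected_nodes & actual_nodes):
        got = frozenset(net.parents_of(name))
        if got != EXPECTED_PARENTS[name]:
            diags.append(
                f"node {name!r}: parents {sorted(got)} != expected "
                f"{sorted(EXPECTED_PARENTS[name])}"
            )
    return diags


# -- synthetic parameter files (for structural property checks) ------------


def random_prevalence_frame(rng: np.random.Generator) -> pd.DataFrame:
    """A random strictly positive parameter file in the packaged schema.

    Exposure prevalences and outcome risks are drawn in ranges where every
    published ratio stays feasible (no implied risk above 1); used to check
    that structural facts hold independently of the parameterisation.
    """
    q4 = rng.dirichlet(np.full(4, 8.0))
    rows = [("dhea", f"Q{i + 1}", q4[i]) for i in range(4)]
    rows += [
        ("bmi", "obese", rng.uniform(0.1, 0.5)),
        ("crp", "elevated", rng.uniform(0.1, 0.5)),
        ("il6", "elevated", rng.uniform(0.1, 0.6)),
        ("systolic_bp", "elevated", rng.uniform(0.2, 0.7)),
        ("hdl_c", "low", rng.uniform(0.1, 0.6)),
        ("metabolic_syndrome", "yes", rng.uniform(0.05, 0.3)),
        # kept below the tightest feasibility bound: with exposure prevalences
        # at their range minima the joint ratio 4.42 * 6.76 caps the marginal
        # diabetes risk at ~0.062 before the exposed-risk product exceeds 1
        ("type2_diabetes", "yes", rng.uniform(0.02, 0.06)),
        ("stroke", "yes", rng.uniform(0.01, 0.1)),
        ("stroke_recovery", "adverse", rng.uniform(0.01, 0.15)),
        ("postoperative_complications", "yes", rng.uniform(0.02, 0.2)),
        ("mortality_8yr", "yes", rng.uniform(0.05, 0.3)),
    ]
    return pd.DataFrame(
        [
            {
                "variable": v,
                "state": s,
                "probability": repr(float(p)),
                "provenance": "default-assumption",
                "source": "randomly drawn parameterisation",
            }
            for v, s, p in rows
        ]
    )


def build_with_random_params(rng: np.random.Generator, tmpdir: str | Path) -> Network:
    """Compile the ALI^E structure under a random positive parameter file."""
    path = Path(tmpdir) / "params.csv"
    random_prevalence_frame(rng).to_csv(path, index=False)
    net, _ = build_ali_network(params_path=path)
    return net


# -- recovery experiment (generating vs cohort-estimated statistics) -------


def recovery_frame(spec: ModelSpec, cohort_df: pd.DataFrame) -> pd.DataFrame:
    """Estimate every published ratio from a sampled cohort.

    Gated outcomes are estimated on the stratum where the gate does not
    force the child (e.g. stroke-recovery ratios among stroke = yes), since
    that conditional is what the published ratios describe.  Returns one row
    per statistic with the generating value, the cohort estimate, the
    log-scale standard error and the z-score of the log discrepancy.
    """
    from .cohort import estimate_rr  # local import: cohort depends on network only

    rows = []
    items = [(rec, rec.value, rec.exposure_state, None) for rec in spec.evidence_records]
    for qrec in spec.quartile_records:
        ref_idx = qrec.values.index(1.0)
        exposure_var = spec.variable(qrec.exposure)
        ref_state = exposure_var.states[ref_idx]
        for k, v in enumerate(qrec.values):
            state = exposure_var.states[k]
            if state == ref_state:
                continue
            items.append((qrec, v, state, ref_state))
    for rec, value, state, ref_state in items:
        restrict = None
        gate = spec.gates.get(rec.outcome)
        if gate is not None:
            gate_var, gate_state, _ = gate
            other = [
                s for s in spec.variable(gate_var).states if s != gate_state
            ]
            restrict = {gate_var: other[0]}
        est = estimate_rr(
            cohort_df,
            exposure=(rec.exposure, state),
            outcome=(rec.outcome, rec.adverse_state),
            reference_state=ref_state,
            restrict=restrict,
        )
        z = np.nan
        if np.isfinite(est.rr) and est.rr > 0 and est.se_log > 0:
            z = (np.log(est.rr) - np.log(value)) / est.se_log
        rows.append(
            {
                "exposure": rec.exposure,
                "exposure_state": state,
                "outcome": rec.outcome,
                "adverse_state": rec.adverse_state,
                "generating": value,
                "estimate": est.rr,
                "se_log": est.se_log,
                "z": z,
                "flag": est.flag,
            }
        )
    return pd.DataFrame(rows)
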