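"""Compile published summary statistics into conditional probability tables.

Epidemiological sources rarely print the conditional risks a Bayesian
network needs; they print a prevalence of exposure ``q``, a marginal
(population) risk of the outcome ``p``, and a relative measure — a risk
ratio RR or an odds ratio OR — linking the two.  These three numbers pin
down the two conditional risks exactly:

*   With a risk ratio ``r``, writing ``x = P(outcome | reference)``,

        q * r * x  +  (1 - q) * x  =  p     =>     x = p / (1 - q + r q)

    and ``P(outcome | exposed) = r x``.

*   With an odds ratio ``o``, the exposed risk is ``o x / (1 + (o - 1) x)``
    and the marginal constraint becomes a quadratic in ``x`` with exactly
    one admissible root in (0, 1).

*   Several exposures acting on one outcome combine multiplicatively on the
    risk scale: ``P(outcome | config) = b * prod_j r_j(state_j)`` with the
    baseline ``b`` solved from the marginal constraint
    ``E_priors[b * prod_j r_j] = p``.

*   A four-state exposure reported as per-quartile risk ratios (priors 1/4
    each) is the same construction with a single four-state parent.

Every builder preserves the published ratio and the supplied marginal
exactly, so re-deriving the statistic from the compiled table returns the
printed value — the quantitative meaning of building a model "bottom-up"
from literature statistics.  A combination whose implied risk exceeds 1 is
an infeasibility in the published inputs and raises, never clips: clipping
would silently destroy that round-trip.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import ConditionalTable, Network, NetworkError, Variable

__all__ = [
    "EvidenceRecord",
    "PrevalenceRecord",
    "QuartileRiskRecord",
    "ModelSpec",
    "InfeasibleStatisticError",
    "cpt_from_rr",
    "cpt_from_or",
    "multi_parent_cpt",
    "quartile_cpt",
    "deterministic_or_cpt",
    "compile_network",
    "CompilationReport",
]

MARGINAL_TOL = 1e-12


class InfeasibleStatisticError(NetworkError):
    """The published statistic is incompatible with the supplied marginals."""


@dataclass(frozen=True)
class EvidenceRecord:
    """One published statistic tying an exposure state to an outcome state.

    ``measure`` is ``"RR"`` or ``"OR"``; ``value`` is the published ratio of
    the exposure's non-reference state against its reference state.
    """

    exposure: str
    exposure_state: str
    outcome: str
    adverse_state: str
    measure: str
    value: float
    cutoff: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.measure not in ("RR", "OR"):
            raise NetworkError(f"measure must be RR or OR, got {self.measure!r}")
        if not self.value > 0:
            raise NetworkError(f"ratio must be positive, got {self.value}")
        if self.exposure == self.outcome:
            raise NetworkError(f"record relates {self.exposure!r} to itself")


@dataclass(frozen=True)
class PrevalenceRecord:
    """Marginal probability of one state of one variable.

    ``provenance`` is ``"cited-source"`` when the number comes from a
    reference, ``"default-assumption"`` when it is a packaged default the
    source literature does not print.
    """

    variable: str
    state: str
    probability: float
    provenance: str = "default-assumption"
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.probability < 1.0:
            raise NetworkError(
                f"prevalence of {self.variable}={self.state} must lie in (0, 1), "
                f"got {self.probability}"
            )
        if self.provenance not in ("cited-source", "default-assumption"):
            raise NetworkError(f"unknown provenance {self.provenance!r}")


@dataclass(frozen=True)
class QuartileRiskRecord:
    """Per-quartile risk ratios of a four-state exposure on one outcome.

    ``values[k]`` is the risk ratio of quartile ``k + 1`` relative to the
    reference quartile; at least one entry must equal 1 (the reference).
    Quartile priors are 1/4 each by construction.
    """

    exposure: str
    outcome: str
    adverse_state: str
    values: tuple[float, float, float, float]
    cutoffs: tuple[str, str, str, str] = ("", "", "", "")
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) != 4:
            raise NetworkError("quartile record needs exactly 4 risk ratios")
        if not any(v == 1.0 for v in self.values):
            raise NetworkError("one quartile must be the reference (ratio 1)")
        if not all(v > 0 for v in self.values):
            raise NetworkError("quartile risk ratios must be positive")


# -- two-state builders ----------------------------------------------------


def cpt_from_rr(exposure_prev: float, outcome_prev: float, rr: float) -> tuple[float, float]:
    """Invert a risk ratio under the marginal constraint.

    Returns ``(risk_ref, risk_exposed)`` with
    ``risk_exposed / risk_ref == rr`` and
    ``q * risk_exposed + (1 - q) * risk_ref == p``.
    """
    q, p, r = exposure_prev, outcome_prev, rr
    _check_qp(q, p)
    if not r > 0:
        raise InfeasibleStatisticError(f"risk ratio must be positive, got {r}")
    risk_ref = p / (1.0 - q + r * q)
    risk_exposed = r * risk_ref
    if risk_exposed > 1.0:
        raise InfeasibleStatisticError(
            f"infeasible RR given marginals: RR={r} with exposure prevalence "
            f"{q} and outcome prevalence {p} implies exposed risk "
            f"{risk_exposed:.6g} > 1"
        )
    return risk_ref, risk_exposed


def cpt_from_or(exposure_prev: float, outcome_prev: float, odds_ratio: float) -> tuple[float, float]:
    """Invert an odds ratio under the marginal constraint.

    With ``x = risk_ref`` the exposed risk is ``o x / (1 + (o - 1) x)`` and
    the marginal constraint is the quadratic

        (1 - q)(o - 1) x^2 + [q o + (1 - q) - p (o - 1)] x - p = 0,

    which has exactly one root in (0, 1).
    """
    q, p, o = exposure_prev, outcome_prev, odds_ratio
    _check_qp(q, p)
    if not o > 0:
        raise InfeasibleStatisticError(f"odds ratio must be positive, got {o}")
    if o == 1.0:
        return p, p
    a = (1.0 - q) * (o - 1.0)
    b = q * o + (1.0 - q) - p * (o - 1.0)
    c = -p
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise InfeasibleStatisticError(
            f"infeasible OR given marginals: OR={o}, q={q}, p={p}"
        )
    # numerically stable quadratic roots
    sq = math.sqrt(disc)
    qq = -0.5 * (b + math.copysign(sq, b))
    roots = [r for r in (qq / a, c / qq) if 0.0 < r < 1.0]
    if not roots:
        raise InfeasibleStatisticError(
            f"infeasible OR given marginals: OR={o}, q={q}, p={p} "
            "(no admissible root in (0, 1))"
        )
    x = min(roots)  # for o > 1 the admissible root is the smaller positive one
    risk_exposed = o * x / (1.0 + (o - 1.0) * x)
    if not 0.0 < risk_exposed <= 1.0:
        raise InfeasibleStatisticError(
            f"infeasible OR given marginals: OR={o}, q={q}, p={p}"
        )
    return x, risk_exposed


def _check_qp(q: float, p: float) -> None:
    if not 0.0 < q < 1.0:
        raise InfeasibleStatisticError(f"exposure prevalence must lie in (0, 1), got {q}")
    if not 0.0 < p < 1.0:
        raise InfeasibleStatisticError(f"outcome prevalence must lie in (0, 1), got {p}")


# -- multi-parent builders -------------------------------------------------


def multi_parent_cpt(
    child: Variable,
    adverse_state: str,
    parents: Sequence[Variable],
    parent_priors: Mapping[str, Mapping[str, float]],
    parent_rrs: Mapping[str, Mapping[str, float]],
    outcome_prev: float,
) -> ConditionalTable:
    """Combine per-parent risk ratios multiplicatively on the risk scale.

    ``P(child = adverse | config) = b * prod_j r_j(state_j)`` where each
    parent's reference state has ratio 1 and the baseline ``b`` is solved
    from the marginal constraint ``E_priors[b * prod_j r_j] = outcome_prev``.
    With a single parent this reduces exactly to :func:`cpt_from_rr`.

    ``parent_rrs[name]`` maps non-reference states of that parent to their
    risk ratios (reference states default to 1).
    """
    p = outcome_prev
    if not 0.0 < p < 1.0:
        raise InfeasibleStatisticError(f"outcome prevalence must lie in (0, 1), got {p}")
    parents = tuple(parents)
    rr_per_parent: list[np.ndarray] = []
    expectation = 1.0
    for parent in parents:
        rrs = np.array(
            [float(parent_rrs.get(parent.name, {}).get(s, 1.0)) for s in parent.states]
        )
        if np.any(rrs <= 0):
            raise InfeasibleStatisticError(
                f"risk ratios for parent {parent.name!r} must be positive"
            )
        priors = np.array([float(parent_priors[parent.name][s]) for s in parent.states])
        if abs(priors.sum() - 1.0) > 1e-9 or np.any(priors < 0):
            raise NetworkError(f"priors for parent {parent.name!r} are not a distribution")
        rr_per_parent.append(rrs)
        expectation *= float(priors @ rrs)
    baseline = p / expectation

    shape = tuple(pa.card for pa in parents)
    adverse = np.full(shape, baseline)
    for j, rrs in enumerate(rr_per_parent):
        adverse *= rrs.reshape([-1 if k == j else 1 for k in range(len(parents))])
    if np.any(adverse > 1.0):
        idx = np.unravel_index(int(np.argmax(adverse)), shape)
        config = tuple(pa.states[i] for pa, i in zip(parents, idx))
        raise InfeasibleStatisticError(
            f"risk overflow for {child.name!r}: configuration {config} implies "
            f"adverse probability {adverse[idx]:.6g} > 1"
        )
    ai = child.index(adverse_state)
    values = np.zeros(shape + (child.card,))
    values[..., ai] = adverse
    # two-state child: the remaining mass goes to the benign state
    benign = [i for i in range(child.card) if i != ai]
    if len(benign) != 1:
        raise NetworkError(
            f"multiplicative-risk builder needs a two-state child, "
            f"{child.name!r} has {child.card} states"
        )
    values[..., benign[0]] = 1.0 - adverse
    return ConditionalTable(child, parents, values)


def quartile_cpt(
    child: Variable,
    adverse_state: str,
    exposure: Variable,
    record: QuartileRiskRecord,
    outcome_prev: float,
) -> ConditionalTable:
    """Table for an outcome driven by a four-state (quartile) exposure.

    Quartile priors are 1/4 each; ``b = p / (mean of the four ratios)`` and
    ``P(adverse | Q_k) = b * values[k]``, so the ratio between any two
    quartiles reproduces the published per-quartile risk ratios exactly.
    """
    if exposure.card != 4:
        raise NetworkError(f"quartile exposure {exposure.name!r} must have 4 states")
    priors = {exposure.name: {s: 0.25 for s in exposure.states}}
    rrs = {exposure.name: dict(zip(exposure.states, record.values))}
    return multi_parent_cpt(child, adverse_state, [exposure], priors, rrs, outcome_prev)


def deterministic_or_cpt(
    child: Variable,
    parents: Sequence[tuple[Variable, str]],
) -> ConditionalTable:
    """Deterministic aggregation: child is 'disturbed' iff any parent is adverse.

    ``parents`` lists ``(variable, adverse_state)`` pairs.  The child must
    have exactly two states, ordered (benign, adverse) — e.g. (stable,
    disturbed).  Every row is a point mass, which is what makes the
    stable-conditional profile's 0%/100% cells structural: they hold for any
    strictly positive parameterisation upstream.
    """
    if not parents:
        raise NetworkError("deterministic OR needs at least one parent")
    if child.card != 2:
        raise NetworkError(f"deterministic-OR child {child.name!r} must have 2 states")
    pvars = tuple(v for v, _ in parents)
    adverse_idx = [v.index(s) for v, s in parents]
    shape = tuple(v.card for v in pvars)
    values = np.zeros(shape + (2,))
    for idx in itertools.product(*(range(v.card) for v in pvars)):
        hit = any(i == ai for i, ai in zip(idx, adverse_idx))
        values[idx + ((1,) if hit else (0,))] = 1.0
    return ConditionalTable(child, pvars, values)


# -- whole-model compilation ----------------------------------------------


@dataclass
class ModelSpec:
    """Everything needed to compile a network from published statistics.

    Attributes
    ----------
    variables:
        Ordered node list with state spaces (first state = reference).
    evidence_records, quartile_records:
        The published RR/OR statistics, grouped per outcome at compile time.
    prevalences:
        Marginal probabilities: for a root node, its prior; for an outcome
        node, the marginal adverse risk the compiled table must reproduce.
    aggregations:
        ``child -> [(parent, adverse_state), ...]`` deterministic-OR nodes.
    gates:
        ``child -> (gate_variable, gate_state, forced_child_state)``:
        context-specific determinism.  When the gate variable is in the gate
        state the child is forced (e.g. stroke recovery is 'positive' with
        probability 1 when no stroke occurred); in all other gate states the
        statistical table applies.
    """

    variables: list[Variable] = field(default_factory=list)
    evidence_records: list[EvidenceRecord] = field(default_factory=list)
    quartile_records: list[QuartileRiskRecord] = field(default_factory=list)
    prevalences: list[PrevalenceRecord] = field(default_factory=list)
    aggregations: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    gates: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise NetworkError(f"model spec has no variable {name!r}")


@dataclass
class CompilationReport:
    """Per-table provenance: which records and prevalences built each table."""

    entries: list[dict] = field(default_factory=list)

    def add(self, node: str, builder: str, records: list, prevalences: list) -> None:
        self.entries.append(
            {
                "node": node,
                "builder": builder,
                "records": records,
                "prevalences": prevalences,
            }
        )

    def to_rows(self) -> list[dict]:
        rows = []
        for e in self.entries:
            for rec in e["records"] or [None]:
                rows.append(
                    {
                        "node": e["node"],
                        "builder": e["builder"],
                        "record": _describe_record(rec),
                        "prevalences": "; ".join(
                            f"{p.variable}={p.state}:{p.probability:g} [{p.provenance}]"
                            for p in e["prevalences"]
                        ),
                    }
                )
        return rows


def _describe_record(rec) -> str:
    if rec is None:
        return ""
    if isinstance(rec, EvidenceRecord):
        return (
            f"{rec.exposure}={rec.exposure_state} -> {rec.outcome}="
            f"{rec.adverse_state} {rec.measure}={rec.value:g} ({rec.source})"
        )
    if isinstance(rec, QuartileRiskRecord):
        vals = "/".join(f"{v:g}" for v in rec.values)
        return f"{rec.exposure} quartiles -> {rec.outcome}={rec.adverse_state} RR={vals} ({rec.source})"
    return str(rec)


def _prevalence_map(spec: ModelSpec) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for rec in spec.prevalences:
        out.setdefault(rec.variable, {})[rec.state] = rec.probability
    return out


def _root_prior(var: Variable, prevs: Mapping[str, float], node: str) -> np.ndarray:
    probs = np.zeros(var.card)
    given = dict(prevs)
    stated = {s: given.pop(s) for s in list(given) if s in var.states}
    if given:
        raise NetworkError(f"prevalence for {node!r} names unknown state(s) {sorted(given)}")
    missing = [s for s in var.states if s not in stated]
    total = sum(stated.values())
    if len(missing) == 0:
        if abs(total - 1.0) > 1e-6:
            raise NetworkError(f"prevalences for {node!r} sum to {total:g} != 1")
    elif len(missing) == 1:
        if total >= 1.0:
            raise NetworkError(f"prevalences for {node!r} already sum to {total:g}")
        stated[missing[0]] = 1.0 - total
    else:
        raise NetworkError(
            f"prevalence for {node!r} leaves {len(missing)} states unspecified"
        )
    for i, s in enumerate(var.states):
        probs[i] = stated[s]
    return probs


def _marginal_of(spec: ModelSpec, prev_map, name: str) -> Mapping[str, float]:
    """Prior over a parent's states, from the prevalence file.

    For a two-state parent with a single stated prevalence the complement is
    filled in; quartile parents default to 1/4 each when unstated.
    """
    var = spec.variable(name)
    stated = prev_map.get(name, {})
    if not stated:
        if var.card == 4 and set(var.states) == {"Q1", "Q2", "Q3", "Q4"}:
            return {s: 0.25 for s in var.states}
        raise NetworkError(f"missing prevalence for {name!r}")
    probs = _root_prior(var, stated, name)
    return dict(zip(var.states, probs))


def compile_network(spec: ModelSpec) -> tuple[Network, CompilationReport]:
    """Build a validated network, one node at a time, from published statistics.

    Root nodes get priors from the prevalence file; outcome nodes are built
    by the RR/OR/quartile/multiplicative builders from their grouped
    records; aggregation nodes are deterministic OR.  Every missing
    prevalence or infeasible statistic raises with the node (and record)
    named.  Returns the network plus a report listing, per table, the
    records and prevalences used with their provenance flags.
    """
    report = CompilationReport()
    prev_map = _prevalence_map(spec)
    prev_records: dict[str, list[PrevalenceRecord]] = {}
    for rec in spec.prevalences:
        prev_records.setdefault(rec.variable, []).append(rec)

    by_outcome: dict[str, list[EvidenceRecord]] = {}
    for rec in spec.evidence_records:
        by_outcome.setdefault(rec.outcome, []).append(rec)
    quartile_by_outcome: dict[str, list[QuartileRiskRecord]] = {}
    for qrec in spec.quartile_records:
        quartile_by_outcome.setdefault(qrec.outcome, []).append(qrec)

    child_names = set(by_outcome) | set(quartile_by_outcome) | set(spec.aggregations)
    tables: list[ConditionalTable] = []

    for var in spec.variables:
        name = var.name
        if name in spec.aggregations:
            parents = [(spec.variable(pn), st) for pn, st in spec.aggregations[name]]
            tables.append(deterministic_or_cpt(var, parents))
            report.add(name, "deterministic_or", [], [])
            continue
        if name not in child_names:
            if name not in prev_map:
                raise NetworkError(f"missing prevalence for root node {name!r}")
            probs = _root_prior(var, prev_map[name], name)
            tables.append(ConditionalTable(var, [], probs))
            report.add(name, "prior", [], prev_records.get(name, []))
            continue
        # statistical outcome node
        if name not in prev_map:
            raise NetworkError(f"missing outcome prevalence for node {name!r}")
        prev_state, p = _adverse_prevalence(spec, prev_map, name)
        recs = by_outcome.get(name, [])
        qrecs = quartile_by_outcome.get(name, [])
        used_prevs = list(prev_records.get(name, []))
        if qrecs:
            if recs or len(qrecs) > 1:
                raise NetworkError(
                    f"node {name!r}: quartile records cannot be mixed with other records"
                )
            qrec = qrecs[0]
            exposure = spec.variable(qrec.exposure)
            try:
                tables.append(quartile_cpt(var, qrec.adverse_state, exposure, qrec, p))
            except InfeasibleStatisticError as err:
                raise InfeasibleStatisticError(
                    f"{err} [record: {_describe_record(qrec)}]"
                ) from err
            report.add(name, "quartile", [qrec], used_prevs)
            continue
        adverse_states = {r.adverse_state for r in recs}
        if len(adverse_states) != 1:
            raise NetworkError(
                f"node {name!r}: records disagree on the adverse state {adverse_states}"
            )
        adverse_state = adverse_states.pop()
        if len(recs) == 1 and recs[0].measure == "OR" and name not in spec.gates:
            rec = recs[0]
            exposure = spec.variable(rec.exposure)
            q = _marginal_of(spec, prev_map, rec.exposure)[rec.exposure_state]
            try:
                risk_ref, risk_exposed = cpt_from_or(q, p, rec.value)
            except InfeasibleStatisticError as err:
                raise InfeasibleStatisticError(
                    f"{err} [record: {_describe_record(rec)}]"
                ) from err
            tables.append(
                _two_state_table(var, adverse_state, exposure, rec.exposure_state,
                                 risk_ref, risk_exposed)
            )
            report.add(name, "cpt_from_or", recs, used_prevs)
            continue
        if any(r.measure == "OR" for r in recs):
            raise NetworkError(
                f"node {name!r}: odds ratios are only supported for single-parent "
                "tables (no multiplicative combination rule is defined for ORs)"
            )
        # one or more RR records -> multiplicative-risk table
        stat_parents = []
        priors: dict[str, Mapping[str, float]] = {}
        rrs: dict[str, dict[str, float]] = {}
        for rec in sorted(recs, key=lambda r: [v.name for v in spec.variables].index(r.exposure)):
            pv = spec.variable(rec.exposure)
            stat_parents.append(pv)
            priors[pv.name] = _marginal_of(spec, prev_map, pv.name)
            rrs.setdefault(pv.name, {})[rec.exposure_state] = rec.value
        try:
            table = multi_parent_cpt(var, adverse_state, stat_parents, priors, rrs, p)
        except InfeasibleStatisticError as err:
            raise InfeasibleStatisticError(
                f"{err} [records: "
                + "; ".join(_describe_record(r) for r in recs) + "]"
            ) from err
        if name in spec.gates:
            table = _apply_gate(spec, var, table, spec.gates[name])
            report.add(name, "multiplicative_rr+gate", recs, used_prevs)
        else:
            report.add(name, "multiplicative_rr", recs, used_prevs)
        tables.append(table)

    net = Network(spec.variables, tables)
    return net, report


def _adverse_prevalence(spec: ModelSpec, prev_map, name: str) -> tuple[str, float]:
    var = spec.variable(name)
    stated = prev_map[name]
    if len(stated) != 1:
        raise NetworkError(
            f"outcome node {name!r} needs exactly one stated (adverse) prevalence, "
            f"got {sorted(stated)}"
        )
    ((state, p),) = stated.items()
    var.index(state)
    return state, p


def _two_state_table(
    child: Variable,
    adverse_state: str,
    exposure: Variable,
    exposed_state: str,
    risk_ref: float,
    risk_exposed: float,
) -> ConditionalTable:
    ai = child.index(adverse_state)
    values = np.zeros((exposure.card, child.card))
    for i, s in enumerate(exposure.states):
        risk = risk_exposed if s == exposed_state else risk_ref
        values[i, ai] = risk
        values[i, 1 - ai] = 1.0 - risk
    return ConditionalTable(child, [exposure], values)


def _apply_gate(
    spec: ModelSpec,
    child: Variable,
    table: ConditionalTable,
    gate: tuple[str, str, str],
) -> ConditionalTable:
    """Prepend a gate parent enforcing context-specific determinism.

    The returned table has parents ``(gate_variable, *table.parents)``.  In
    the gate state the child is forced to ``forced_state`` with probability
    1; in every other gate state the statistical rows apply unchanged.  The
    statistical rows are interpreted as conditional on the gate NOT being in
    the forcing state (e.g. adverse stroke recovery given that a stroke
    occurred), so the prevalence fed to the builder must be that conditional
    risk.
    """
    gate_name, gate_state, forced_state = gate
    gate_var = spec.variable(gate_name)
    gi = gate_var.index(gate_state)
    fi = child.index(forced_state)
    shape = (gate_var.card,) + table.values.shape
    values = np.empty(shape)
    for g in range(gate_var.card):
        if g == gi:
            values[g] = 0.0
            values[g, ..., fi] = 1.0
        else:
            values[g] = table.values
    return ConditionalTable(child, (gate_var,) + table.parents, values)


def derive_rr(table: ConditionalTable, exposure_state: str, reference_state: str,
              adverse_state: str, parent: str | None = None,
              fixed: Mapping[str, str] | None = None) -> float:
    """Re-derive a risk ratio from a compiled table.

    For a multi-parent table pass ``parent`` to select the exposure; the
    remaining parents are read at their first (reference) state unless
    pinned via ``fixed`` — under the multiplicative model their contribution
    cancels in the ratio, but a gate parent must be pinned to its
    non-forcing state (a forced row has zero adverse risk on both sides).
    """
    names = [p.name for p in table.parents]
    fixed = dict(fixed or {})
    if parent is None:
        if len(names) != 1:
            raise NetworkError("table has several parents; name the exposure")
        parent = names[0]
    pi = names.index(parent)
    ai = table.child.index(adverse_state)

    def risk(state: str) -> float:
        idx = []
        for j, pv in enumerate(table.parents):
            if j == pi:
                idx.append(pv.index(state))
            elif pv.name in fixed:
                idx.append(pv.index(fixed[pv.name]))
            else:
                idx.append(0)
        return float(table.values[tuple(idx)][ai])

    num, den = risk(exposure_state), risk(reference_state)
    if den == 0.0:
        raise NetworkError("reference risk is zero; ratio undefined")
    return num / den


def derive_or(table: ConditionalTable, exposure_state: str, reference_state: str,
              adverse_state: str) -> float:
    """Re-derive an odds ratio from a compiled single-parent table."""
    if len(table.parents) != 1:
        raise NetworkError("odds-ratio derivation needs a single-parent table")
    ai = table.child.index(adverse_state)
    pv = table.parents[0]
    re_ = float(table.values[pv.index(exposure_state), ai])
    rr_ = float(table.values[pv.index(reference_state), ai])
    if not (0 < re_ < 1 and 0 < rr_ < 1):
        raise NetworkError("odds ratio undefined for risks at 0 or 1")
    return (re_ / (1 - re_)) / (rr_ / (1 - rr_))
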