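"""Compiling published statistics into conditional tables.

The closed-form inversions are checked against independent bisection
solvers that know nothing of the closed forms: they only enforce the two
defining constraints (the marginal and the ratio).
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alinet.cpt import (
    EvidenceRecord,
    InfeasibleStatisticError,
    ModelSpec,
    PrevalenceRecord,
    QuartileRiskRecord,
    compile_network,
    cpt_from_or,
    cpt_from_rr,
    derive_or,
    derive_rr,
    deterministic_or_cpt,
    multi_parent_cpt,
    quartile_cpt,
)
from alinet.network import NetworkError, Variable, validate_network

from conftest import brute_posterior

# -- independent oracles ---------------------------------------------------


def bisect_rr(q: float, p: float, r: float, tol: float = 1e-14) -> tuple[float, float]:
    """Solve q*r*x + (1-q)*x = p for x = risk_ref by bisection."""
    lo, hi = 0.0, 1.0

    def f(x):
        return q * r * x + (1 - q) * x - p

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    x = 0.5 * (lo + hi)
    return x, r * x


def bisect_or(q: float, p: float, o: float, tol: float = 1e-14) -> tuple[float, float]:
    """Solve q*o*x/(1+(o-1)x) + (1-q)*x = p for x = risk_ref by bisection."""

    def f(x):
        return q * o * x / (1 + (o - 1) * x) + (1 - q) * x - p

    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    x = 0.5 * (lo + hi)
    return x, o * x / (1 + (o - 1) * x)


def bisect_baseline(priors: list[np.ndarray], rrs: list[np.ndarray], p: float) -> float:
    """Solve E[b * prod_j r_j] = p for b by bisection over explicit enumeration."""

    def marginal(b):
        total = 0.0
        for combo in itertools.product(*(range(len(pr)) for pr in priors)):
            w = 1.0
            risk = b
            for j, i in enumerate(combo):
                w *= priors[j][i]
                risk *= rrs[j][i]
            total += w * risk
        return total

    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if marginal(mid) > p:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# published ratios with the marginals used by the packaged parameter file
TABLE2_RR = [
    ("metabolic_syndrome->type2_diabetes", 0.20, 0.10, 4.42),
    ("bmi->type2_diabetes", 0.25, 0.10, 6.76),
    ("il6->mortality_8yr", 0.40, 0.15, 1.49),
    ("crp->stroke_recovery", 0.25, 0.04, 1.36),
    ("il6->stroke_recovery", 0.40, 0.04, 1.97),
    ("systolic_bp->stroke_recovery", 0.50, 0.04, 1.18),
    ("bmi->postoperative_complications", 0.25, 0.10, 1.6),
    ("crp->postoperative_complications", 0.25, 0.10, 1.4),
    ("hdl_c->stroke", 0.35, 0.05, 1.24),
]


class TestRiskRatioInversion:
    def test_rr_one_collapses_to_marginal(self):
        assert cpt_from_rr(0.2, 0.1, 1.0) == pytest.approx((0.1, 0.1), abs=1e-15)

    def test_matches_bisection_oracle_frozen_case(self):
        # oracle-derived for q=0.2, p=0.1, r=4.42
        risk_ref, risk_exp = cpt_from_rr(0.2, 0.1, 4.42)
        assert risk_ref == pytest.approx(0.0593824228, abs=1e-9)
        assert risk_exp == pytest.approx(0.2624703088, abs=1e-9)
        oref, oexp = bisect_rr(0.2, 0.1, 4.42)
        assert risk_ref == pytest.approx(oref, abs=1e-12)
        assert risk_exp == pytest.approx(oexp, abs=1e-12)

    @pytest.mark.parametrize("label,q,p,r", TABLE2_RR)
    def test_constraints_hold_for_every_published_ratio(self, label, q, p, r):
        risk_ref, risk_exp = cpt_from_rr(q, p, r)
        assert q * risk_exp + (1 - q) * risk_ref == pytest.approx(p, abs=1e-12)
        assert risk_exp / risk_ref == pytest.approx(r, abs=1e-12)
        oref, oexp = bisect_rr(q, p, r)
        assert risk_ref == pytest.approx(oref, abs=1e-10)
        assert risk_exp == pytest.approx(oexp, abs=1e-10)

    def test_infeasible_rr_raises(self):
        with pytest.raises(InfeasibleStatisticError, match="infeasible RR"):
            cpt_from_rr(0.9, 0.95, 10.0)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        q=st.floats(0.01, 0.99),
        p=st.floats(0.01, 0.5),
        r=st.floats(1.0, 5.0),
    )
    def test_monotone_in_rr(self, q, p, r):
        try:
            risk_ref, risk_exp = cpt_from_rr(q, p, r)
        except InfeasibleStatisticError:
            return
        if r > 1:
            assert risk_exp > risk_ref
        else:
            assert risk_exp == pytest.approx(risk_ref, abs=1e-12)


class TestOddsRatioInversion:
    def test_or_one_collapses_to_marginal(self):
        assert cpt_from_or(0.3, 0.2, 1.0) == pytest.approx((0.2, 0.2), abs=1e-15)

    def test_matches_bisection_oracle_frozen_case(self):
        risk_ref, risk_exp = cpt_from_or(0.3, 0.2, 2.0)
        assert risk_ref == pytest.approx(0.1645810, abs=1e-6)
        assert risk_exp == pytest.approx(0.2826443, abs=1e-6)
        oref, oexp = bisect_or(0.3, 0.2, 2.0)
        assert risk_ref == pytest.approx(oref, abs=1e-10)
        assert risk_exp == pytest.approx(oexp, abs=1e-10)

    @pytest.mark.parametrize("q,p,o", [(0.3, 0.2, 2.0), (0.1, 0.05, 3.5), (0.5, 0.3, 0.5)])
    def test_marginal_and_odds_constraints(self, q, p, o):
        risk_ref, risk_exp = cpt_from_or(q, p, o)
        assert q * risk_exp + (1 - q) * risk_ref == pytest.approx(p, abs=1e-10)
        odds = (risk_exp / (1 - risk_exp)) / (risk_ref / (1 - risk_ref))
        assert odds == pytest.approx(o, abs=1e-10)

    def test_rare_outcome_limit_recovers_rr(self):
        # as p -> 0 the OR and RR readings coincide
        for o in (1.5, 2.0, 4.0):
            risk_ref, risk_exp = cpt_from_or(0.3, 1e-6, o)
            assert risk_exp / risk_ref == pytest.approx(o, rel=1e-3)
            rref, rexp = cpt_from_rr(0.3, 1e-6, o)
            assert risk_ref == pytest.approx(rref, rel=1e-3)
            assert risk_exp == pytest.approx(rexp, rel=1e-3)


CHILD = Variable("outcome", ("no", "yes"))
CRP = Variable("crp", ("normal", "elevated"))
IL6 = Variable("il6", ("normal", "elevated"))
SBP = Variable("systolic_bp", ("normal", "elevated"))


class TestMultiParent:
    priors = {
        "crp": {"normal": 0.75, "elevated": 0.25},
        "il6": {"normal": 0.60, "elevated": 0.40},
        "systolic_bp": {"normal": 0.50, "elevated": 0.50},
    }
    rrs = {
        "crp": {"elevated": 1.36},
        "il6": {"elevated": 1.97},
        "systolic_bp": {"elevated": 1.18},
    }

    def test_all_unit_ratios_give_flat_rows(self):
        t = multi_parent_cpt(CHILD, "yes", [CRP, IL6], self.priors, {}, 0.04)
        assert t.values[..., 1] == pytest.approx(np.full((2, 2), 0.04), abs=1e-15)

    def test_stroke_recovery_block_matches_enumeration_oracle(self):
        t = multi_parent_cpt(CHILD, "yes", [CRP, IL6, SBP], self.priors, self.rrs, 0.04)
        pri = [np.array([0.75, 0.25]), np.array([0.6, 0.4]), np.array([0.5, 0.5])]
        rr = [np.array([1.0, 1.36]), np.array([1.0, 1.97]), np.array([1.0, 1.18])]
        b = bisect_baseline(pri, rr, 0.04)
        assert b == pytest.approx(0.0242559, abs=1e-6)
        assert t.values[0, 0, 0, 1] == pytest.approx(b, abs=1e-9)
        assert t.values[1, 1, 1, 1] == pytest.approx(b * 1.36 * 1.97 * 1.18, abs=1e-9)
        # marginal constraint under the priors
        marg = 0.0
        for i, j, k in itertools.product(range(2), repeat=3):
            marg += pri[0][i] * pri[1][j] * pri[2][k] * t.values[i, j, k, 1]
        assert marg == pytest.approx(0.04, abs=1e-12)

    def test_single_parent_reduces_to_rr_inversion(self):
        t = multi_parent_cpt(CHILD, "yes", [CRP], self.priors,
                             {"crp": {"elevated": 1.36}}, 0.1)
        risk_ref, risk_exp = cpt_from_rr(0.25, 0.1, 1.36)
        assert t.values[0, 1] == pytest.approx(risk_ref, abs=1e-15)
        assert t.values[1, 1] == pytest.approx(risk_exp, abs=1e-15)

    def test_risk_overflow_is_an_error_naming_the_configuration(self):
        with pytest.raises(InfeasibleStatisticError, match="risk overflow"):
            multi_parent_cpt(CHILD, "yes", [CRP, IL6], self.priors,
                             {"crp": {"elevated": 20.0}, "il6": {"elevated": 20.0}},
                             0.3)


class TestQuartile:
    DHEA = Variable("dhea", ("Q1", "Q2", "Q3", "Q4"))
    MET = Variable("metabolic_syndrome", ("no", "yes"))

    def test_flat_ratios_give_marginal_everywhere(self):
        rec = QuartileRiskRecord("dhea", "metabolic_syndrome", "yes", (1, 1, 1, 1))
        t = quartile_cpt(self.MET, "yes", self.DHEA, rec, 0.2)
        assert t.values[:, 1] == pytest.approx(np.full(4, 0.2), abs=1e-15)

    def test_published_quartile_block(self):
        rec = QuartileRiskRecord("dhea", "metabolic_syndrome", "yes", (1, 1.66, 1, 2.68))
        t = quartile_cpt(self.MET, "yes", self.DHEA, rec, 0.25)
        # four-term hand enumeration: b = p / ((1+1.66+1+2.68)/4)
        assert t.values[0, 1] == pytest.approx(0.157729, abs=1e-6)
        assert t.values[3, 1] == pytest.approx(0.422713, abs=1e-6)
        assert t.values[3, 1] / t.values[0, 1] == pytest.approx(2.68, abs=1e-12)
        assert t.values[1, 1] / t.values[0, 1] == pytest.approx(1.66, abs=1e-12)
        # quartile priors 1/4 each -> marginal preserved
        assert t.values[:, 1].mean() == pytest.approx(0.25, abs=1e-12)

    def test_ratio_preserved_for_any_feasible_marginal(self):
        rec = QuartileRiskRecord("dhea", "metabolic_syndrome", "yes", (1, 1.66, 1, 2.68))
        for p in (0.05, 0.2, 0.5):
            t = quartile_cpt(self.MET, "yes", self.DHEA, rec, p)
            assert t.values[3, 1] / t.values[0, 1] == pytest.approx(2.68, abs=1e-12)

    def test_reference_quartile_required(self):
        with pytest.raises(NetworkError, match="reference"):
            QuartileRiskRecord("dhea", "metabolic_syndrome", "yes", (1.2, 1.66, 1.3, 2.68))


class TestDeterministicOr:
    M = Variable("m", ("no", "yes"))
    R = Variable("r", ("positive", "adverse"))
    LOAD = Variable("load", ("stable", "disturbed"))

    def table(self):
        return deterministic_or_cpt(self.LOAD, [(self.M, "yes"), (self.R, "adverse")])

    def test_all_benign_parents_give_stable(self):
        assert self.table().row(("no", "positive")) == pytest.approx([1.0, 0.0])

    def test_any_adverse_parent_gives_disturbed(self):
        t = self.table()
        assert t.row(("yes", "positive")) == pytest.approx([0.0, 1.0])
        assert t.row(("no", "adverse")) == pytest.approx([0.0, 1.0])
        assert t.row(("yes", "adverse")) == pytest.approx([0.0, 1.0])

    def test_row_count_is_product_of_parent_cards(self):
        assert self.table().values.shape == (2, 2, 2)


class TestCompile:
    def test_empty_spec_gives_empty_network(self):
        net, report = compile_network(ModelSpec())
        assert len(net.variables) == 0
        assert report.entries == []

    def test_missing_prevalence_names_the_node(self, ali_spec):
        spec = ModelSpec(
            variables=ali_spec.variables,
            evidence_records=ali_spec.evidence_records,
            quartile_records=ali_spec.quartile_records,
            prevalences=[p for p in ali_spec.prevalences if p.variable != "il6"],
            aggregations=ali_spec.aggregations,
            gates=ali_spec.gates,
        )
        with pytest.raises(NetworkError, match="il6"):
            compile_network(spec)

    def test_packaged_spec_compiles_to_valid_13_node_network(self, ali_spec):
        net, report = compile_network(ali_spec)
        assert len(net.variables) == 13
        assert validate_network(net) == []
        assert {e["node"] for e in report.entries} == set(net.variables)

    def test_report_carries_provenance_flags(self, ali_spec):
        _, report = compile_network(ali_spec)
        rows = report.to_rows()
        assert any("default-assumption" in r["prevalences"] for r in rows)

    def test_marginal_preservation_by_enumeration(self, ali_net, ali_spec):
        """Compiled network reproduces every supplied outcome prevalence."""
        stated = {
            (p.variable, p.state): p.probability
            for p in ali_spec.prevalences
            if p.variable not in ("dhea",)
        }
        for (var, state), p in stated.items():
            if var == "stroke_recovery":
                # stated conditionally on a stroke having occurred
                d = brute_posterior(ali_net, var, {"stroke": "yes"})
            else:
                d = brute_posterior(ali_net, var, {})
            assert d[state] == pytest.approx(p, abs=1e-9), (var, state)

    def test_round_trip_of_every_published_ratio(self, ali_net):
        """Re-deriving each published ratio from the compiled tables."""
        t = ali_net.tables
        cases = [
            (t["type2_diabetes"], "yes", "no", "yes", "metabolic_syndrome", None, 4.42),
            (t["type2_diabetes"], "obese", "normal", "yes", "bmi", None, 6.76),
            (t["mortality_8yr"], "elevated", "normal", "yes", "il6", None, 1.49),
            (t["stroke_recovery"], "elevated", "normal", "adverse", "crp",
             {"stroke": "yes"}, 1.36),
            (t["stroke_recovery"], "elevated", "normal", "adverse", "il6",
             {"stroke": "yes"}, 1.97),
            (t["stroke_recovery"], "elevated", "normal", "adverse", "systolic_bp",
             {"stroke": "yes"}, 1.18),
            (t["postoperative_complications"], "obese", "normal", "yes", "bmi", None, 1.6),
            (t["postoperative_complications"], "elevated", "normal", "yes", "crp", None, 1.4),
            (t["stroke"], "low", "normal", "yes", "hdl_c", None, 1.24),
            (t["metabolic_syndrome"], "Q2", "Q1", "yes", "dhea", None, 1.66),
            (t["metabolic_syndrome"], "Q4", "Q1", "yes", "dhea", None, 2.68),
        ]
        for table, exp_state, ref_state, adverse, parent, fixed, value in cases:
            got = derive_rr(table, exp_state, ref_state, adverse, parent, fixed)
            assert got == pytest.approx(value, abs=1e-9)

    def test_single_parent_or_record_uses_or_inversion(self):
        e = Variable("exposure", ("reference", "exposed"))
        d = Variable("disease", ("no", "yes"))
        spec = ModelSpec(
            variables=[e, d],
            evidence_records=[
                EvidenceRecord("exposure", "exposed", "disease", "yes", "OR", 2.0)
            ],
            prevalences=[
                PrevalenceRecord("exposure", "exposed", 0.3),
                PrevalenceRecord("disease", "yes", 0.2),
            ],
        )
        net, _ = compile_network(spec)
        assert derive_or(net.tables["disease"], "exposed", "reference", "yes") == \
            pytest.approx(2.0, abs=1e-9)

    def test_gate_forces_child_when_gate_state_holds(self, ali_net):
        row = ali_net.tables["stroke_recovery"].row(
            {"stroke": "no", "crp": "elevated", "il6": "elevated", "systolic_bp": "elevated"}
        )
        assert row == pytest.approx([1.0, 0.0])
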