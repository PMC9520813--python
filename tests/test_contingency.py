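"""Closed-form table estimators: worked values, identities, properties."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import caseonly as co
from caseonly.contingency import sample_case_control_exact
from caseonly.errors import (
    DegenerateReferenceError,
    InvalidTableError,
    ParameterError,
    ZeroCellError,
)
from conftest import random_tables

APPROX = pytest.approx

cells = st.integers(min_value=1, max_value=1000)
eight_cells = st.tuples(*[cells] * 8)


# ---------------------------------------------------------------------------
# point estimates on worked tables
# ---------------------------------------------------------------------------

class TestEffects:
    def test_uniform_table_is_null_everywhere(self, uniform_table):
        t = uniform_table
        for est in {**co.rr_effects(t), **co.or_effects(t)}.values():
            assert est.point == APPROX(1.0)
        assert co.icr_co(t.cases).point == APPROX(1.0)
        assert co.seor_cnc(t).point == APPROX(1.0)
        assert co.icr_cnc(t).point == APPROX(1.0)
        assert co.icr_cnc(t, scale="additive").point == APPROX(0.0)

    def test_relative_risks(self, table):
        rr = co.rr_effects(table)
        assert rr["RR_s"].point == APPROX(2.0)
        assert rr["RR_e"].point == APPROX(3.0)
        assert rr["RR_se"].point == APPROX(12.0)

    def test_odds_ratios(self, table):
        odds = co.or_effects(table)
        assert odds["OR_s"].point == APPROX(3800 / 1800)
        assert odds["OR_e"].point == APPROX(5700 / 1700)
        assert odds["OR_se"].point == APPROX(28.5)

    def test_rr_zero_numerator_flagged(self):
        t = co.TwoByFourTable(a=10, B=190, c=0, D=200, e=30, F=170, g=120, H=80)
        rr = co.rr_effects(t)
        assert rr["RR_s"].point == 0.0
        assert "zero-numerator" in rr["RR_s"].flags
        assert rr["RR_s"].ci_low is None
        corrected = co.rr_effects(t, continuity=True)["RR_s"]
        assert corrected.point > 0
        assert "continuity-corrected" in corrected.flags

    def test_degenerate_reference_raises(self):
        t = co.TwoByFourTable(a=0, B=200, c=20, D=180, e=30, F=170, g=120, H=80)
        with pytest.raises(DegenerateReferenceError):
            co.rr_effects(t)

    def test_zero_cell_or_raises_without_continuity(self):
        t = co.TwoByFourTable(a=10, B=190, c=0, D=200, e=30, F=170, g=120, H=80)
        with pytest.raises(ZeroCellError):
            co.or_effects(t)
        assert co.or_effects(t, continuity=True)["OR_s"].point > 0

    def test_rr_log_se_formula(self, table):
        est = co.rr_effects(table)["RR_s"]
        var = 1 / 20 - 1 / 200 + 1 / 10 - 1 / 200
        assert est.log_se == APPROX(math.sqrt(var))


class TestCaseOnly:
    def test_worked_value(self):
        assert co.icr_co(co.CaseOnlyCounts(10, 20, 30, 120)).point == APPROX(2.0)

    def test_equal_cells_variance(self):
        est = co.icr_co(co.CaseOnlyCounts(10, 10, 10, 10))
        assert est.point == APPROX(1.0)
        assert est.log_se == APPROX(math.sqrt(0.4))

    def test_zero_denominator_named(self):
        with pytest.raises(ZeroCellError) as err:
            co.icr_co(co.CaseOnlyCounts(10, 0, 30, 120))
        assert err.value.cell == "c"

    def test_implied_from_decomposition(self):
        # printed worked-example identities: full-sample ICR and conventional
        # S-E OR pin down the case-only estimate
        assert co.implied_icr_co(2.5, 1.0) == APPROX(2.5)
        assert co.implied_icr_co(1.0, 2.0) == APPROX(2.0)
        assert co.implied_icr_co(1.0, 2.0, orientation="decomposition") == APPROX(0.5)


class TestSeorAndIcrCnc:
    def test_independent_margins(self, table):
        assert co.seor_cnc(table).point == APPROX(1.0)

    def test_dependent_margins(self, dependent_table):
        assert co.seor_cnc(dependent_table).point == APPROX(100 * 100 / (100 * 150))
        conv = co.seor_cnc(dependent_table, orientation="conventional")
        assert conv.point == APPROX(1.5)

    def test_icr_cnc_values(self, table):
        assert co.icr_cnc(table, basis="RR").point == APPROX(2.0)
        assert co.icr_cnc(table, basis="OR").point == APPROX(4.0263, rel=1e-4)
        reri = co.icr_cnc(table, scale="additive", basis="RR")
        assert reri.point == APPROX(8.0)
        assert reri.ci_low is None

    def test_or_basis_has_saturated_wald_ci(self, table):
        est = co.icr_cnc(table, basis="OR")
        assert est.log_se == APPROX(math.sqrt(sum(1 / v for v in table.to_dict().values())))

    def test_bootstrap_ci_brackets_point(self, table):
        est = co.icr_cnc(table, basis="RR", ci="bootstrap", n_boot=400, seed=1)
        assert est.ci_low < est.point < est.ci_high
        again = co.icr_cnc(table, basis="RR", ci="bootstrap", n_boot=400, seed=1)
        assert (est.ci_low, est.ci_high) == (again.ci_low, again.ci_high)


class TestCaseControl:
    def test_expected_sampling(self, table):
        cc = co.sample_case_control(table, 0.1)
        assert cc.controls == (19.0, 18.0, 17.0, 8.0)
        assert cc.cases.to_dict() == table.cases.to_dict()

    def test_equal_noncases(self):
        t = co.TwoByFourTable(a=5, B=100, c=7, D=100, e=9, F=100, g=11, H=100)
        cc = co.sample_case_control(t, 0.1)
        assert cc.controls == (10.0, 10.0, 10.0, 10.0)

    def test_non_integer_rounds_with_warning(self, table):
        with pytest.warns(UserWarning, match="not an integer"):
            co.sample_case_control(table, 0.13)

    def test_binomial_mode_reproducible(self, table):
        cc1 = co.sample_case_control(table, 0.3, mode="binomial", seed=5)
        cc2 = co.sample_case_control(table, 0.3, mode="binomial", seed=5)
        assert cc1.controls == cc2.controls

    def test_bad_fraction(self, table):
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                co.sample_case_control(table, p)

    def test_icr_cc_worked_value(self, table):
        cc = co.sample_case_control(table, 0.1)
        assert co.icr_cc(cc).point == APPROX(2.0 * (18 * 17) / (19 * 8))
        assert co.seor_control(cc).point == APPROX(306 / 152)
        assert co.seor_control(cc, orientation="conventional").point == APPROX(152 / 306)

    def test_full_control_design_equals_or_basis(self, table):
        cc = co.sample_case_control(table, 1.0)
        assert co.icr_cc(cc).point == APPROX(co.icr_cnc(table, basis="OR").point)

    def test_balanced_controls_reduce_to_case_only(self, table):
        cc = co.CaseControlTable(*table.cases.to_dict().values(),
                                 b=12, d=6, f=8, h=4)  # df = bh = 48
        assert co.icr_cc(cc).point == APPROX(co.icr_co(table.cases).point)


class TestAdjustIcr:
    def test_printed_arithmetic_bound_product(self):
        icr = co.EffectEstimate("ICR_co", 1.14, None, 1.03, 1.37)
        seor = co.EffectEstimate("S-E OR", 1.06, None, 1.03, 1.10)
        adj = co.adjust_icr(icr, seor)
        assert round(adj.point, 2) == 1.21
        assert round(adj.ci_low, 2) == 1.06
        assert round(adj.ci_high, 2) == 1.51

    def test_identity_adjustment(self):
        icr = co.EffectEstimate("ICR_co", 1.7, 0.1, 1.4, 2.1)
        one = co.EffectEstimate("S-E OR", 1.0, 0.0, 1.0, 1.0)
        adj = co.adjust_icr(icr, one, ci_method="lognormal_sum")
        assert adj.point == APPROX(1.7)
        assert adj.log_se == APPROX(0.1)

    def test_reciprocal_cancellation(self):
        a = co.EffectEstimate("x", 2.0, None, 1.5, 2.5)
        b = co.EffectEstimate("y", 0.5, None, 0.4, 0.6)
        assert co.adjust_icr(a, b).point == APPROX(1.0)

    def test_lognormal_sum_adds_variances(self):
        a = co.EffectEstimate("x", 2.0, 0.3, 1.1, 3.6)
        b = co.EffectEstimate("y", 1.5, 0.4, 0.7, 3.3)
        adj = co.adjust_icr(a, b, ci_method="lognormal_sum")
        assert adj.log_se == APPROX(math.hypot(0.3, 0.4))


# ---------------------------------------------------------------------------
# identities and invariances (property-based)
# ---------------------------------------------------------------------------

@settings(max_examples=60, deadline=None, derandomize=True)
@given(eight_cells)
def test_decomposition_identity(cells8):
    """Full-sample ICR (RR basis) factors exactly into case-only ICR times
    the decomposition-oriented S-E OR."""
    t = co.TwoByFourTable(*map(float, cells8))
    lhs = co.icr_cnc(t, basis="RR").point
    rhs = co.icr_co(t.cases).point * co.seor_cnc(t).point
    assert lhs == pytest.approx(rhs, rel=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(eight_cells, st.sampled_from([0.05, 0.1, 0.25, 0.5, 1.0]))
def test_case_control_identities(cells8, p):
    """Sampling a fraction p of controls cancels from the case-control ICR:
    it equals the OR-basis full-sample ICR for every p, and factors through
    the design-relationship identity."""
    t = co.TwoByFourTable(*(float(v * 20) for v in cells8))  # p*count integral
    cc = sample_case_control_exact(t, p)
    icr_cc = co.icr_cc(cc).point
    assert icr_cc == pytest.approx(co.icr_cnc(t, basis="OR").point, rel=1e-12)
    df_bh = (t.D * t.F) / (t.B * t.H)
    m = t.margins
    rhs = co.icr_cnc(t, basis="RR").point * df_bh * (m[0] * m[3]) / (m[1] * m[2])
    assert icr_cc == pytest.approx(rhs, rel=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(eight_cells, st.floats(min_value=1.5, max_value=50))
def test_scale_invariance(cells8, factor):
    """Multiplying all eight counts by a constant leaves every point
    estimate unchanged and shrinks every log-scale standard error."""
    t = co.TwoByFourTable(*map(float, cells8))
    ts = t.scaled(factor)
    pairs = [
        (co.icr_co(t.cases), co.icr_co(ts.cases)),
        (co.seor_cnc(t), co.seor_cnc(ts)),
        (co.icr_cnc(t, basis="OR"), co.icr_cnc(ts, basis="OR")),
        (co.or_effects(t)["OR_se"], co.or_effects(ts)["OR_se"]),
        (co.rr_effects(t)["RR_se"], co.rr_effects(ts)["RR_se"]),
    ]
    for before, after in pairs:
        assert after.point == pytest.approx(before.point, rel=1e-9)
        assert after.log_se < before.log_se


def test_conditional_equalities():
    """When the controls are S-E balanced the case-control ICR collapses to
    the case-only one; when the full-sample margins are balanced the
    full-sample ICR collapses to the case-only one."""
    for t in random_tables(20, seed=3):
        if abs(co.seor_cnc(t).point - 1.0) < 1e-12:
            assert co.icr_cnc(t, basis="RR").point == pytest.approx(
                co.icr_co(t.cases).point, rel=1e-12)
    # constructed balanced-margin table
    t = co.TwoByFourTable(a=10, B=90, c=40, D=60, e=25, F=75, g=70, H=30)
    assert co.seor_cnc(t).point == pytest.approx(1.0)
    assert co.icr_cnc(t, basis="RR").point == pytest.approx(
        co.icr_co(t.cases).point, rel=1e-12)


def test_rare_disease_limit():
    """Scaling non-cases up (cases fixed) drives the RR- and OR-basis
    full-sample ICRs together, and the control-population S-E OR toward
    the full-sample one, monotonically.  Uses a fixed table with modest
    effects (interaction ~1.37), where the absolute RR/OR gap at a
    1000-fold scaling falls below 1e-3."""
    base = co.TwoByFourTable(a=6, B=194, c=8, D=192, e=9, F=191, g=16, H=184)
    gaps, seor_gaps = [], []
    for lam in (1, 10, 100, 1000):
        t = base.scale_noncases(lam)
        gaps.append(abs(co.icr_cnc(t, basis="RR").point
                        - co.icr_cnc(t, basis="OR").point))
        cc = sample_case_control_exact(t, 1.0)
        seor_gaps.append(abs(co.seor_cnc(t).point - co.seor_control(cc).point))
    assert gaps == sorted(gaps, reverse=True)
    assert seor_gaps == sorted(seor_gaps, reverse=True)
    assert gaps[-1] < 1e-3


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def test_invalid_tables_rejected():
    with pytest.raises(InvalidTableError):
        co.TwoByFourTable(-1, 10, 10, 10, 10, 10, 10, 10)
    with pytest.raises(InvalidTableError):
        co.TwoByFourTable(0, 0, 0, 0, 0, 0, 0, 0)
    with pytest.raises(InvalidTableError):
        co.TwoByFourTable.from_dict({"a": 1})
    t = co.TwoByFourTable(a=5, B=0, c=1, D=0, e=1, F=0, g=1, H=0)
    with pytest.raises(InvalidTableError):
        co.seor_cnc(co.TwoByFourTable(a=0, B=0, c=1, D=1, e=1, F=1, g=1, H=1))


def test_estimate_serialization_roundtrip(table):
    est = co.icr_co(table.cases)
    d = est.to_dict()
    assert d["estimand"] == "ICR_co"
    assert d["point"] == est.point
    assert "95% CI" in est.rounded()
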