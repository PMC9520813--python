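"""Regression estimators versus closed-form table oracles and simulation."""

import math

import numpy as np
import pandas as pd
import pytest

import caseonly as co
from caseonly import glm
from caseonly.errors import ContractViolationError, FitError, InputError, ParameterError
from conftest import random_tables

APPROX = pytest.approx


# ---------------------------------------------------------------------------
# saturated-model equivalence with the table estimators
# ---------------------------------------------------------------------------

class TestSaturatedEquivalence:
    def test_uniform_table_null(self, uniform_table):
        sd = glm.table_to_subjects(uniform_table)
        assert glm.fit_interaction(sd).point == APPROX(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_all_estimators_match_closed_form(self, seed):
        """On expanded binary data the MLE is the closed-form estimator."""
        for t in random_tables(8, seed=seed, low=5, high=60):
            sd = glm.table_to_subjects(t)
            assert glm.fit_interaction(sd).point == APPROX(
                co.icr_cnc(t, basis="OR").point, rel=1e-8)
            assert glm.fit_independence(sd).point == APPROX(
                co.seor_cnc(t).point, rel=1e-8)
            assert glm.fit_independence(sd, orientation="conventional").point \
                == APPROX(co.seor_cnc(t, orientation="conventional").point, rel=1e-8)
            cases = sd.restrict_to_cases()
            assert glm.fit_case_only(cases).point == APPROX(
                co.icr_co(t.cases).point, rel=1e-8)
            # single-effect fit equals the crude 2x2 collapse odds ratio
            crude_e = ((t.e + t.g) * (t.B + t.D)) / ((t.a + t.c) * (t.F + t.H))
            assert glm.fit_single_effect(sd, "E").point == APPROX(crude_e, rel=1e-8)

    def test_case_only_counts_expansion(self):
        sd = glm.cases_to_subjects(co.CaseOnlyCounts(10, 20, 30, 120))
        assert glm.fit_case_only(sd).point == APPROX(2.0, rel=1e-8)

    def test_wald_variances_equal_reciprocal_cell_sums(self, table):
        """Asymptotic variances: all eight cells for the full-sample
        interaction, the four case cells for the case-only estimate -- and
        the case-only variance is strictly smaller."""
        sd = glm.table_to_subjects(table)
        _, fit_full = glm.fit_interaction(sd, full_output=True)
        var_full = fit_full.se("S:E") ** 2
        assert var_full == APPROX(sum(1 / v for v in table.to_dict().values()),
                                  abs=1e-6)
        _, fit_co = glm.fit_case_only(sd.restrict_to_cases(), full_output=True)
        var_co = fit_co.se("E") ** 2
        assert var_co == APPROX(sum(1 / v for v in table.cases.to_dict().values()),
                                abs=1e-6)
        assert var_co < var_full

    def test_case_control_same_code_path(self, table):
        """The interaction fit on an expanded case-control sample returns
        the case-control ICR."""
        cc = co.sample_case_control(table, 0.1)
        t_cc = co.TwoByFourTable(a=cc.a, B=cc.b, c=cc.c, D=cc.d,
                                 e=cc.e, F=cc.f, g=cc.g, H=cc.h)
        sd = glm.table_to_subjects(t_cc)
        assert glm.fit_interaction(sd).point == APPROX(co.icr_cc(cc).point, rel=1e-8)

    def test_recoding_flips_to_reciprocal(self, table):
        """Swapping the reference levels of both S and E leaves exp(b3)
        invariant; swapping one flips it to its reciprocal."""
        sd = glm.table_to_subjects(table)
        base = glm.fit_interaction(sd).point
        df = sd.df.copy()
        df["S"] = 1 - df["S"]
        flipped = glm.fit_interaction(glm.SubjectData(df)).point
        assert flipped == APPROX(1.0 / base, rel=1e-8)
        df["E"] = 1 - df["E"]
        both = glm.fit_interaction(glm.SubjectData(df)).point
        assert both == APPROX(base, rel=1e-8)


# ---------------------------------------------------------------------------
# simulation recovery
# ---------------------------------------------------------------------------

class TestRecovery:
    def test_null_predictor_recovers_one(self):
        params = co.SimParams(n=6000, beta1=0.0, beta0=-2.0, seed=42)
        data = co.simulate_population(params)
        est = glm.fit_single_effect(data, "S")
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_single_effect_parameter_recovery(self):
        true_or = 1.5
        params = co.SimParams(n=5000, beta2=math.log(true_or), beta0=-2.5, seed=9)
        data = co.simulate_population(params)
        est = glm.fit_single_effect(data, "E")
        assert abs(math.log(est.point) - math.log(true_or)) < 3 * est.log_se

    def test_independence_recovery_conventional(self):
        params = co.SimParams(n=5000, se_or=2.0, beta0=-2.5, seed=10)
        data = co.simulate_population(params)
        est = glm.fit_independence(data, orientation="conventional")
        assert abs(math.log(est.point) - math.log(2.0)) < 3 * est.log_se
        decomp = glm.fit_independence(data)
        assert decomp.point == APPROX(1.0 / est.point, rel=1e-10)

    def test_null_interaction_coverage(self):
        """95% Wald CI for exp(b3) covers 1 in at least 90% of seeded
        replicates under a null interaction with independent S and E."""
        master = np.random.default_rng(2024)
        hits = 0
        n_reps = 100
        for _ in range(n_reps):
            params = co.SimParams(n=4000, beta0=-3.0, seed=int(master.integers(2**31)))
            t = glm.collapse_to_table(co.simulate_population(params))
            if min(t.to_dict().values()) <= 0:
                n_reps -= 1
                continue
            est = co.icr_cnc(t, basis="OR")
            hits += est.ci_low <= 1.0 <= est.ci_high
        assert hits / n_reps >= 0.90

    def test_confounder_adjustment_restores_independence(self):
        """A shared binary cause of S and E biases the raw case-only
        estimate; conditioning on it recovers the generative exp(b3)."""
        params = co.SimParams(
            n=60000, beta0=-3.0, beta3=0.0, seed=77,
            confounder=co.ConfounderSpec(p_c=0.5, log_or_cs=1.6, log_or_ce=1.6))
        cases = co.simulate_population(params).restrict_to_cases()
        raw = glm.fit_case_only(cases, covariates=())
        adjusted = glm.fit_case_only(cases, covariates=("C",))
        assert raw.point > 1.1  # confounding inflates the raw estimate
        assert abs(math.log(adjusted.point)) < 3 * adjusted.log_se


# ---------------------------------------------------------------------------
# contracts and error handling
# ---------------------------------------------------------------------------

class TestContracts:
    def test_case_only_rejects_noncases(self, table):
        sd = glm.table_to_subjects(table)
        with pytest.raises(ContractViolationError):
            glm.fit_case_only(sd)

    def test_constant_s_among_cases(self):
        df = pd.DataFrame({"D": [1] * 20, "S": [1] * 20,
                           "E": [0, 1] * 10})
        with pytest.raises(InputError):
            glm.SubjectData(df)  # S constant fails construction already

    def test_missing_values_dropped_and_counted(self):
        df = pd.DataFrame({"D": [0, 1] * 5, "S": [0, 1] * 5,
                           "E": [0.2, None, 1.4, 2.0, None, 0.1, 0.9, 1.1, 0.4, 2.2]})
        sd = glm.SubjectData(df)
        assert sd.n == 8
        assert sd.n_dropped == 2

    def test_single_class_outcome_fit_error(self):
        df = pd.DataFrame({"D": [0] * 30, "S": [0, 1] * 15, "E": [0, 0, 1] * 10})
        with pytest.raises(FitError):
            glm.fit_interaction(glm.SubjectData(df))

    def test_continuous_s_requires_explicit_approximation(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"D": rng.integers(0, 2, 200),
                           "S": rng.normal(6.0, 1.0, 200),
                           "E": rng.integers(0, 2, 200)})
        sd = glm.SubjectData(df)
        with pytest.raises(ParameterError, match="continuous"):
            glm.fit_independence(sd)
        est = glm.fit_independence(sd, continuous_s="approx",
                                   orientation="conventional")
        assert "continuous-S approximation" in est.flags

    def test_which_validated(self, table):
        sd = glm.table_to_subjects(table)
        with pytest.raises(ParameterError):
            glm.fit_single_effect(sd, "X")
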