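"""Assumption diagnostics for the case-only design.

Three families:

* **Rare-disease sensitivity** -- how far the control-population S-E odds
  ratio can drift from the full-sample one as the baseline disease risk
  grows, at given single-factor and joint relative risks.
* **Stratification bias** -- the confounding interaction ratio (CIR),
  the ratio of the crude to the stratification-adjusted interaction
  estimate, with its closed-form prediction from stratum-level prevalence
  odds and its analytic bounds.
* **Design efficiency** -- the asymptotic variances of the interaction
  log-estimate under the full-sample, case-control and case-only designs
  (sums of reciprocal cells); the case-only variance omits every non-case
  term and is strictly smallest.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contingency import TwoByFourTable, sample_case_control_exact
from .errors import DomainError, FitError, ParameterError
from .glm import SubjectData, fit_case_only, fit_interaction

__all__ = [
    "SensitivityInputs",
    "seor_control_sensitivity",
    "sensitivity_grid",
    "cir",
    "cir_bounds",
    "cir_empirical",
    "variance_comparison",
    "DEFAULT_P0_GRID",
    "DEFAULT_RRS_GRID",
]

# Grid defaults span baseline risks of 0.1%..6% and modest-to-strong
# susceptibility effects, the region where the control-vs-full-sample
# discrepancy turns from negligible to material.
DEFAULT_P0_GRID = (0.001, 0.005, 0.01, 0.03, 0.06)
DEFAULT_RRS_GRID = (1.0, 1.5, 2.5, 4.0)


@dataclass(frozen=True)
class SensitivityInputs:
    """Inputs of the control-population sensitivity formula.

    ``p0`` is the baseline risk P(D | S- E-); the three relative risks are
    taken versus the S-E- reference.  The formula requires ``1/p0`` to
    exceed every relative risk (each stratum risk below 1), else the
    factor is undefined.
    """

    p0: float
    rr_s: float = 1.0
    rr_e: float = 1.0
    rr_se: float = 1.0
    seor_cnc: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.p0 < 1.0):
            raise ParameterError(f"baseline risk p0 must be in (0,1), got {self.p0}")
        for name in ("rr_s", "rr_e", "rr_se", "seor_cnc"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        inv = 1.0 / self.p0
        for name in ("rr_s", "rr_e", "rr_se"):
            if inv <= getattr(self, name):
                raise DomainError(
                    f"1/p0 = {inv:g} must strictly exceed {name} = "
                    f"{getattr(self, name):g}: some stratum risk reaches 1")


def seor_control_sensitivity(s: SensitivityInputs) -> float:
    """Implied control-population S-E odds ratio.

    ``seor_control = seor_cnc x ((1/p0 - 1)(1/p0 - RR_se)) /
    ((1/p0 - RR_s)(1/p0 - RR_e))``.  As ``p0 -> 0`` the factor tends to 1,
    so the control OR converges to the full-sample OR -- the rare-disease
    guarantee.  The formula applies identically in either orientation of
    the S-E odds ratio (the distortion factor is orientation-free).
    """
    inv = 1.0 / s.p0
    factor = ((inv - 1.0) * (inv - s.rr_se)) / ((inv - s.rr_s) * (inv - s.rr_e))
    return s.seor_cnc * factor


def sensitivity_grid(p0_values=DEFAULT_P0_GRID, rr_s_values=DEFAULT_RRS_GRID,
                     rr_e: float = 1.0, rr_se: float = 1.0,
                     seor_cnc: float = 1.0) -> pd.DataFrame:
    """Sensitivity surface over (baseline risk, RR_s) combinations.

    Returns a tidy frame with columns ``p0``, ``rr_s``, ``seor_control``.
    """
    rows = []
    for p0, rr_s in itertools.product(p0_values, rr_s_values):
        val = seor_control_sensitivity(
            SensitivityInputs(p0=p0, rr_s=rr_s, rr_e=rr_e, rr_se=rr_se,
                              seor_cnc=seor_cnc))
        rows.append({"p0": p0, "rr_s": rr_s, "seor_control": val})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratification bias (confounding interaction ratio)
# ---------------------------------------------------------------------------

def cir(r_se: float, cv_s: float, cv_e: float) -> float:
    """Confounding interaction ratio ``CIR = r_SE x CV_S x CV_E + 1``.

    ``r_se`` is the across-strata correlation between susceptibility
    prevalence odds and exposure prevalence odds; the CVs are their
    coefficients of variation.  CIR = 1 (no stratification bias) whenever
    the odds are uncorrelated or either set of odds shows no variation.
    """
    if not (-1.0 <= r_se <= 1.0):
        raise ParameterError(f"correlation r_se must be in [-1,1], got {r_se}")
    if cv_s < 0 or cv_e < 0:
        raise ParameterError("coefficients of variation must be non-negative")
    return r_se * cv_s * cv_e + 1.0


def cir_bounds(upsilon_s: float, upsilon_e: float) -> tuple[float, float]:
    """Analytic (lower, upper) bounds of the CIR from odds extremes.

    ``upsilon_s`` and ``upsilon_e`` are the largest-over-smallest
    susceptibility and exposure prevalence odds across strata (both >= 1).

    ``U = sqrt(vS vE) (sqrt(vS vE)+1)^2 / ((sqrt(vS vE)+vS)(sqrt(vS vE)+vE))``
    and ``L = 1/U``; ``U >= 1`` always, with equality iff either ratio is 1.
    """
    if upsilon_s < 1.0 or upsilon_e < 1.0:
        raise ParameterError("upsilon ratios are max/min odds and must be >= 1")
    s = math.sqrt(upsilon_s * upsilon_e)
    upper = s * (s + 1.0) ** 2 / ((s + upsilon_s) * (s + upsilon_e))
    return 1.0 / upper, upper


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx, vy = np.sum(w * (x - mx) ** 2), np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return 0.0
    # guard against |r| creeping past 1 by floating-point rounding
    return float(np.clip(cov / math.sqrt(vx * vy), -1.0, 1.0))


def _weighted_cv(x: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    m = np.sum(w * x)
    if m <= 0:
        raise ParameterError("prevalence odds must have positive mean")
    sd = math.sqrt(float(np.sum(w * (x - m) ** 2)))
    return sd / m


def cir_empirical(data: SubjectData, weighted: bool = True,
                  level: float = 0.95) -> dict:
    """Empirical CIR from stratified subject-level data.

    Mixing strata whose susceptibility and exposure prevalences co-vary
    induces a marginal S-E association even when S and E are independent
    within every stratum.  That association inflates the *case-only*
    interaction estimate multiplicatively; the reported CIR is therefore
    the ratio of the crude case-only estimate (strata ignored) to the
    stratification-adjusted one (stratum indicator terms in the model).
    The full-sample interaction fit, by contrast, is algebraically immune
    to pure margin mixing when the within-stratum disease model is shared
    -- the mixture weights cancel between the case and non-case factors --
    and both its crude and stratified versions are returned for reference.

    Also computed: the closed-form ingredients of the CIR prediction --
    stratum-size weighted correlation ``r_SE`` of susceptibility and
    exposure prevalence odds, their weighted CVs -- and the odds extremes
    ``upsilon_s``/``upsilon_e`` with the implied analytic bounds.
    ``weighted=False`` switches to unweighted moments across strata.
    """
    if data.stratum_col is None:
        raise ParameterError("data has no stratum column")
    df = data.df
    strata = df[data.stratum_col].unique()
    if len(strata) < 2:
        raise ParameterError("at least 2 strata are required")
    s_odds, e_odds, sizes = [], [], []
    for label in strata:
        sub = df[df[data.stratum_col] == label]
        n_s1 = float((sub[data.s_col] == 1).sum())
        n_e1 = float((sub[data.e_col] == 1).sum())
        n = float(len(sub))
        if n_s1 in (0.0, n) or n_e1 in (0.0, n):
            raise FitError(f"stratum {label!r}: S or E is constant; "
                           "prevalence odds undefined")
        s_odds.append(n_s1 / (n - n_s1))
        e_odds.append(n_e1 / (n - n_e1))
        sizes.append(n)
    s_odds, e_odds = np.asarray(s_odds), np.asarray(e_odds)
    w = np.asarray(sizes) if weighted else np.ones(len(sizes))

    dummies = pd.get_dummies(df[data.stratum_col].astype("category"),
                             prefix="stratum", drop_first=True, dtype=float)
    pooled_df = pd.concat([df, dummies], axis=1)
    pooled_data = SubjectData(pooled_df, d_col=data.d_col, s_col=data.s_col,
                              e_col=data.e_col,
                              covariates=tuple(dummies.columns),
                              stratum_col=data.stratum_col)
    try:
        crude_cnc = fit_interaction(data, covariates=(), level=level)
        strat_cnc = fit_interaction(pooled_data, level=level)
        cases = pooled_data.restrict_to_cases()
        crude_co = fit_case_only(cases, covariates=(), level=level)
        strat_co = fit_case_only(cases, level=level)  # stratum dummies adjust
    except FitError as exc:
        raise FitError(f"stratified interaction model failed: {exc}") from exc

    r_se = _weighted_corr(s_odds, e_odds, w)
    cv_s = _weighted_cv(s_odds, w)
    cv_e = _weighted_cv(e_odds, w)
    ups_s = float(s_odds.max() / s_odds.min())
    ups_e = float(e_odds.max() / e_odds.min())
    lower, upper = cir_bounds(ups_s, ups_e)
    return {
        "crude_icr_co": crude_co,
        "stratified_icr_co": strat_co,
        "crude_icr_cnc": crude_cnc,
        "stratified_icr_cnc": strat_cnc,
        "cir_empirical": crude_co.point / strat_co.point,
        "cir_predicted": cir(r_se, cv_s, cv_e),
        "r_se": r_se,
        "cv_s": cv_s,
        "cv_e": cv_e,
        "upsilon_s": ups_s,
        "upsilon_e": ups_e,
        "cir_lower": lower,
        "cir_upper": upper,
        "n_strata": int(len(strata)),
    }


# ---------------------------------------------------------------------------
# design efficiency
# ---------------------------------------------------------------------------

def variance_comparison(t: TwoByFourTable, p: float = 1.0) -> dict:
    """Asymptotic variances of the log interaction estimate by design.

    * full sample: sum of reciprocals of all eight cells;
    * case-control at control fraction ``p``: cases plus ``p x`` non-cases;
    * case-only: the four case cells only.

    Returns the three variances plus the efficiency ratios
    ``var_co/var_full`` and ``var_co/var_cc`` (both < 1 whenever every
    non-case cell is positive).
    """
    cells = t.to_dict()
    for name, v in cells.items():
        if v <= 0:
            raise ParameterError(f"cell {name} must be positive for variance formulas")
    cc = sample_case_control_exact(t, p)
    var_full = sum(1.0 / v for v in cells.values())
    var_co = 1.0 / t.a + 1.0 / t.c + 1.0 / t.e + 1.0 / t.g
    var_cc = var_co + sum(1.0 / v for v in cc.controls)
    return {
        "var_full": var_full,
        "var_cc": var_cc,
        "var_co": var_co,
        "ratio_co_full": var_co / var_full,
        "ratio_co_cc": var_co / var_cc,
    }
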