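"""Regression-based estimation of interaction and independence quantities.

Every closed-form table estimator has a logistic-regression twin that
also accommodates continuous variables and covariate adjustment:

* single effects:      logit P(D=1) = b0 + b.X          -> exp(b)
* interaction:         logit P(D=1) = b0 + b1 S + b2 E + b3 SE -> exp(b3)
  (the identical model serves cohort-type and case-control samples)
* independence check:  logit P(S=1) = n0 + n1 E   on the FULL sample
* case-only estimate:  logit P(S=1) = g0 + g1 E   among cases only,
  optionally with covariates C (the covariate-adjusted case-only model).

On data expanded from a count table with binary S and E these fits are
saturated, so the maximum-likelihood estimates equal the closed-form
table estimators exactly and the Wald variances equal the sums of
reciprocal cells.

The independence and case-only fits regress S on E; the coefficient's
exponential is the *conventional* S-E odds ratio.  ``fit_independence``
therefore supports the same ``orientation`` switch as the table
functions; the decomposition orientation (default) is the factor that the
workflow multiplies onto the case-only ICR to undo dependence bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .contingency import (
    CaseOnlyCounts,
    EffectEstimate,
    TwoByFourTable,
    _check_orientation,
    _log_wald,
)
from .errors import ContractViolationError, FitError, InputError, ParameterError

__all__ = [
    "SubjectData",
    "FitResult",
    "fit_single_effect",
    "fit_interaction",
    "fit_independence",
    "fit_case_only",
    "table_to_subjects",
    "cases_to_subjects",
    "collapse_to_table",
    "collapse_cases",
]

SEPARATION_THRESHOLD = 15.0  # |log-odds| beyond this flags quasi-separation


# ---------------------------------------------------------------------------
# subject-level container
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Subject-level records with declared column roles.

    ``df`` holds one row per subject.  The disease column must be 0/1;
    susceptibility and exposure may each be binary 0/1 or continuous.
    Rows with missing values in any used column are dropped at
    construction (listwise deletion) and counted in ``n_dropped``.
    """

    df: pd.DataFrame
    d_col: str = "D"
    s_col: str = "S"
    e_col: str = "E"
    covariates: tuple[str, ...] = ()
    stratum_col: str | None = None
    n_dropped: int = field(default=0, init=False)

    def __post_init__(self):
        self.covariates = tuple(self.covariates)
        used = [self.d_col, self.s_col, self.e_col, *self.covariates]
        if self.stratum_col is not None:
            used.append(self.stratum_col)
        missing = [c for c in used if c not in self.df.columns]
        if missing:
            raise InputError(f"columns not found in data: {missing}")
        n0 = len(self.df)
        self.df = self.df.dropna(subset=used).reset_index(drop=True)
        self.n_dropped = n0 - len(self.df)
        if len(self.df) == 0:
            raise InputError("no usable rows after dropping missing values")
        d = self.df[self.d_col]
        if not set(pd.unique(d)) <= {0, 1}:
            raise InputError(f"disease column {self.d_col!r} must be coded 0/1")
        for col in (self.s_col, self.e_col):
            if self.df[col].nunique() < 2:
                raise InputError(f"column {col!r} has fewer than 2 distinct values")

    # -- views ----------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    def is_binary(self, col: str) -> bool:
        return set(pd.unique(self.df[col])) <= {0, 1}

    @property
    def s_binary(self) -> bool:
        return self.is_binary(self.s_col)

    @property
    def e_binary(self) -> bool:
        return self.is_binary(self.e_col)

    def cases(self) -> pd.DataFrame:
        return self.df[self.df[self.d_col] == 1]

    def restrict_to_cases(self) -> "SubjectData":
        sub = self.cases().reset_index(drop=True)
        if len(sub) == 0:
            raise InputError("no cases in the data")
        out = object.__new__(SubjectData)
        out.df = sub
        out.d_col, out.s_col, out.e_col = self.d_col, self.s_col, self.e_col
        out.covariates, out.stratum_col = self.covariates, self.stratum_col
        out.n_dropped = 0
        return out


@dataclass(frozen=True)
class FitResult:
    """Raw output of one regression: named coefficients, their covariance,
    convergence flag and the number of rows used."""

    params: dict[str, float]
    cov: pd.DataFrame
    converged: bool
    n_used: int
    flags: tuple[str, ...] = ()

    def se(self, name: str) -> float:
        return math.sqrt(float(self.cov.loc[name, name]))


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> FitResult:
    ybar = float(np.mean(y))
    if ybar in (0.0, 1.0):
        raise FitError("outcome has a single class; logistic fit impossible")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(np.asarray(y, dtype=float), Xc.astype(float)).fit(
            method="newton", maxiter=200, tol=1e-12, disp=0)
    except Exception as exc:  # statsmodels raises several flavours (singular, separation)
        raise FitError(f"logistic fit failed: {exc}") from exc
    params = {k: float(v) for k, v in res.params.items()}
    if not np.all(np.isfinite(list(params.values()))):
        raise FitError("logistic fit produced non-finite coefficients")
    flags = []
    if any(abs(v) > SEPARATION_THRESHOLD for v in params.values()):
        flags.append("possible-separation")
    cov = pd.DataFrame(np.asarray(res.cov_params(), dtype=float),
                       index=Xc.columns, columns=Xc.columns)
    if not res.mle_retvals.get("converged", True):
        raise FitError("logistic fit did not converge")
    return FitResult(params=params, cov=cov, converged=True,
                     n_used=len(y), flags=tuple(flags))


def _fit_ols(y: np.ndarray, X: pd.DataFrame) -> FitResult:
    Xc = sm.add_constant(X, has_constant="add")
    res = sm.OLS(np.asarray(y, dtype=float), Xc.astype(float)).fit()
    cov = pd.DataFrame(np.asarray(res.cov_params(), dtype=float),
                       index=Xc.columns, columns=Xc.columns)
    return FitResult(params={k: float(v) for k, v in res.params.items()},
                     cov=cov, converged=True, n_used=len(y),
                     flags=("continuous-S approximation",))


def _estimate_from_fit(fit: FitResult, coef: str, estimand: str, level: float,
                       invert: bool = False) -> EffectEstimate:
    beta = fit.params[coef]
    if invert:
        beta = -beta
    est = _log_wald(estimand, math.exp(beta), fit.se(coef) ** 2, level,
                    flags=fit.flags, n=fit.n_used)
    return est


def _require_both_classes(data: SubjectData) -> None:
    d = data.df[data.d_col]
    if d.nunique() < 2:
        raise FitError("disease indicator has a single class; cannot fit")


# ---------------------------------------------------------------------------
# public fits
# ---------------------------------------------------------------------------

def fit_single_effect(data: SubjectData, which: str = "E",
                      level: float = 0.95,
                      full_output: bool = False):
    """Crude disease odds ratio per one-unit difference of S or of E.

    Maximum-likelihood logistic fit of D on the single predictor; returns
    exp(coefficient) with a Wald CI.
    """
    if which not in ("S", "E"):
        raise ParameterError(f"which must be 'S' or 'E', got {which!r}")
    _require_both_classes(data)
    col = data.s_col if which == "S" else data.e_col
    fit = _fit_logit(data.df[data.d_col].to_numpy(), data.df[[col]])
    est = _estimate_from_fit(fit, col, f"OR_{which.lower()}", level)
    return (est, fit) if full_output else est


def fit_interaction(data: SubjectData, covariates: tuple[str, ...] | None = None,
                    level: float = 0.95, full_output: bool = False):
    """Multiplicative interaction contrast exp(b3) from
    ``logit P(D=1) = b0 + b1 S + b2 E + b3 SE (+ covariates)``.

    The same model serves full cohort-type samples (ICR_c/nc) and
    case-control samples (ICR_cc); only the sampling design differs.
    """
    _require_both_classes(data)
    covs = list(data.covariates if covariates is None else covariates)
    df = data.df
    X = df[[data.s_col, data.e_col]].copy()
    inter = f"{data.s_col}:{data.e_col}"
    X[inter] = df[data.s_col] * df[data.e_col]
    if X[inter].nunique() < 2:
        raise FitError("the S*E product term has no variation")
    for c in covs:
        X[c] = df[c]
    fit = _fit_logit(df[data.d_col].to_numpy(), X)
    est = _estimate_from_fit(fit, inter, "ICR_c/nc", level)
    return (est, fit) if full_output else est


def _s_on_e_fit(df: pd.DataFrame, s_col: str, e_col: str, covs: list[str],
                s_is_binary: bool, continuous_s: str) -> tuple[FitResult, tuple[str, ...]]:
    X = df[[e_col]].copy()
    for c in covs:
        X[c] = df[c]
    if s_is_binary:
        return _fit_logit(df[s_col].to_numpy(), X), ()
    if continuous_s != "approx":
        raise ParameterError(
            f"susceptibility column {s_col!r} is continuous: the logistic model "
            "logit P(S=1) is undefined. Pass continuous_s='approx' to use the "
            "least-squares approximation (exp(slope) of S on E), documented as "
            "an approximation only.")
    return _fit_ols(df[s_col].to_numpy(), X), ("continuous-S approximation",)


def fit_independence(data: SubjectData, covariates: tuple[str, ...] | None = None,
                     level: float = 0.95, orientation: str = "decomposition",
                     continuous_s: str = "error", full_output: bool = False):
    """S-E association in the FULL sample (cases and non-cases):
    ``logit P(S=1) = n0 + n1 E``.

    ``orientation="conventional"`` returns exp(n1); the default
    decomposition orientation returns exp(-n1), the factor that multiplies
    the case-only ICR in the full-sample decomposition.  With a continuous
    S the logistic model is undefined; ``continuous_s="approx"`` fits S on
    E by least squares and reports exp(slope) under an explicit flag.
    """
    _check_orientation(orientation)
    covs = list(data.covariates if covariates is None else covariates)
    fit, extra = _s_on_e_fit(data.df, data.s_col, data.e_col, covs,
                             data.s_binary, continuous_s)
    est = _estimate_from_fit(fit, data.e_col,
                             f"S-E OR_c/nc ({orientation})", level,
                             invert=(orientation == "decomposition"))
    if extra:
        est = dc_replace(est, flags=tuple(sorted(set(est.flags) | set(extra))))
    return (est, fit) if full_output else est


def fit_case_only(data: SubjectData, covariates: tuple[str, ...] | None = None,
                  level: float = 0.95, continuous_s: str = "error",
                  full_output: bool = False):
    """Case-only interaction estimate exp(g1) from
    ``logit P(S=1) = g0 + g1 E`` among cases, optionally covariate-adjusted.

    The input must contain cases only (every D = 1); presence of any
    non-case is a contract violation, not a silent subset.  Supplying
    covariates C gives the adjusted case-only estimate exp(g1') that
    restores independence when C induces the S-E association.
    """
    if (data.df[data.d_col] != 1).any():
        raise ContractViolationError(
            "fit_case_only requires data restricted to cases (all D == 1); "
            "use SubjectData.restrict_to_cases() first")
    covs = list(data.covariates if covariates is None else covariates)
    df = data.df
    if df[data.s_col].nunique() < 2:
        raise FitError("susceptibility is constant among cases; case-only fit impossible")
    fit, extra = _s_on_e_fit(df, data.s_col, data.e_col, covs,
                             data.s_binary, continuous_s)
    est = _estimate_from_fit(fit, data.e_col, "ICR_co", level)
    if extra:
        est = dc_replace(est, flags=tuple(sorted(set(est.flags) | set(extra))))
    return (est, fit) if full_output else est


# ---------------------------------------------------------------------------
# table <-> subject-level conversions
# ---------------------------------------------------------------------------

def _expand(counts: dict[tuple[int, int, int], float]) -> pd.DataFrame:
    rows = []
    for (d, s, e), k in counts.items():
        ki = round(k)
        if abs(k - ki) > 1e-9:
            raise ParameterError("table expansion requires integer counts")
        rows.append(pd.DataFrame({"D": d, "S": s, "E": e}, index=range(int(ki))))
    return pd.concat(rows, ignore_index=True)


def table_to_subjects(t: TwoByFourTable) -> SubjectData:
    """Expand a 2x4 count table into one row per subject (binary S, E)."""
    df = _expand({
        (1, 0, 0): t.a, (0, 0, 0): t.B,
        (1, 1, 0): t.c, (0, 1, 0): t.D,
        (1, 0, 1): t.e, (0, 0, 1): t.F,
        (1, 1, 1): t.g, (0, 1, 1): t.H,
    })
    return SubjectData(df)


def cases_to_subjects(k: CaseOnlyCounts) -> SubjectData:
    """Expand case-only counts into subject rows (all D = 1)."""
    df = _expand({(1, 0, 0): k.a, (1, 1, 0): k.c, (1, 0, 1): k.e, (1, 1, 1): k.g})
    return SubjectData(df)


def collapse_to_table(data: SubjectData) -> TwoByFourTable:
    """Cross-tabulate binary subject-level data back into the 2x4 layout."""
    if not (data.s_binary and data.e_binary):
        raise ParameterError("collapse requires binary S and E")
    df = data.df

    def count(d: int, s: int, e: int) -> float:
        return float(((df[data.d_col] == d) & (df[data.s_col] == s)
                      & (df[data.e_col] == e)).sum())

    return TwoByFourTable(
        a=count(1, 0, 0), B=count(0, 0, 0),
        c=count(1, 1, 0), D=count(0, 1, 0),
        e=count(1, 0, 1), F=count(0, 0, 1),
        g=count(1, 1, 1), H=count(0, 1, 1),
    )


def collapse_cases(data: SubjectData) -> CaseOnlyCounts:
    return collapse_to_table(data).cases
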