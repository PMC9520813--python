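"""Closed-form interaction estimators on aggregated count tables.

The central object is the 2x4 layout of a study with cases and non-cases:
four strata defined by a binary susceptibility factor S and a binary
environmental exposure E, each split into cases and non-cases::

    E  S   cases  non-cases
    -  -     a        B
    -  +     c        D
    +  -     e        F
    +  +     g        H

From these eight counts every design-specific multiplicative interaction
contrast ratio (ICR) has a closed form:

* ``ICR_co = ag/ce`` -- the S-E odds ratio among cases only;
* ``ICR_c/nc = RR_se/(RR_s RR_e) = ICR_co x (c+D)(e+F)/((a+B)(g+H))`` --
  the full-sample (cases + non-cases) ratio of the joint relative risk to
  the product of the single-factor relative risks;
* ``ICR_cc = OR_se/(OR_s OR_e) = ICR_co x df/bh`` -- the case-control
  analogue, where b,d,f,h are sampled control counts.

A note on orientation.  The factor ``(c+D)(e+F)/((a+B)(g+H))`` that links
the case-only and full-sample ICRs is the S-E association odds ratio
written in the orientation that makes the decomposition an identity; it is
the *reciprocal* of the conventional odds ratio
``odds(S+|E+)/odds(S+|E-)``.  Functions returning S-E association
estimates therefore take an ``orientation`` argument:
``"decomposition"`` (default; multiply it onto ICR_co to recover the
full-sample ICR) or ``"conventional"`` (the textbook odds ratio, what a
logistic regression of S on E estimates).  The two are reciprocal and both
equal 1 exactly when S and E are independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import (
    DegenerateReferenceError,
    InvalidTableError,
    ParameterError,
    ZeroCellError,
)

__all__ = [
    "TwoByFourTable",
    "CaseOnlyCounts",
    "CaseControlTable",
    "EffectEstimate",
    "rr_effects",
    "or_effects",
    "icr_co",
    "seor_cnc",
    "icr_cnc",
    "sample_case_control",
    "icr_cc",
    "seor_control",
    "adjust_icr",
    "implied_icr_co",
]

_ORIENTATIONS = ("decomposition", "conventional")


def _check_orientation(orientation: str) -> None:
    if orientation not in _ORIENTATIONS:
        raise ParameterError(
            f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectEstimate:
    """A ratio (or, for RERI, difference) estimate with its uncertainty.

    ``point`` is on the ratio scale; ``log_se`` is the standard error of
    ``ln(point)`` when a log-Wald construction applies, else ``None``.
    ``flags`` records qualitative events (continuity correction applied,
    zero numerator, ...) that a presentation layer should surface.
    """

    estimand: str
    point: float
    log_se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    level: float = 0.95
    method: str = "log-wald"
    flags: tuple[str, ...] = ()
    n: float | None = None

    def __post_init__(self):
        if not (0.0 < self.level < 1.0):
            raise ParameterError(f"confidence level must be in (0,1), got {self.level}")

    def to_dict(self) -> dict:
        return {
            "estimand": self.estimand,
            "point": self.point,
            "log_se": self.log_se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "method": self.method,
            "flags": list(self.flags),
        }

    def rounded(self, digits: int = 2) -> str:
        """Presentation form, 2 decimals by default (internal values stay full precision)."""
        if self.ci_low is None or self.ci_high is None:
            return f"{self.point:.{digits}f}"
        pct = f"{self.level * 100:g}"
        return (f"{self.point:.{digits}f} ({pct}% CI "
                f"{self.ci_low:.{digits}f}–{self.ci_high:.{digits}f})")

    def reciprocal(self) -> "EffectEstimate":
        """Flip the orientation of a ratio estimate (CI bounds swap)."""
        if self.point <= 0:
            raise ParameterError("cannot invert a non-positive ratio estimate")
        lo = None if self.ci_high is None else 1.0 / self.ci_high
        hi = None if self.ci_low is None else 1.0 / self.ci_low
        return replace(self, point=1.0 / self.point, ci_low=lo, ci_high=hi)


def _validate_counts(items: dict[str, float], cls: str) -> None:
    total = 0.0
    for name, v in items.items():
        if not math.isfinite(v) or v < 0:
            raise InvalidTableError(f"{cls}: count {name}={v!r} must be a finite non-negative number")
        total += v
    if total <= 0:
        raise InvalidTableError(f"{cls}: total count must be positive")


@dataclass(frozen=True)
class TwoByFourTable:
    """Cases and non-cases cross-classified by S and E (the 2x4 layout).

    Counts may be non-integral: expected-value tables produced by the
    simulator are real-valued and every closed-form estimator is defined
    on them unchanged.
    """

    a: float  # cases,     S- E-
    B: float  # non-cases, S- E-
    c: float  # cases,     S+ E-
    D: float  # non-cases, S+ E-
    e: float  # cases,     S- E+
    F: float  # non-cases, S- E+
    g: float  # cases,     S+ E+
    H: float  # non-cases, S+ E+

    _FIELDS = ("a", "B", "c", "D", "e", "F", "g", "H")

    def __post_init__(self):
        _validate_counts(self.to_dict(), "TwoByFourTable")

    # -- convenience views ---------------------------------------------------
    @property
    def cases(self) -> "CaseOnlyCounts":
        return CaseOnlyCounts(self.a, self.c, self.e, self.g)

    @property
    def noncases(self) -> tuple[float, float, float, float]:
        return (self.B, self.D, self.F, self.H)

    @property
    def margins(self) -> tuple[float, float, float, float]:
        """Stratum totals (a+B, c+D, e+F, g+H)."""
        return (self.a + self.B, self.c + self.D, self.e + self.F, self.g + self.H)

    @property
    def total(self) -> float:
        return sum(self.to_dict().values())

    def scaled(self, factor: float) -> "TwoByFourTable":
        if factor <= 0:
            raise ParameterError("scale factor must be positive")
        return TwoByFourTable(**{k: v * factor for k, v in self.to_dict().items()})

    def scale_noncases(self, factor: float) -> "TwoByFourTable":
        """Multiply only B, D, F, H -- used to approach the rare-disease limit."""
        if factor <= 0:
            raise ParameterError("scale factor must be positive")
        return TwoByFourTable(self.a, self.B * factor, self.c, self.D * factor,
                              self.e, self.F * factor, self.g, self.H * factor)

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "TwoByFourTable":
        missing = [k for k in cls._FIELDS if k not in d]
        if missing:
            raise InvalidTableError(f"table is missing keys {missing}")
        return cls(**{k: float(d[k]) for k in cls._FIELDS})


@dataclass(frozen=True)
class CaseOnlyCounts:
    """The four case counts of a case-only study (S x E among cases)."""

    a: float  # S- E-
    c: float  # S+ E-
    e: float  # S- E+
    g: float  # S+ E+

    def __post_init__(self):
        _validate_counts(self.to_dict(), "CaseOnlyCounts")

    @property
    def total(self) -> float:
        return self.a + self.c + self.e + self.g

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("a", "c", "e", "g")}


@dataclass(frozen=True)
class CaseControlTable:
    """Case counts plus control counts sampled at fraction ``p`` of non-cases."""

    a: float
    c: float
    e: float
    g: float
    b: float  # controls, S- E-
    d: float  # controls, S+ E-
    f: float  # controls, S- E+
    h: float  # controls, S+ E+
    p: float | None = None

    def __post_init__(self):
        _validate_counts({k: getattr(self, k) for k in "acegbdfh"}, "CaseControlTable")
        if self.p is not None and not (0.0 < self.p <= 1.0):
            raise ParameterError(f"sampling fraction p must be in (0,1], got {self.p}")

    @property
    def cases(self) -> CaseOnlyCounts:
        return CaseOnlyCounts(self.a, self.c, self.e, self.g)

    @property
    def controls(self) -> tuple[float, float, float, float]:
        return (self.b, self.d, self.f, self.h)

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in "acegbdfh"}
        out["p"] = self.p
        return out


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _z(level: float) -> float:
    if not (0.0 < level < 1.0):
        raise ParameterError(f"confidence level must be in (0,1), got {level}")
    return float(stats.norm.ppf(0.5 + level / 2.0))


def _log_wald(estimand: str, point: float, var_log: float, level: float,
              flags: tuple[str, ...] = (), method: str = "log-wald",
              n: float | None = None) -> EffectEstimate:
    z = _z(level)
    se = math.sqrt(var_log)
    return EffectEstimate(
        estimand=estimand, point=point, log_se=se,
        ci_low=point * math.exp(-z * se), ci_high=point * math.exp(z * se),
        level=level, method=method, flags=flags, n=n,
    )


def _continuity(cells: dict[str, float]) -> dict[str, float]:
    """Haldane-Anscombe +0.5 added to every involved cell."""
    return {k: v + 0.5 for k, v in cells.items()}


def _ratio_2x2(estimand: str, num1: float, num2: float, den1: float, den2: float,
               names: tuple[str, str, str, str], continuity: bool,
               level: float, n: float | None = None) -> EffectEstimate:
    """Odds-ratio style estimate num1*num2/(den1*den2) with Var(log) = sum 1/cell."""
    cells = dict(zip(names, (num1, num2, den1, den2)))
    flags: tuple[str, ...] = ()
    if any(v <= 0 for v in cells.values()):
        if not continuity:
            zero = next(k for k, v in cells.items() if v <= 0)
            raise ZeroCellError(zero)
        cells = _continuity(cells)
        flags = ("continuity-corrected",)
    v1, v2, v3, v4 = (cells[k] for k in names)
    point = (v1 * v2) / (v3 * v4)
    var = sum(1.0 / v for v in cells.values())
    return _log_wald(estimand, point, var, level, flags=flags, n=n)


# ---------------------------------------------------------------------------
# estimators on the 2x4 table
# ---------------------------------------------------------------------------

def rr_effects(t: TwoByFourTable, level: float = 0.95,
               continuity: bool = False) -> dict[str, EffectEstimate]:
    """Relative risks of the S+, E+ and joint strata versus the S-E- reference.

    ``RR_s = c(a+B)/(a(c+D))``, ``RR_e = e(a+B)/(a(e+F))``,
    ``RR_se = g(a+B)/(a(g+H))``.  Log-Wald CIs use the standard
    log-relative-risk variance ``1/c - 1/(c+D) + 1/a - 1/(a+B)`` (and
    analogues).  A zero numerator cell yields a point estimate of 0 with a
    ``zero-numerator`` flag (CI only via the continuity option); zero
    reference cases raise :class:`DegenerateReferenceError`.
    """
    m00, m10, m01, m11 = t.margins
    if min(t.margins) <= 0:
        raise InvalidTableError("every S x E stratum total must be positive for relative risks")
    if t.a <= 0:
        raise DegenerateReferenceError(
            "no cases in the S-E- reference stratum: relative risks are undefined")

    def one(name: str, x: float, mx: float) -> EffectEstimate:
        a, m0 = t.a, m00
        flags: tuple[str, ...] = ()
        if x <= 0:
            if not continuity:
                return EffectEstimate(estimand=name, point=0.0, log_se=None,
                                      ci_low=None, ci_high=None, level=level,
                                      method="point-only", flags=("zero-numerator",),
                                      n=t.total)
            x, mx, a, m0 = x + 0.5, mx + 1.0, a + 0.5, m0 + 1.0
            flags = ("continuity-corrected",)
        point = (x * m0) / (a * mx)
        var = 1.0 / x - 1.0 / mx + 1.0 / a - 1.0 / m0
        return _log_wald(name, point, max(var, 0.0), level, flags=flags, n=t.total)

    return {
        "RR_s": one("RR_s", t.c, m10),
        "RR_e": one("RR_e", t.e, m01),
        "RR_se": one("RR_se", t.g, m11),
    }


def or_effects(t: TwoByFourTable, level: float = 0.95,
               continuity: bool = False) -> dict[str, EffectEstimate]:
    """Odds ratios versus the S-E- reference: ``OR_s = cB/(aD)`` etc.

    Var(log OR) is the sum of reciprocal cells of the 2x2 involved.  Any
    zero cell raises :class:`ZeroCellError` unless ``continuity`` enables
    the +0.5 correction (flagged in the output).
    """
    return {
        "OR_s": _ratio_2x2("OR_s", t.c, t.B, t.a, t.D, ("c", "B", "a", "D"),
                           continuity, level, n=t.total),
        "OR_e": _ratio_2x2("OR_e", t.e, t.B, t.a, t.F, ("e", "B", "a", "F"),
                           continuity, level, n=t.total),
        "OR_se": _ratio_2x2("OR_se", t.g, t.B, t.a, t.H, ("g", "B", "a", "H"),
                            continuity, level, n=t.total),
    }


def icr_co(k: CaseOnlyCounts | TwoByFourTable, level: float = 0.95,
           continuity: bool = False) -> EffectEstimate:
    """Case-only interaction contrast ratio ``ICR_co = ag/ce``.

    Equal to the S-E odds ratio among cases (conventional orientation).
    ``Var(log) = 1/a + 1/c + 1/e + 1/g`` -- the case-only asymptotic
    variance, strictly smaller than the full-sample one because the
    non-case reciprocals are absent.
    """
    if isinstance(k, TwoByFourTable):
        k = k.cases
    cells = {"a": k.a, "g": k.g, "c": k.c, "e": k.e}
    flags: tuple[str, ...] = ()
    if k.c <= 0 or k.e <= 0:
        if not continuity:
            raise ZeroCellError("c" if k.c <= 0 else "e")
        cells = _continuity(cells)
        flags = ("continuity-corrected",)
    elif k.a <= 0 or k.g <= 0:
        if not continuity:
            return EffectEstimate(estimand="ICR_co", point=0.0, log_se=None,
                                  ci_low=None, ci_high=None, level=level,
                                  method="point-only", flags=("zero-numerator",),
                                  n=k.total)
        cells = _continuity(cells)
        flags = ("continuity-corrected",)
    point = cells["a"] * cells["g"] / (cells["c"] * cells["e"])
    var = sum(1.0 / v for v in cells.values())
    return _log_wald("ICR_co", point, var, level, flags=flags, n=k.total)


def seor_cnc(t: TwoByFourTable, level: float = 0.95,
             orientation: str = "decomposition") -> EffectEstimate:
    """S-E association odds ratio in the full sample (cases + non-cases).

    ``orientation="decomposition"`` (default) returns
    ``(c+D)(e+F)/((a+B)(g+H))`` -- the factor satisfying
    ``ICR_c/nc = ICR_co x seor_cnc`` exactly.  ``"conventional"`` returns
    its reciprocal, ``odds(S+|E+)/odds(S+|E-)``, the quantity a logistic
    regression of S on E estimates.  Independence means 1 either way.
    """
    _check_orientation(orientation)
    m00, m10, m01, m11 = t.margins
    margins = {"a+B": m00, "c+D": m10, "e+F": m01, "g+H": m11}
    for name, v in margins.items():
        if v <= 0:
            raise InvalidTableError(f"stratum total {name} is zero; the S-E odds ratio is undefined")
    point = (m10 * m01) / (m00 * m11)
    if orientation == "conventional":
        point = 1.0 / point
    var = sum(1.0 / v for v in margins.values())
    return _log_wald(f"S-E OR_c/nc ({orientation})", point, var, level, n=t.total)


def icr_cnc(t: TwoByFourTable, scale: str = "multiplicative", basis: str = "RR",
            level: float = 0.95, continuity: bool = False,
            ci: str | None = None, n_boot: int = 2000,
            seed: int | None = None) -> EffectEstimate:
    """Interaction contrast in the full sample, multiplicative or additive.

    Multiplicative: joint effect over the product of single effects
    (``RR_se/(RR_s RR_e)`` or ``OR_se/(OR_s OR_e)``).  Additive: the RERI,
    joint minus sum of singles plus one (may be negative; no log CI).

    CIs: the OR basis carries the exact saturated-model log-Wald variance
    (sum of all eight reciprocal cells).  The RR basis shares cells across
    numerator and denominator, so no closed form is attached; request
    ``ci="bootstrap"`` for a seeded multinomial percentile interval
    (also available for the OR basis and the additive scale).
    """
    if scale not in ("multiplicative", "additive"):
        raise ParameterError(f"scale must be 'multiplicative' or 'additive', got {scale!r}")
    if basis not in ("RR", "OR"):
        raise ParameterError(f"basis must be 'RR' or 'OR', got {basis!r}")
    if ci not in (None, "bootstrap"):
        raise ParameterError(f"ci must be None or 'bootstrap', got {ci!r}")

    point, flags = _icr_cnc_point(t, scale, basis, continuity)
    name = f"ICR_c/nc ({scale}, {basis})" if scale == "multiplicative" else f"RERI ({basis})"

    if scale == "multiplicative" and basis == "OR" and ci is None:
        cells = t.to_dict()
        if any(v <= 0 for v in cells.values()):
            if not continuity:
                raise ZeroCellError(next(k for k, v in cells.items() if v <= 0))
            cells = _continuity(cells)
        var = sum(1.0 / v for v in cells.values())
        return _log_wald(name, point, var, level, flags=flags, n=t.total)

    if ci == "bootstrap":
        lo, hi = _bootstrap_ci(t, scale, basis, level, n_boot, seed)
        return EffectEstimate(estimand=name, point=point, log_se=None,
                              ci_low=lo, ci_high=hi, level=level,
                              method=f"bootstrap-percentile({n_boot})",
                              flags=flags, n=t.total)

    return EffectEstimate(estimand=name, point=point, log_se=None,
                          ci_low=None, ci_high=None, level=level,
                          method="point-only", flags=flags, n=t.total)


def _icr_cnc_point(t: TwoByFourTable, scale: str, basis: str,
                   continuity: bool) -> tuple[float, tuple[str, ...]]:
    effects = (rr_effects if basis == "RR" else or_effects)(t, continuity=continuity)
    prefix = "RR" if basis == "RR" else "OR"
    single_s = effects[f"{prefix}_s"].point
    single_e = effects[f"{prefix}_e"].point
    joint = effects[f"{prefix}_se"].point
    flags = tuple(sorted({f for e in effects.values() for f in e.flags}))
    if scale == "additive":
        return joint - (single_s + single_e - 1.0), flags
    if single_s <= 0 or single_e <= 0:
        raise ZeroCellError("c" if single_s <= 0 else "e")
    return joint / (single_s * single_e), flags


def _bootstrap_ci(t: TwoByFourTable, scale: str, basis: str, level: float,
                  n_boot: int, seed: int | None) -> tuple[float, float]:
    if n_boot < 2:
        raise ParameterError("n_boot must be at least 2")
    cells = np.array(list(t.to_dict().values()), dtype=float)
    n = cells.sum()
    if abs(n - round(n)) > 1e-9:
        warnings.warn("bootstrap on a non-integer (expected-value) table rounds the total")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(int(round(n)), cells / n, size=n_boot)
    vals = []
    names = TwoByFourTable._FIELDS
    for row in draws:
        try:
            bt = TwoByFourTable(**dict(zip(names, row.astype(float))))
            vals.append(_icr_cnc_point(bt, scale, basis, continuity=True)[0])
        except InvalidTableError:
            continue
    if len(vals) < n_boot // 2:
        raise ParameterError("too many degenerate bootstrap resamples; table too sparse")
    alpha = 1.0 - level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# case-control sampling and estimators
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> float:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def sample_case_control(t: TwoByFourTable, p: float, mode: str = "expected",
                        seed: int | None = None) -> CaseControlTable:
    """Draw a case-control study from the 2x4 population table.

    Cases are carried over; controls are a fraction ``p`` of each non-case
    stratum.  ``mode="expected"`` takes ``p x count`` deterministically
    (rounding half away from zero with a warning when not integral);
    ``mode="binomial"`` draws each control count from Binomial(non-cases, p)
    with the stated seed.
    """
    if not (0.0 < p <= 1.0):
        raise ParameterError(f"sampling fraction p must be in (0,1], got {p}")
    if mode not in ("expected", "binomial"):
        raise ParameterError(f"mode must be 'expected' or 'binomial', got {mode!r}")
    noncases = t.noncases
    if mode == "expected":
        controls = []
        for name, count in zip("bdfh", noncases):
            x = p * count
            if abs(x - round(x)) > 1e-9:
                rounded = _round_half_away(x)
                warnings.warn(f"expected control count {name} = p*{count} = {x:g} "
                              f"is not an integer; rounded to {rounded}")
                x = rounded
            else:
                x = round(x)
            controls.append(float(x))
    else:
        rng = np.random.default_rng(seed)
        counts = np.asarray(noncases)
        if np.any(np.abs(counts - np.round(counts)) > 1e-9):
            raise ParameterError("binomial sampling requires integer non-case counts")
        controls = [float(v) for v in rng.binomial(np.round(counts).astype(int), p)]
    return CaseControlTable(t.a, t.c, t.e, t.g, *controls, p=p)


def sample_case_control_exact(t: TwoByFourTable, p: float) -> CaseControlTable:
    """Expected-value sampling without rounding (real-valued controls).

    Preserves the exact identities ``ICR_cc = ICR_c/nc(OR basis)`` for any
    ``p``; use for analytic work rather than count data.
    """
    if not (0.0 < p <= 1.0):
        raise ParameterError(f"sampling fraction p must be in (0,1], got {p}")
    b, d, f, h = (p * v for v in t.noncases)
    return CaseControlTable(t.a, t.c, t.e, t.g, b, d, f, h, p=p)


def icr_cc(cc: CaseControlTable, level: float = 0.95,
           continuity: bool = False) -> EffectEstimate:
    """Case-control interaction contrast ratio ``ICR_cc = (ag/ce)(df/bh)``.

    ``Var(log) = sum of reciprocals of all eight cells`` -- the
    case-control asymptotic variance of the interaction coefficient.
    """
    cells = cc.to_dict()
    cells.pop("p")
    flags: tuple[str, ...] = ()
    if any(v <= 0 for v in cells.values()):
        if not continuity:
            raise ZeroCellError(next(k for k, v in cells.items() if v <= 0))
        cells = _continuity(cells)
        flags = ("continuity-corrected",)
    point = (cells["a"] * cells["g"] / (cells["c"] * cells["e"]) *
             cells["d"] * cells["f"] / (cells["b"] * cells["h"]))
    var = sum(1.0 / v for v in cells.values())
    n = sum(cells.values())
    return _log_wald("ICR_cc", point, var, level, flags=flags, n=n)


def seor_control(cc: CaseControlTable, level: float = 0.95,
                 orientation: str = "decomposition",
                 continuity: bool = False) -> EffectEstimate:
    """S-E association odds ratio among controls only.

    Decomposition orientation ``df/bh`` satisfies
    ``ICR_cc = ICR_co x seor_control`` exactly; the conventional
    orientation is its reciprocal ``bh/df``.
    """
    _check_orientation(orientation)
    cells = {"b": cc.b, "d": cc.d, "f": cc.f, "h": cc.h}
    flags: tuple[str, ...] = ()
    if any(v <= 0 for v in cells.values()):
        if not continuity:
            raise ZeroCellError(next(k for k, v in cells.items() if v <= 0))
        cells = _continuity(cells)
        flags = ("continuity-corrected",)
    point = cells["d"] * cells["f"] / (cells["b"] * cells["h"])
    if orientation == "conventional":
        point = 1.0 / point
    var = sum(1.0 / v for v in cells.values())
    return _log_wald(f"S-E OR_control ({orientation})", point, var, level,
                     flags=flags, n=sum(cells.values()))


# ---------------------------------------------------------------------------
# independence correction
# ---------------------------------------------------------------------------

def adjust_icr(icr_co_est: EffectEstimate, seor: EffectEstimate,
               ci_method: str = "bound_product") -> EffectEstimate:
    """Correct a case-only ICR by multiplying in an S-E association estimate.

    ``point = icr_co x seor``.  With the decomposition-oriented full-sample
    S-E OR this recovers the full-sample ICR exactly (the identity
    ``ICR_c/nc = ICR_co x seor``).

    CI methods:

    * ``bound_product`` (default): multiply the CI bounds pairwise --
      simple interval arithmetic, reproducible by hand from two printed
      estimates.
    * ``lognormal_sum``: add the two log-scale standard errors in
      quadrature and build a log-Wald interval.  Documented caveat: this
      treats the two estimates as independent, ignoring their covariance
      (they may share subjects).
    """
    if icr_co_est.point <= 0 or seor.point <= 0:
        raise ParameterError("both point estimates must be positive")
    if ci_method not in ("bound_product", "lognormal_sum"):
        raise ParameterError(f"unknown ci_method {ci_method!r}")
    if abs(icr_co_est.level - seor.level) > 1e-12:
        raise ParameterError("confidence levels of the two estimates differ")
    point = icr_co_est.point * seor.point
    flags = tuple(sorted(set(icr_co_est.flags) | set(seor.flags)))
    estimand = "ICR_c/nc (adjusted)"
    if ci_method == "bound_product":
        if None in (icr_co_est.ci_low, icr_co_est.ci_high, seor.ci_low, seor.ci_high):
            raise ParameterError("bound_product requires both input CIs")
        return EffectEstimate(
            estimand=estimand, point=point, log_se=None,
            ci_low=icr_co_est.ci_low * seor.ci_low,
            ci_high=icr_co_est.ci_high * seor.ci_high,
            level=icr_co_est.level, method="bound-product", flags=flags)
    if icr_co_est.log_se is None or seor.log_se is None:
        raise ParameterError("lognormal_sum requires both log-scale standard errors")
    var = icr_co_est.log_se ** 2 + seor.log_se ** 2
    return _log_wald(estimand, point, var, icr_co_est.level, flags=flags,
                     method="lognormal-sum (covariance ignored)")


def implied_icr_co(icr_cnc_point: float, seor_point: float,
                   orientation: str = "conventional") -> float:
    """Case-only ICR implied by a full-sample ICR and an S-E association OR.

    With the conventional S-E OR the case-only estimate inflates
    multiplicatively: ``ICR_co = ICR_c/nc x seor``.  With the
    decomposition orientation the same relation reads
    ``ICR_co = ICR_c/nc / seor``.  Under independence (seor = 1) the two
    designs agree either way.
    """
    _check_orientation(orientation)
    if icr_cnc_point <= 0 or seor_point <= 0:
        raise ParameterError("ratios must be positive")
    if orientation == "conventional":
        return icr_cnc_point * seor_point
    return icr_cnc_point / seor_point
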