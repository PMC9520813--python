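"""The five-step case-only analysis procedure.

1. Crude disease odds ratio per unit of the environmental exposure E.
2. Crude disease odds ratio per unit of the susceptibility factor S.
3. Full-sample multiplicative interaction contrast exp(b3) from the
   joint logistic model.
4. Independence check: the S-E odds ratio in the full sample, with a
   configurable decision rule (default: its CI contains 1).
5. The case-only estimate exp(g1) from cases alone.  If step 4 found
   dependence, the case-only estimate is multiplied by the
   decomposition-oriented S-E OR to recover the full-sample contrast;
   the adjusted value is always computed and stored so a borderline
   independence decision can be inspected, but it is flagged as the
   headline only in the dependent branch.

Under independence the case-only estimate targets the same contrast as
step 3 with a strictly smaller asymptotic variance (its Wald CI is
narrower), which is the point of the design.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .contingency import EffectEstimate, adjust_icr
from .errors import CaseOnlyError, ParameterError
from .glm import (
    SubjectData,
    fit_case_only,
    fit_independence,
    fit_interaction,
    fit_single_effect,
)

__all__ = [
    "Threshold",
    "WorkflowConfig",
    "IndependenceDecision",
    "WorkflowReport",
    "independence_decision",
    "run_workflow",
]


@dataclass(frozen=True)
class Threshold:
    """Explicit dichotomization rule: value and which side is 'abnormal' (=1).

    The direction is never inferred from the data; ``"above"`` codes
    values strictly greater than the cutoff as 1, ``"below"`` codes
    values strictly smaller as 1.
    """

    cutoff: float
    direction: str = "above"

    def __post_init__(self):
        if self.direction not in ("above", "below"):
            raise ParameterError(f"direction must be 'above' or 'below', got {self.direction!r}")
        if not (self.cutoff == self.cutoff and abs(self.cutoff) != float("inf")):
            raise ParameterError("threshold cutoff must be finite")

    def apply(self, series: pd.Series) -> pd.Series:
        if self.direction == "above":
            return (series > self.cutoff).astype(int)
        return (series < self.cutoff).astype(int)


@dataclass(frozen=True)
class WorkflowConfig:
    dichotomize_s: Threshold | None = None
    dichotomize_e: Threshold | None = None
    independence_rule: str = "ci_contains_one"
    epsilon: float | None = None
    ci_method: str = "bound_product"
    level: float = 0.95
    covariates: tuple[str, ...] = ()
    continuous_s_approximation: bool = False

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.independence_rule not in ("ci_contains_one", "tolerance"):
            raise ParameterError(
                f"independence_rule must be 'ci_contains_one' or 'tolerance', "
                f"got {self.independence_rule!r}")
        if self.independence_rule == "tolerance":
            if self.epsilon is None or self.epsilon <= 0:
                raise ParameterError("the tolerance rule requires epsilon > 0")
        if self.ci_method not in ("bound_product", "lognormal_sum"):
            raise ParameterError(f"unknown ci_method {self.ci_method!r}")
        if not (0.0 < self.level < 1.0):
            raise ParameterError("level must be in (0,1)")


@dataclass(frozen=True)
class IndependenceDecision:
    independent: bool
    rule: str
    rationale: str

    def to_dict(self) -> dict:
        return {"independent": self.independent, "rule": self.rule,
                "rationale": self.rationale}


def independence_decision(seor: EffectEstimate, rule: str = "ci_contains_one",
                          epsilon: float | None = None) -> IndependenceDecision:
    """Decide whether S and E can be treated as independent.

    Default rule: independent iff the S-E OR confidence interval contains
    1 (invariant to the orientation of the OR, since inversion swaps the
    bounds around 1).  The ``tolerance`` rule additionally requires the
    point estimate to be within a factor (1 + epsilon) of 1, making the
    informal "close to 1" clause operational.
    """
    if seor.ci_low is None or seor.ci_high is None:
        raise ParameterError("the independence rule needs a confidence interval")
    ci_ok = seor.ci_low <= 1.0 <= seor.ci_high
    if rule == "ci_contains_one":
        verdict = ci_ok
        why = (f"CI ({seor.ci_low:.4g}, {seor.ci_high:.4g}) "
               f"{'contains' if ci_ok else 'excludes'} 1")
    elif rule == "tolerance":
        if epsilon is None or epsilon <= 0:
            raise ParameterError("tolerance rule requires epsilon > 0")
        close = abs(math.log(seor.point)) <= math.log1p(epsilon)
        verdict = ci_ok and close
        why = (f"CI {'contains' if ci_ok else 'excludes'} 1; point "
               f"{seor.point:.4g} {'within' if close else 'outside'} "
               f"factor {1 + epsilon:g} of 1")
    else:
        raise ParameterError(f"unknown independence rule {rule!r}")
    return IndependenceDecision(independent=verdict, rule=rule, rationale=why)


@dataclass(frozen=True)
class WorkflowReport:
    """Ordered outputs of the five-step procedure.

    ``headline`` names which of ``icr_co`` / ``icr_adjusted`` carries the
    final interaction estimate; the other is retained for inspection.
    ``narrative`` mirrors a two-column estimate/explanation layout.
    """

    or_e: EffectEstimate
    or_s: EffectEstimate
    icr_cnc: EffectEstimate
    seor_cnc: EffectEstimate              # decomposition orientation
    seor_cnc_conventional: EffectEstimate
    decision: IndependenceDecision
    icr_co: EffectEstimate
    icr_adjusted: EffectEstimate
    headline: str
    narrative: tuple[tuple[str, str], ...] = field(default=())
    n_used: int = 0

    @property
    def headline_estimate(self) -> EffectEstimate:
        return self.icr_co if self.headline == "icr_co" else self.icr_adjusted

    def to_dict(self) -> dict:
        return {
            "or_e": self.or_e.to_dict(),
            "or_s": self.or_s.to_dict(),
            "icr_cnc": self.icr_cnc.to_dict(),
            "seor_cnc": self.seor_cnc.to_dict(),
            "seor_cnc_conventional": self.seor_cnc_conventional.to_dict(),
            "independence_decision": self.decision.to_dict(),
            "icr_co": self.icr_co.to_dict(),
            "icr_adjusted": self.icr_adjusted.to_dict(),
            "headline": self.headline,
            "narrative": [list(row) for row in self.narrative],
            "n_used": self.n_used,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        width = max(len(e) for e, _ in self.narrative) + 2
        lines = ["Case-only workflow report", "=" * 25, ""]
        lines += [f"{'Effect estimate':<{width}}Explanation", "-" * (width + 40)]
        for est, expl in self.narrative:
            lines.append(f"{est:<{width}}{expl}")
        return "\n".join(lines)


def _step(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except CaseOnlyError as exc:
        raise type(exc)(f"workflow aborted at step '{name}': {exc}") from exc


def run_workflow(data: SubjectData, cfg: WorkflowConfig) -> WorkflowReport:
    """Execute steps 1-5 on subject-level data and assemble the report.

    Dichotomization thresholds from the config are applied first (on
    copies; direction explicit).  Any fit failure aborts with the step
    named in the error.  Identical input, config and data yield a
    byte-identical report.
    """
    df = data.df.copy()
    if cfg.dichotomize_s is not None:
        df[data.s_col] = cfg.dichotomize_s.apply(df[data.s_col])
    if cfg.dichotomize_e is not None:
        df[data.e_col] = cfg.dichotomize_e.apply(df[data.e_col])
    work = SubjectData(df, d_col=data.d_col, s_col=data.s_col, e_col=data.e_col,
                       covariates=cfg.covariates or data.covariates,
                       stratum_col=data.stratum_col)
    cs = "approx" if cfg.continuous_s_approximation else "error"

    or_e = _step("1: single-effect OR of E", fit_single_effect, work, "E",
                 level=cfg.level)
    or_s = _step("2: single-effect OR of S", fit_single_effect, work, "S",
                 level=cfg.level)
    icr_full = _step("3: full-sample interaction", fit_interaction, work,
                     level=cfg.level)
    seor = _step("4: independence check", fit_independence, work,
                 level=cfg.level, orientation="decomposition", continuous_s=cs)
    decision = independence_decision(seor, cfg.independence_rule, cfg.epsilon)
    cases = _step("5: restrict to cases", SubjectData.restrict_to_cases, work)
    co = _step("5: case-only estimate", fit_case_only, cases, level=cfg.level,
               continuous_s=cs)
    adjusted = _step("5: independence correction", adjust_icr, co, seor,
                     ci_method=cfg.ci_method)
    headline = "icr_co" if decision.independent else "icr_adjusted"

    verdict = ("independent; the case-only ICR substitutes for the full-sample ICR"
               if decision.independent else
               "associated; the case-only ICR is multiplied by the S-E OR "
               "(decomposition orientation) to recover the full-sample ICR")
    narrative = (
        (or_e.rounded(), "Fold-difference in disease odds per one unit of E."),
        (or_s.rounded(), "Fold-difference in disease odds per one unit of S."),
        (icr_full.rounded(), "Multiplicative ICR, full sample (cases and non-cases)."),
        (seor.rounded(), f"S-E association in the full sample: {verdict} "
                         f"[{decision.rationale}]."),
        (co.rounded(), "Case-only ICR from cases alone."),
        (adjusted.rounded(),
         "Case-only ICR x S-E OR = full-sample ICR (adjusted estimate"
         + ("; retained for inspection, not the headline" if decision.independent
            else "; headline estimate") + ")."),
    )
    return WorkflowReport(
        or_e=or_e, or_s=or_s, icr_cnc=icr_full, seor_cnc=seor,
        seor_cnc_conventional=replace(seor.reciprocal(),
                                      estimand="S-E OR_c/nc (conventional)"),
        decision=decision,
        icr_co=co, icr_adjusted=adjusted, headline=headline,
        narrative=narrative, n_used=work.n,
    )
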