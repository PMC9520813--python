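"""File formats, configuration and run logging.

Aggregated tables travel as JSON objects with keys ``a,B,c,D,e,F,g,H``
or as a single-row CSV with those headers.  Estimates and workflow
reports serialize to JSON records ``{estimand, point, ci_low, ci_high,
level, method}``.  Subject-level data is CSV with a column map declared
in a YAML config.  Report files are byte-stable given identical inputs;
wall-clock timestamps live only in the separate run log.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .contingency import EffectEstimate, TwoByFourTable
from .errors import InputError, ParameterError
from .glm import SubjectData
from .workflow import Threshold, WorkflowConfig, WorkflowReport

__all__ = [
    "RunLog",
    "read_table",
    "write_table",
    "read_config",
    "read_subjects",
    "write_report",
    "write_estimates",
]


@dataclass
class RunLog:
    """Append-only record of one analysis run.

    Each entry is a step name plus free-form detail; the log also pins
    the package version, the seed in force and a hash of the effective
    configuration, so a report can be traced to exactly one run.
    """

    seed: int | None = None
    config_hash: str | None = None
    version: str = __version__
    entries: list[dict] = field(default_factory=list)

    def record(self, step: str, **detail) -> None:
        self.entries.append({
            "step": step,
            "time": datetime.now(timezone.utc).isoformat(),
            **detail,
        })

    def to_json(self) -> str:
        return json.dumps({
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "entries": self.entries,
        }, indent=2)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# aggregated tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> TwoByFourTable:
    """Read a 2x4 table from JSON (keys a,B,c,D,e,F,g,H) or one-row CSV."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"table file not found: {path}")
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise InputError(f"{path}: invalid JSON ({exc})") from exc
        if not isinstance(payload, dict):
            raise InputError(f"{path}: expected a JSON object with the eight cell keys")
        return TwoByFourTable.from_dict(payload)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"{path}: unreadable CSV ({exc})") from exc
    if len(df) != 1:
        raise InputError(f"{path}: table CSV must contain exactly one row, got {len(df)}")
    return TwoByFourTable.from_dict(df.iloc[0].to_dict())


def write_table(t: TwoByFourTable, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(t.to_dict(), indent=2, sort_keys=True) + "\n")
    else:
        pd.DataFrame([t.to_dict()]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration and subject-level data
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {"d": "D", "s": "S", "e": "E"}


def read_config(path: str | Path) -> dict:
    """Parse the YAML analysis config into column map, drop rules and
    a :class:`WorkflowConfig`.

    Schema (all keys optional except ``columns`` when names differ from
    D/S/E)::

        columns: {d: outcome, s: biomarker, e: metal_level}
        covariates: [age]
        stratum: site
        drop:                      # applied before anything else
          - {column: on_treatment, equals: 1}
        dichotomize:
          e: {cutoff: 1.4, direction: above}
        independence_rule: ci_contains_one   # or tolerance
        epsilon: null
        ci_method: bound_product             # or lognormal_sum
        level: 0.95
        continuous_s_approximation: false
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise InputError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise InputError(f"{path}: config must be a mapping")

    columns = {**_DEFAULT_COLUMNS, **{k.lower(): v for k, v in
                                      (raw.get("columns") or {}).items()}}
    unknown = set(columns) - set(_DEFAULT_COLUMNS)
    if unknown:
        raise InputError(f"unknown column roles {sorted(unknown)}; use d/s/e")

    dicho = {}
    for role, spec in (raw.get("dichotomize") or {}).items():
        role = role.lower()
        if role not in ("s", "e", "d"):
            raise InputError(f"dichotomize role must be s, e or d, got {role!r}")
        if not isinstance(spec, dict) or "cutoff" not in spec:
            raise InputError(f"dichotomize.{role} needs a cutoff")
        if "direction" not in spec:
            raise InputError(f"dichotomize.{role} needs an explicit direction "
                             "(above/below); it is never inferred")
        dicho[role] = Threshold(float(spec["cutoff"]), spec["direction"])

    drop_rules = []
    for rule in raw.get("drop") or []:
        if not isinstance(rule, dict) or "column" not in rule:
            raise InputError("each drop rule needs a 'column'")
        ops = {k: v for k, v in rule.items() if k in ("equals", "above", "below")}
        if len(ops) != 1:
            raise InputError("each drop rule needs exactly one of equals/above/below")
        drop_rules.append(rule)

    wf = WorkflowConfig(
        dichotomize_s=dicho.get("s"),
        dichotomize_e=dicho.get("e"),
        independence_rule=raw.get("independence_rule", "ci_contains_one"),
        epsilon=raw.get("epsilon"),
        ci_method=raw.get("ci_method", "bound_product"),
        level=float(raw.get("level", 0.95)),
        covariates=tuple(raw.get("covariates") or ()),
        continuous_s_approximation=bool(raw.get("continuous_s_approximation", False)),
    )
    return {
        "columns": columns,
        "stratum": raw.get("stratum"),
        "drop": drop_rules,
        "dichotomize_d": dicho.get("d"),
        "workflow": wf,
        "raw": raw,
    }


def read_subjects(path: str | Path, config: dict,
                  log: RunLog | None = None) -> SubjectData:
    """Load subject-level CSV, apply drop rules and outcome dichotomization.

    Drop rules remove matching rows before any fit; missing values in
    used columns are dropped (and counted) by :class:`SubjectData`.  The
    S/E dichotomizations from the config are applied later by the
    workflow, so the loaded data keeps the measured values.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"data file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"{path}: unreadable CSV ({exc})") from exc
    if log is not None:
        log.record("data-loaded", path=str(path), rows=len(df))

    for rule in config.get("drop", []):
        col = rule["column"]
        if col not in df.columns:
            raise InputError(f"drop rule column {col!r} not in data")
        before = len(df)
        if "equals" in rule:
            mask = df[col] == rule["equals"]
        elif "above" in rule:
            mask = df[col] > rule["above"]
        else:
            mask = df[col] < rule["below"]
        df = df[~mask].reset_index(drop=True)
        if log is not None:
            log.record("drop-rule", column=col, rule={k: v for k, v in rule.items()
                                                      if k != "column"},
                       removed=before - len(df))

    cols = config["columns"]
    d_col = cols["d"]
    if config.get("dichotomize_d") is not None:
        if d_col not in df.columns:
            raise InputError(f"outcome column {d_col!r} not in data")
        thr: Threshold = config["dichotomize_d"]
        df[d_col] = thr.apply(df[d_col])
        if log is not None:
            log.record("dichotomize-outcome", column=d_col,
                       cutoff=thr.cutoff, direction=thr.direction)

    wf: WorkflowConfig = config["workflow"]
    data = SubjectData(df, d_col=d_col, s_col=cols["s"], e_col=cols["e"],
                       covariates=wf.covariates,
                       stratum_col=config.get("stratum"))
    if log is not None:
        log.record("missing-dropped", removed=data.n_dropped, n_used=data.n)
    return data


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_estimates(estimates: dict[str, EffectEstimate] | list[EffectEstimate],
                    path: str | Path) -> None:
    if isinstance(estimates, dict):
        payload = {k: v.to_dict() for k, v in estimates.items()}
    else:
        payload = [v.to_dict() for v in estimates]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_report(report: WorkflowReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json() + "\n")
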