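"""CSV input, parameter-block round-tripping, and the pre-analysis filters.

Serial results arrive as a long CSV with columns ``subject_id``,
``timestamp`` (ISO-8601) and ``value``; optional ``analyte`` and ``sex``
columns pass through untouched.  Two filters run before any analysis:
results below the assay's reporting limit are excluded outright, and, for
diurnally varying biomarkers, only samples collected inside the morning
window (08:00-10:00 by default) are retained.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bv import BVEstimates
from .errors import ConfigError, DataError
from .model import PEBParameters
from .series import SubjectSeries

__all__ = [
    "RunConfig",
    "validate_schema",
    "read_results",
    "frame_to_series",
    "write_parameters",
    "read_parameters",
    "write_bv_estimates",
    "read_bv_estimates",
]

REQUIRED_COLUMNS = ("subject_id", "timestamp", "value")


@dataclass(frozen=True)
class RunConfig:
    """Shared run settings: thresholds, filters, randomness."""

    analyte: str = ""
    subgroup: str | None = None
    z: float = 1.96
    min_gap_hours: float = 24.0
    diurnal_window: tuple[float, float] | None = None  # e.g. (8.0, 10.0)
    reporting_limit: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ConfigError(f"z must be > 0, got {self.z}")
        if self.min_gap_hours < 0:
            raise ConfigError("min_gap_hours must be >= 0")
        if self.diurnal_window is not None:
            lo, hi = self.diurnal_window
            if not lo < hi:
                raise ConfigError("diurnal window start must precede its end")


def validate_schema(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"input table is missing required columns: {missing}")


def read_results(
    path: str | Path,
    cfg: RunConfig | None = None,
) -> tuple[list[SubjectSeries], dict]:
    """Read, validate and filter a serial-results CSV into per-subject series.

    Returns the series plus an audit dict of exclusion counts.  Rows with
    unparseable timestamps or values raise a schema error naming the row.
    """
    cfg = cfg or RunConfig()
    df = pd.read_csv(path)
    validate_schema(df)
    audit: dict[str, int] = {"n_input": int(len(df))}

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise DataError(f"row {row}: unparseable timestamp {df['timestamp'].iloc[row]!r}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna())[0])
        raise DataError(f"row {row}: unparseable value {df['value'].iloc[row]!r}")
    df = df.assign(timestamp=ts, value=vals)

    if cfg.reporting_limit is not None:
        keep = df["value"] >= cfg.reporting_limit
        audit["n_below_reporting_limit"] = int((~keep).sum())
        df = df[keep]
    if cfg.diurnal_window is not None:
        hours = df["timestamp"].dt.hour + df["timestamp"].dt.minute / 60.0
        keep = (hours >= cfg.diurnal_window[0]) & (hours < cfg.diurnal_window[1])
        audit["n_outside_diurnal_window"] = int((~keep).sum())
        df = df[keep]
    audit["n_retained"] = int(len(df))

    return frame_to_series(df, sort=True), audit


def frame_to_series(df: pd.DataFrame, sort: bool = True) -> list[SubjectSeries]:
    """Group a long table into SubjectSeries, sorted by time within subject."""
    out: list[SubjectSeries] = []
    sub_col = "sex" if "sex" in df.columns else None
    for sid, grp in df.groupby("subject_id", sort=True):
        if sort:
            grp = grp.sort_values("timestamp", kind="stable")
        ts = [t.to_pydatetime() if hasattr(t, "to_pydatetime") else t for t in pd.to_datetime(grp["timestamp"])]
        subgroup = str(grp[sub_col].iloc[0]) if sub_col else None
        out.append(
            SubjectSeries(
                subject_id=str(sid),
                timestamps=ts,
                values=grp["value"].to_numpy(float),
                subgroup=subgroup,
            )
        )
    return out


def _plain(value):
    if isinstance(value, np.floating):
        return float(value)
    if isinstance(value, np.integer):
        return int(value)
    return value


def write_parameters(params: PEBParameters, path: str | Path) -> None:
    """Persist a parameter set as a flat key-value YAML block."""
    block = {k: _plain(v) for k, v in dataclasses.asdict(params).items()}
    Path(path).write_text(yaml.safe_dump(block, sort_keys=True))


def read_parameters(path: str | Path) -> PEBParameters:
    block = yaml.safe_load(Path(path).read_text())
    if not isinstance(block, dict):
        raise DataError(f"{path}: not a parameter block")
    try:
        return PEBParameters(**block)
    except TypeError as exc:
        raise DataError(f"{path}: malformed parameter block ({exc})") from exc


def write_bv_estimates(bv: BVEstimates, path: str | Path) -> None:
    block = {k: _plain(v) for k, v in dataclasses.asdict(bv).items()}
    block["ci_cv_i"] = list(bv.ci_cv_i) if bv.ci_cv_i else None
    block["ci_cv_g"] = list(bv.ci_cv_g) if bv.ci_cv_g else None
    Path(path).write_text(yaml.safe_dump(block, sort_keys=True))


def read_bv_estimates(path: str | Path) -> BVEstimates:
    block = yaml.safe_load(Path(path).read_text())
    if not isinstance(block, dict):
        raise DataError(f"{path}: not a BV estimate block")
    for key in ("ci_cv_i", "ci_cv_g"):
        if block.get(key) is not None:
            block[key] = tuple(block[key])
    try:
        return BVEstimates(**block)
    except TypeError as exc:
        raise DataError(f"{path}: malformed BV estimate block ({exc})") from exc
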