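"""Synthetic serial-result cohorts with the hierarchical structure PEB assumes.

The generator draws each subject's homeostatic set point from
``N(mu_pop, sigma_G^2)`` on the working scale (natural log or Box-Cox) and
each result from ``N(mu_I, sigma_I^2 + sigma_A^2)``, then back-transforms to
the original measurement scale.  On top of that clean hierarchical core it can
layer the artifacts routine laboratory extracts contain: a persistently
shifted pathological subgroup, censoring below a reporting limit, results
collected outside the morning phlebotomy window, and subjects whose
within-subject variation is inflated relative to the population value
(heteroscedasticity).

Coefficients of variation (percent, original scale) are converted to
working-scale variances with ``sigma^2 = ln(1 + CV^2/100^2)`` on the log
scale, and by the delta method ``sigma = (CV/100) * mu^lambda`` on a Box-Cox
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import PEBParameters, boxcox, boxcox_inverse
from .series import SubjectSeries

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort", "simulate_bv_study"]

_EPOCH = datetime(2022, 1, 3, 0, 0, 0)  # arbitrary Monday anchor for timestamps


@dataclass(frozen=True)
class SimulationConfig:
    """Generating conditions for a synthetic cohort.

    Defaults emulate an albumin-like biomarker sampled in a designed
    biological-variation study: 30 subjects, 10 weekly visits, morning
    collection, no pathology and no censoring.
    """

    mu_pop_original: float = 4.522       # g/dL, albumin-like population mean
    cv_g_pct: float = 6.0                # between-subject CV, %
    cv_i_pct: float = 2.3                # within-subject CV, %
    cv_a_pct: float = 1.8                # analytical CV, %
    lambda_shape: float | str = "log"    # "log" or a Box-Cox exponent
    n_subjects: int = 30
    visits_per_subject: int = 10
    replicate_count: int = 1
    pathological_fraction: float = 0.0   # fraction of subjects with shifted set point
    pathological_shift_sd: float = 4.0   # shift in units of sigma_pop (working scale)
    spike_fraction: float = 0.0          # per-result probability of a transient spike
    spike_shift_sd: float = 6.0          # spike size in units of sigma_pop (working scale)
    reporting_limit: float = 0.0         # original-scale censoring threshold
    gap_hours_range: tuple[float, float] = (6.5 * 24, 7.5 * 24)  # ~weekly sampling
    morning_window: tuple[float, float] = (8.0, 10.0)  # collection hour-of-day window
    scatter_times: bool = False          # spread collection over the whole day
    heteroscedastic_multiplier: float = 1.0  # sigma_I inflation for affected subjects
    affected_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_pop_original <= 0:
            raise ConfigError("mu_pop_original must be positive")
        if min(self.cv_g_pct, self.cv_i_pct, self.cv_a_pct) < 0:
            raise ConfigError("coefficients of variation must be non-negative")
        if self.n_subjects < 1 or self.visits_per_subject < 1:
            raise ConfigError("n_subjects and visits_per_subject must be >= 1")
        if self.replicate_count < 1:
            raise ConfigError("replicate_count must be >= 1")
        if not 0.0 <= self.pathological_fraction < 1.0:
            raise ConfigError("pathological_fraction must lie in [0, 1)")
        if not 0.0 <= self.spike_fraction < 1.0:
            raise ConfigError("spike_fraction must lie in [0, 1)")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ConfigError("affected_fraction must lie in [0, 1]")
        if self.heteroscedastic_multiplier < 1.0:
            raise ConfigError("heteroscedastic_multiplier must be >= 1")
        if self.reporting_limit < 0:
            raise ConfigError("reporting_limit must be >= 0")
        lo, hi = self.gap_hours_range
        if not 0 < lo <= hi:
            raise ConfigError("gap_hours_range must satisfy 0 < low <= high")
        w0, w1 = self.morning_window
        if not 0 <= w0 < w1 <= 24:
            raise ConfigError("morning_window must satisfy 0 <= start < end <= 24")

    # -- working-scale geometry --------------------------------------------

    @property
    def lambda_(self) -> float:
        return 0.0 if self.lambda_shape == "log" else float(self.lambda_shape)

    @property
    def mu_work(self) -> float:
        return boxcox(self.mu_pop_original, self.lambda_)

    def _sigma_work(self, cv_pct: float) -> float:
        if self.lambda_shape == "log":
            return math.sqrt(math.log1p((cv_pct / 100.0) ** 2))
        # delta method: d/dx boxcox(x) = x^(lambda-1)
        return (cv_pct / 100.0) * self.mu_pop_original**self.lambda_

    @property
    def sigma_g_work(self) -> float:
        return self._sigma_work(self.cv_g_pct)

    @property
    def sigma_i_work(self) -> float:
        return self._sigma_work(self.cv_i_pct)

    @property
    def sigma_a_work(self) -> float:
        return self._sigma_work(self.cv_a_pct)

    @property
    def sigma_pop_work(self) -> float:
        return math.sqrt(self.sigma_g_work**2 + self.sigma_i_work**2 + self.sigma_a_work**2)

    def true_b1(self) -> float:
        """Intraclass correlation implied by the generating variances."""
        vg = self.sigma_g_work**2
        vw = self.sigma_i_work**2 + self.sigma_a_work**2
        return vg / (vg + vw)

    def true_parameters(self) -> PEBParameters:
        """PEB parameters matched to the generating model (the oracle)."""
        scale = "log" if self.lambda_shape == "log" else "boxcox"
        return PEBParameters(
            mu_pop=self.mu_work,
            sigma_pop=self.sigma_pop_work,
            b1=self.true_b1(),
            scale=scale,
            lambda_=None if scale == "log" else self.lambda_,
        )


@dataclass
class SyntheticCohort:
    """Generated series plus the generating truth, kept for recovery tests."""

    series: list[SubjectSeries]
    truth: SimulationConfig
    set_points: dict[str, float]            # per-subject true mu_I (working scale)
    pathological: set[str] = field(default_factory=set)
    heteroscedastic: set[str] = field(default_factory=set)
    below_limit: list[tuple[str, int]] = field(default_factory=list)
    spikes: list[tuple[str, int]] = field(default_factory=list)

    def to_frame(self, include_censored: bool = False) -> pd.DataFrame:
        """Long-format table with the CSV schema the estimation pipelines read."""
        censored = set(self.below_limit)
        rows = []
        for s in self.series:
            for i, (ts, v) in enumerate(zip(s.timestamps, s.values)):
                if not include_censored and (s.subject_id, i) in censored:
                    continue
                rows.append((s.subject_id, ts, v))
        return pd.DataFrame(rows, columns=["subject_id", "timestamp", "value"])


def _timestamps(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> list[datetime]:
    lo, hi = cfg.gap_hours_range
    gaps = rng.uniform(lo, hi, size=n - 1) if n > 1 else np.empty(0)
    start_day = int(rng.integers(0, 365))
    days = np.floor(np.concatenate([[0.0], np.cumsum(gaps)]) / 24.0)
    if cfg.scatter_times:
        hours = rng.uniform(0.0, 24.0, size=n)
    else:
        hours = rng.uniform(cfg.morning_window[0], cfg.morning_window[1], size=n)
    out = []
    for d, h in zip(days, hours):
        out.append(_EPOCH + timedelta(days=start_day + float(d), hours=float(h)))
    # guard against identical-day collisions producing non-increasing stamps
    for i in range(1, n):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + timedelta(hours=1)
    return out


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort of serial results from the two-level hierarchical model.

    Each subject receives an independent random sub-stream spawned from the
    configured seed, so cohorts are reproducible and individual subjects are
    stable under changes to ``n_subjects``.
    """
    root = np.random.SeedSequence(cfg.seed)
    subj_seqs = root.spawn(cfg.n_subjects + 1)
    assign_rng = np.random.default_rng(subj_seqs[-1])

    n_path = round(cfg.pathological_fraction * cfg.n_subjects)
    n_het = round(cfg.affected_fraction * cfg.n_subjects)
    ids = [f"S{i:05d}" for i in range(cfg.n_subjects)]
    path_ids = set(assign_rng.choice(ids, size=n_path, replace=False)) if n_path else set()
    het_ids = set(assign_rng.choice(ids, size=n_het, replace=False)) if n_het else set()

    sigma_within = math.sqrt(cfg.sigma_i_work**2 + cfg.sigma_a_work**2)
    series: list[SubjectSeries] = []
    set_points: dict[str, float] = {}
    below: list[tuple[str, int]] = []
    spikes: list[tuple[str, int]] = []

    for sid, seq in zip(ids, subj_seqs):
        rng = np.random.default_rng(seq)
        mu_i = rng.normal(cfg.mu_work, cfg.sigma_g_work)
        if sid in path_ids:
            mu_i += cfg.pathological_shift_sd * cfg.sigma_pop_work
        sw = sigma_within
        if sid in het_ids:
            sw = math.sqrt(
                (cfg.heteroscedastic_multiplier * cfg.sigma_i_work) ** 2
                + cfg.sigma_a_work**2
            )
        t_vals = rng.normal(mu_i, sw, size=cfg.visits_per_subject)
        if cfg.spike_fraction > 0:
            hit = rng.random(cfg.visits_per_subject) < cfg.spike_fraction
            t_vals[hit] += cfg.spike_shift_sd * cfg.sigma_pop_work
            for i in np.flatnonzero(hit):
                spikes.append((sid, int(i)))
        lam = cfg.lambda_
        if lam != 0.0:
            # reject working-scale draws outside the Box-Cox image (rare tail)
            bad = 1.0 + lam * t_vals <= 0
            while bad.any():
                t_vals[bad] = rng.normal(mu_i, sw, size=int(bad.sum()))
                bad = 1.0 + lam * t_vals <= 0
        values = np.asarray(boxcox_inverse(t_vals, lam), dtype=float).reshape(-1)
        ts = _timestamps(rng, cfg, cfg.visits_per_subject)
        for i, v in enumerate(values):
            if v < cfg.reporting_limit:
                below.append((sid, i))
        series.append(SubjectSeries(subject_id=sid, timestamps=ts, values=values))
        set_points[sid] = float(mu_i)

    return SyntheticCohort(
        series=series,
        truth=cfg,
        set_points=set_points,
        pathological=path_ids,
        heteroscedastic=het_ids,
        below_limit=below,
        spikes=spikes,
    )


def simulate_bv_study(
    cfg: SimulationConfig,
    drift_subject: str | None = None,
    drift_sd_total: float = 0.0,
    inflated_subject: str | None = None,
    inflation: float = 1.0,
) -> pd.DataFrame:
    """Balanced biological-variation study table: subjects x visits x replicates.

    Analytical replicate noise (``cv_a_pct``) is added at the replicate level
    on top of the visit-level biological draw.  Optional engineered violations
    for outlier-cascade tests: ``drift_subject`` receives a deterministic
    linear drift totalling ``drift_sd_total`` within-subject SDs over the
    study; ``inflated_subject`` has its within-subject SD multiplied by
    ``inflation``.
    """
    root = np.random.SeedSequence(cfg.seed)
    subj_seqs = root.spawn(cfg.n_subjects)
    ids = [f"S{i:05d}" for i in range(cfg.n_subjects)]
    lam = cfg.lambda_
    rows = []
    for sid, seq in zip(ids, subj_seqs):
        rng = np.random.default_rng(seq)
        mu_i = rng.normal(cfg.mu_work, cfg.sigma_g_work)
        si = cfg.sigma_i_work * (inflation if sid == inflated_subject else 1.0)
        for visit in range(cfg.visits_per_subject):
            biological = rng.normal(mu_i, si) if si > 0 else mu_i
            if sid == drift_subject and cfg.visits_per_subject > 1:
                frac = visit / (cfg.visits_per_subject - 1)
                biological += frac * drift_sd_total * cfg.sigma_i_work
            for rep in range(cfg.replicate_count):
                t = biological + (
                    rng.normal(0.0, cfg.sigma_a_work) if cfg.sigma_a_work > 0 else 0.0
                )
                if lam != 0.0:
                    while 1.0 + lam * t <= 0:
                        t = biological + rng.normal(0.0, cfg.sigma_a_work)
                rows.append((sid, visit, rep, float(boxcox_inverse(t, lam))))
    return pd.DataFrame(rows, columns=["subject_id", "visit_index", "replicate_index", "value"])
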