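"""Variance-component estimation from a designed biological-variation study.

A balanced design — subjects sampled at scheduled visits, optionally with
duplicate analyses — is cleaned by a four-level outlier cascade and then
decomposed by nested ANOVA into analytical, within-subject and
between-subject components, reported as coefficients of variation (CVs).
Those CVs, together with the analytical CV from quality control and a
population mean, convert to log-scale PEB parameters: proportional
(constant-CV) variation becomes additive on the log scale, where the
hierarchical normal model applies.

Outlier cascade, in order:

1. *analytical* — Burnett-type test on duplicate differences: samples whose
   replicate spread is incompatible with the pooled analytical SD are
   dropped (skipped, with an audit note, when there are no replicates);
2. *participant mean* — Reed criterion: an extreme subject mean is excluded
   when its gap to the nearest mean exceeds one third of the range;
3. *individual trend* — subjects with a significant linear drift over the
   study (regression on visit index, p < 0.01) are excluded;
4. *homogeneity of within-subject variance* — Bartlett (or Cochran's C) on
   per-subject residual variances; the most extreme subject is removed
   iteratively until homogeneity is achieved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DomainError, EstimationError
from .model import PEBParameters

__all__ = [
    "BVEstimates",
    "VarianceComponents",
    "Exclusion",
    "outlier_cascade",
    "nested_anova_cv",
    "bv_to_peb",
]

_REQUIRED_COLS = ("subject_id", "visit_index", "value")


@dataclass(frozen=True)
class BVEstimates:
    """Biological-variation summary: CVs in percent, mean on the original scale."""

    cv_i_pct: float
    cv_g_pct: float
    cv_a_pct: float
    mu_pop_original: float
    ci_cv_i: tuple[float, float] | None = None
    ci_cv_g: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.cv_i_pct, self.cv_g_pct, self.cv_a_pct) < 0:
            raise DomainError("coefficients of variation must be non-negative")
        if self.mu_pop_original <= 0:
            raise DomainError("mu_pop_original must be positive")
        for ci, point in ((self.ci_cv_i, self.cv_i_pct), (self.ci_cv_g, self.cv_g_pct)):
            if ci is not None and not ci[0] <= point <= ci[1]:
                raise DomainError(f"CI {ci} does not bracket the point estimate {point}")


@dataclass(frozen=True)
class Exclusion:
    level: str          # analytical | mean | trend | homogeneity | note
    target: str         # subject or subject/visit identifier
    reason: str


@dataclass(frozen=True)
class VarianceComponents:
    """Nested-ANOVA variance split with the exclusion audit trail.

    Components are variances on the analysis scale used by the chosen mode
    (squared CV fractions for CV-ANOVA, log-scale variances for ln-ANOVA).
    """

    var_analytical: float
    var_within: float
    var_between: float
    n_subjects_used: int
    exclusions: tuple[Exclusion, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if min(self.var_analytical, self.var_within, self.var_between) < 0:
            raise DomainError("variance components must be non-negative")


def _check_schema(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLS if c not in data.columns]
    if missing:
        raise DataError(f"BV table is missing required columns: {missing}")
    df = data.copy()
    if "replicate_index" not in df.columns:
        df["replicate_index"] = 0
    if df["value"].le(0).any():
        raise DataError("BV values must be positive (CV-based analysis)")
    return df


def _burnett_outliers(df: pd.DataFrame, alpha: float = 0.05) -> list[tuple[str, int]]:
    """Duplicate pairs whose difference exceeds the pooled analytical SD bound.

    With k duplicate pairs, the pooled analytical SD is sqrt(sum d^2 / 2k);
    a pair is an outlier when |d| exceeds the Bonferroni-adjusted normal
    bound sd_a * sqrt(2) * z_{1 - alpha/(2k)}.
    """
    pairs = []
    for (sid, visit), grp in df.groupby(["subject_id", "visit_index"], sort=True):
        vals = grp["value"].to_numpy()
        if len(vals) >= 2:
            pairs.append((sid, int(visit), float(vals[1] - vals[0])))
    if not pairs:
        return []
    out: list[tuple[str, int]] = []
    current = pairs
    while True:
        d = np.array([p[2] for p in current])
        k = d.size
        if k < 3:
            break
        sd_a = math.sqrt(float(np.sum(d**2)) / (2 * k))
        if sd_a == 0:
            break
        bound = sd_a * math.sqrt(2.0) * stats.norm.ppf(1 - alpha / (2 * k))
        worst = int(np.argmax(np.abs(d)))
        if abs(d[worst]) > bound:
            sid, visit, _ = current[worst]
            out.append((sid, visit))
            current = current[:worst] + current[worst + 1 :]
        else:
            break
    return out


def _reed_outliers(means: pd.Series) -> list[str]:
    """Subject means excluded by the Reed criterion (gap > range/3), iterated."""
    out: list[str] = []
    m = means.copy()
    while len(m) >= 3:
        s = m.sort_values()
        rng = s.iloc[-1] - s.iloc[0]
        if rng == 0:
            break
        if (s.iloc[-1] - s.iloc[-2]) > rng / 3.0:
            out.append(str(s.index[-1]))
            m = m.drop(s.index[-1])
        elif (s.iloc[1] - s.iloc[0]) > rng / 3.0:
            out.append(str(s.index[0]))
            m = m.drop(s.index[0])
        else:
            break
    return out


def outlier_cascade(
    data: pd.DataFrame,
    trend_alpha: float = 0.01,
    homogeneity_alpha: float = 0.05,
    homogeneity_test: str = "bartlett",
    log_transform: bool = True,
) -> tuple[pd.DataFrame, list[Exclusion]]:
    """Apply the four-level outlier cascade to a BV study table.

    Returns the cleaned table and the audit list of exclusions.  Input needs
    columns ``subject_id``, ``visit_index``, ``value`` and optionally
    ``replicate_index``.  The homogeneity step runs on (optionally
    log-transformed) within-subject residuals and iteratively removes the
    subject with the most extreme variance until the test no longer rejects.
    """
    if homogeneity_test not in ("bartlett", "cochran"):
        raise DataError(f"unknown homogeneity test {homogeneity_test!r}")
    df = _check_schema(data)
    exclusions: list[Exclusion] = []

    # 1 — analytical (needs replicates)
    has_reps = df.groupby(["subject_id", "visit_index"])["value"].size().max() >= 2
    if has_reps:
        for sid, visit in _burnett_outliers(df):
            mask = (df["subject_id"] == sid) & (df["visit_index"] == visit)
            df = df[~mask]
            exclusions.append(
                Exclusion("analytical", f"{sid}/visit{visit}",
                          "duplicate difference exceeds Burnett bound")
            )
    else:
        exclusions.append(
            Exclusion("note", "-", "no replicates: analytical outlier step skipped")
        )

    # 2 — participant mean (Reed)
    means = df.groupby("subject_id")["value"].mean()
    for sid in _reed_outliers(means):
        df = df[df["subject_id"] != sid]
        exclusions.append(
            Exclusion("mean", sid, "subject mean isolated by Reed criterion (gap > range/3)")
        )

    # 3 — individual linear trend over visits
    for sid, grp in df.groupby("subject_id", sort=True):
        per_visit = grp.groupby("visit_index")["value"].mean()
        if len(per_visit) < 4 or per_visit.std() == 0:
            continue
        res = stats.linregress(per_visit.index.to_numpy(float), per_visit.to_numpy())
        if res.pvalue < trend_alpha:
            df = df[df["subject_id"] != sid]
            exclusions.append(
                Exclusion("trend", str(sid),
                          f"significant linear drift (p={res.pvalue:.2e} < {trend_alpha})")
            )

    # 4 — homogeneity of within-subject variances
    def residual_groups(frame: pd.DataFrame) -> dict[str, np.ndarray]:
        groups = {}
        for sid, grp in frame.groupby("subject_id", sort=True):
            v = grp.groupby("visit_index")["value"].mean().to_numpy()
            if log_transform:
                v = np.log(v)
            if len(v) >= 3:
                groups[str(sid)] = v - v.mean()
        return groups

    while True:
        groups = residual_groups(df)
        if len(groups) < 3:
            break
        samples = list(groups.values())
        if homogeneity_test == "bartlett":
            if any(np.allclose(s, 0) for s in samples):
                break
            stat, p = stats.bartlett(*samples)
            reject = p < homogeneity_alpha
        else:
            variances = np.array([np.var(s, ddof=1) for s in samples])
            c = variances.max() / variances.sum()
            k, n = len(variances), len(samples[0])
            # Cochran's C critical value via the F relation
            fcrit = stats.f.ppf(1 - homogeneity_alpha / k, n - 1, (k - 1) * (n - 1))
            reject = c > fcrit / (fcrit + k - 1)
        if not reject:
            break
        variances = {sid: np.var(res, ddof=1) for sid, res in groups.items()}
        worst = max(variances, key=lambda s: variances[s])
        df = df[df["subject_id"] != worst]
        exclusions.append(
            Exclusion("homogeneity", worst,
                      "most extreme within-subject variance; removed to restore homogeneity")
        )

    if df["subject_id"].nunique() < 3:
        raise EstimationError(
            "outlier cascade left fewer than 3 subjects; cannot estimate variance components"
        )
    return df.reset_index(drop=True), exclusions


def _nested_mean_squares(df: pd.DataFrame) -> tuple[float, float, float, int, float, float]:
    """Mean squares of the subjects / visits / replicates nesting.

    Returns (MS_subject, MS_visit, MS_replicate, n_subjects, mean visits per
    subject, mean replicates per visit).  Requires near-balance.
    """
    counts = df.groupby(["subject_id", "visit_index"])["value"].size()
    reps = counts.to_numpy(float)
    visits = df.groupby("subject_id")["visit_index"].nunique().to_numpy(float)
    if reps.size and (reps.min() < 0.8 * reps.max() or visits.min() < 0.8 * visits.max()):
        raise DataError(
            "design is unbalanced beyond 20% missingness; nested ANOVA refused"
        )
    r = float(reps.mean())
    v = float(visits.mean())
    s = df["subject_id"].nunique()

    grand = df["value"].mean()
    subj_means = df.groupby("subject_id")["value"].mean()
    visit_means = df.groupby(["subject_id", "visit_index"])["value"].mean()

    ss_subj = float(((subj_means - grand) ** 2 * df.groupby("subject_id")["value"].size()).sum())
    vm = visit_means.reset_index()
    vm = vm.merge(subj_means.rename("subj_mean"), on="subject_id")
    nrep = counts.reset_index(name="n")["n"].to_numpy(float)
    ss_visit = float((((vm["value"] - vm["subj_mean"]) ** 2).to_numpy() * nrep).sum())
    merged = df.merge(visit_means.rename("visit_mean"), on=["subject_id", "visit_index"])
    ss_rep = float(((merged["value"] - merged["visit_mean"]) ** 2).sum())

    df_subj = s - 1
    df_visit = int(round(s * (v - 1)))
    df_rep = int(round(s * v * (r - 1)))
    ms_subj = ss_subj / df_subj if df_subj > 0 else 0.0
    ms_visit = ss_visit / df_visit if df_visit > 0 else 0.0
    ms_rep = ss_rep / df_rep if df_rep > 0 else 0.0
    return ms_subj, ms_visit, ms_rep, s, v, r


def nested_anova_cv(
    cleaned: pd.DataFrame,
    mode: str = "cv_anova",
    cv_a_pct: float | None = None,
    mu_pop_original: float | None = None,
    exclusions: list[Exclusion] | None = None,
) -> tuple[VarianceComponents, BVEstimates]:
    """Variance components and CVs from a cleaned, near-balanced BV table.

    ``cv_anova`` scales every result by its subject mean so that within-level
    variance components read directly as squared CV fractions; ``ln_anova``
    works on natural-log values and converts components with
    ``CV = sqrt(exp(sigma^2) - 1)``.  The analytical component comes from
    replicates when present, otherwise from the supplied quality-control
    ``cv_a_pct``; the within-subject CV is always reported net of the
    analytical CV.
    """
    if mode not in ("cv_anova", "ln_anova"):
        raise DataError(f"unknown ANOVA mode {mode!r}")
    df = _check_schema(cleaned)
    has_reps = df.groupby(["subject_id", "visit_index"])["value"].size().max() >= 2

    if mode == "ln_anova":
        work = df.assign(value=np.log(df["value"]))
    else:
        subj_means = df.groupby("subject_id")["value"].transform("mean")
        work = df.assign(value=df["value"] / subj_means)

    ms_subj, ms_visit, ms_rep, s, v, r = _nested_mean_squares(work)

    if has_reps:
        var_a = ms_rep
        var_wi_total = max((ms_visit - ms_rep) / r, 0.0) + var_a  # sigma_I^2 + sigma_A^2
    else:
        var_a = 0.0
        var_wi_total = ms_visit  # replicate level absent: visit MS = sigma_I^2 + sigma_A^2

    trunc_notes: list[Exclusion] = []

    if mode == "ln_anova":
        var_between = (ms_subj - ms_visit) / (r * v)
        if var_between < 0:
            trunc_notes.append(
                Exclusion("note", "-", "negative between-subject component truncated to 0")
            )
            warnings.warn("negative between-subject variance truncated to 0", stacklevel=2)
            var_between = 0.0

        def to_cv(var: float) -> float:
            return 100.0 * math.sqrt(math.expm1(var))
    else:
        # subject-mean scaling removes between-subject spread; recover it from
        # the raw subject means on the relative scale
        raw_means = df.groupby("subject_id")["value"].mean()
        grand = float(raw_means.mean())
        var_means_rel = float(raw_means.var(ddof=1)) / grand**2
        var_between = var_means_rel - var_wi_total / (v * r)
        if var_between < 0:
            trunc_notes.append(
                Exclusion("note", "-", "negative between-subject component truncated to 0")
            )
            warnings.warn("negative between-subject variance truncated to 0", stacklevel=2)
            var_between = 0.0

        def to_cv(var: float) -> float:
            return 100.0 * math.sqrt(var)

    if has_reps:
        cv_a = to_cv(var_a)
    elif cv_a_pct is not None:
        cv_a = float(cv_a_pct)
    else:
        cv_a = 0.0
    cv_within_total = to_cv(var_wi_total)
    cv_i_sq = cv_within_total**2 - cv_a**2
    if cv_i_sq < 0:
        trunc_notes.append(
            Exclusion("note", "-", "analytical CV exceeds total within-subject CV; CV_I set to 0")
        )
        cv_i_sq = 0.0
    cv_i = math.sqrt(cv_i_sq)
    cv_g = to_cv(var_between)

    all_excl = tuple(exclusions or []) + tuple(trunc_notes)
    components = VarianceComponents(
        var_analytical=var_a,
        var_within=max(var_wi_total - var_a, 0.0),
        var_between=var_between,
        n_subjects_used=s,
        exclusions=all_excl,
    )
    mu = float(mu_pop_original) if mu_pop_original is not None else float(df["value"].mean())
    estimates = BVEstimates(
        cv_i_pct=cv_i, cv_g_pct=cv_g, cv_a_pct=cv_a, mu_pop_original=mu
    )
    return components, estimates


def bv_to_peb(bv: BVEstimates, analyte_label: str = "", subgroup_label: str = "") -> PEBParameters:
    """Convert biological-variation CVs to log-scale PEB parameters.

    ``sigma_I^2 = ln(1 + (CV_I^2 + CV_A^2)/10^4)`` (analytical noise folded
    into the within-subject component, as it is in routine results),
    ``sigma_G^2 = ln(1 + CV_G^2/10^4)``, ``B_1 = sigma_G^2 / (sigma_G^2 +
    sigma_I^2)``, and the population mean moves to the log scale.
    """
    var_i = math.log1p((bv.cv_i_pct**2 + bv.cv_a_pct**2) / 1e4)
    var_g = math.log1p(bv.cv_g_pct**2 / 1e4)
    total = var_g + var_i
    if total <= 0:
        raise DomainError("all coefficients of variation are zero; no model exists")
    return PEBParameters(
        mu_pop=math.log(bv.mu_pop_original),
        sigma_pop=math.sqrt(total),
        b1=var_g / total,
        scale="log",
        analyte_label=analyte_label,
        subgroup_label=subgroup_label,
    )
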