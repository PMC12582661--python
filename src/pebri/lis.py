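"""Estimation of PEB parameters from routine laboratory (LIS-style) data.

The pipeline mirrors how a laboratory would mine its own archive:

1. keep results above the reporting limit and (optionally) inside the
   morning collection window;
2. fit a Box-Cox-normal *central peak* to each patient's first result —
   an indirect reference-interval fit that is robust to a pathological
   minority — giving ``lambda``, ``mu_pop`` and ``sigma_pop``;
3. drop results outside the central 99% of that fitted distribution;
4. form sequential result pairs separated by more than 24 h;
5. robust-regress the later member of each pair on the earlier one; the
   slope is the intraclass correlation ``B_1``.

The central-peak fit here is a self-contained grid-search estimator: for each
candidate Box-Cox exponent the transformed data's central bulk is located by
iterated truncated moments, and the exponent is chosen to make that bulk look
most like a (truncated) normal, measured by a Cramer-von-Mises distance of
the probability-integral transform from uniformity.  Location and scale come
from the truncated moments, bias-corrected for the truncation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, EstimationError
from .model import PEBParameters, boxcox, boxcox_inverse
from .series import SubjectSeries

__all__ = [
    "PopulationFit",
    "ResultPair",
    "RobustSlopeFit",
    "fit_population",
    "central99_filter",
    "build_pairs",
    "robust_slope",
    "lis_pipeline",
]

#: z covering the central 99% of a normal distribution
Z_99 = 2.5758
#: half-width, in fitted SDs, of the truncation window used by the central-peak fit
_TRUNC_A = 2.0
#: Tukey bisquare tuning constant for 95% Gaussian efficiency
_TUKEY_C = 4.685


@dataclass(frozen=True)
class PopulationFit:
    """Box-Cox-normal central-peak fit to first-per-patient results."""

    mu_pop: float
    sigma_pop: float
    lambda_: float
    n_used: int

    @property
    def central99_bounds(self) -> tuple[float, float]:
        """Working-scale window containing the central 99% of the fitted normal."""
        return (self.mu_pop - Z_99 * self.sigma_pop, self.mu_pop + Z_99 * self.sigma_pop)


@dataclass(frozen=True)
class ResultPair:
    """Two consecutive results of one subject, more than ``min_gap`` apart."""

    subject_id: str
    x_prev: float
    x_next: float
    gap_hours: float


@dataclass(frozen=True)
class RobustSlopeFit:
    """Robust regression of each result on its predecessor; slope estimates B_1."""

    slope: float
    intercept: float
    n_pairs: int
    ci95: tuple[float, float] | None
    converged: bool
    weights_min: float
    weights_median: float


def _trunc_var_factor(a: float) -> float:
    """Variance of a standard normal truncated to [-a, a]."""
    mass = 2.0 * stats.norm.cdf(a) - 1.0
    return 1.0 - 2.0 * a * stats.norm.pdf(a) / mass


def _truncated_moments(t: np.ndarray, a: float = _TRUNC_A, iters: int = 25) -> tuple[float, float]:
    """Robust location/scale by iterated moments on the central window.

    Starts from median and MAD, then alternates between windowing at
    ``mu +/- a*sigma`` and re-estimating ``(mu, sigma)`` from the windowed
    points with the truncated-normal variance correction.
    """
    mu = float(np.median(t))
    mad = float(stats.median_abs_deviation(t, scale="normal"))
    if mad == 0.0:
        raise EstimationError("degenerate data: zero median absolute deviation")
    sigma = mad
    factor = math.sqrt(_trunc_var_factor(a))
    for _ in range(iters):
        inside = t[np.abs(t - mu) <= a * sigma]
        if inside.size < 10:
            break
        new_mu = float(np.mean(inside))
        new_sigma = float(np.std(inside)) / factor
        if new_sigma <= 0:
            break
        if abs(new_mu - mu) < 1e-10 * max(1.0, sigma) and abs(new_sigma - sigma) < 1e-10 * sigma:
            mu, sigma = new_mu, new_sigma
            break
        mu, sigma = new_mu, new_sigma
    return mu, sigma


def _central_misfit(t: np.ndarray, mu: float, sigma: float, a: float = _TRUNC_A) -> float:
    """Cramer-von-Mises distance from uniformity of the central bulk's PIT.

    Under a correct transform the points inside ``mu +/- a*sigma`` follow a
    truncated normal; their probability-integral transform should be uniform.
    """
    inside = np.sort(t[np.abs(t - mu) <= a * sigma])
    m = inside.size
    if m < 20:
        return np.inf
    lo, hi = stats.norm.cdf(-a), stats.norm.cdf(a)
    u = (stats.norm.cdf((inside - mu) / sigma) - lo) / (hi - lo)
    grid = (np.arange(1, m + 1) - 0.5) / m
    return float(np.mean((u - grid) ** 2))


def _robust_grid_fit(x: np.ndarray, lambda_grid: np.ndarray) -> tuple[float, float, float]:
    """Stage 0: robust grid search for the Box-Cox exponent.

    Picks the exponent whose transformed central bulk looks most like a
    truncated normal (Cramer-von-Mises misfit); location/scale come from the
    iterated truncated moments.  Coarse but highly resistant to a
    pathological minority — used only to place the central window.
    """

    def misfit_at(lam: float) -> tuple[float, float, float]:
        t = boxcox(x, lam)
        try:
            mu, sigma = _truncated_moments(t)
        except EstimationError:
            return np.inf, np.nan, np.nan
        return _central_misfit(t, mu, sigma), mu, sigma

    scores = np.array([misfit_at(lam)[0] for lam in lambda_grid])
    if not np.isfinite(scores).any():
        raise EstimationError("central-peak fit failed for every candidate exponent")
    k = int(np.argmin(scores))
    _, mu, sigma = misfit_at(float(lambda_grid[k]))
    return float(lambda_grid[k]), mu, sigma


def _truncated_boxcox_nll(lam: float, xr: np.ndarray, lo: float, hi: float):
    """Profile negative log-likelihood of a Box-Cox normal truncated to [lo, hi].

    ``xr`` are the original-scale values inside the window; the inner (mu,
    sigma) maximization uses Nelder-Mead from the transformed moments.
    """
    t = boxcox(xr, lam)
    a, b = boxcox(lo, lam), boxcox(hi, lam)
    sum_log = float(np.sum(np.log(xr)))

    def nll(p):
        mu, log_sig = p
        sig = math.exp(log_sig)
        mass = stats.norm.cdf((b - mu) / sig) - stats.norm.cdf((a - mu) / sig)
        if mass <= 1e-12:
            return 1e12
        return -(
            float(np.sum(stats.norm.logpdf(t, mu, sig)))
            + (lam - 1.0) * sum_log
            - t.size * math.log(mass)
        )

    res = optimize.minimize(
        nll,
        [float(np.mean(t)), math.log(float(np.std(t)))],
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-7},
    )
    return float(res.fun), float(res.x[0]), math.exp(float(res.x[1]))


def fit_population(
    first_results: np.ndarray,
    lambda_grid: np.ndarray | None = None,
) -> PopulationFit:
    """Fit the Box-Cox-normal central peak of first-per-patient results.

    Two stages: a robust grid search locates the central bulk and a coarse
    exponent; a truncated maximum-likelihood fit over a *fixed* original-scale
    window (the central 99% of the stage-0 fit) then refines all three
    parameters coherently, with the Box-Cox Jacobian and the truncation mass
    in the likelihood.  Pathological results far from the bulk never enter
    the window and therefore cannot distort the fit.

    Intended for large extracts (>= 5000 values, pathological fraction below
    ~30%); refuses below 500 values.  The exponent is only weakly identified
    from the central bulk (its information sits in the tails this fit
    deliberately ignores), so (lambda, mu, sigma) trade off against each
    other; the implied original-scale distribution is pinned down much more
    tightly than the individual parameters.
    """
    x = np.asarray(first_results, dtype=float)
    if x.size < 500:
        raise DataError(
            f"central-peak fit needs at least 500 first results, got {x.size}"
        )
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise DataError("all first results must be finite and positive")
    if np.ptp(x) == 0:
        raise EstimationError("degenerate data: all first results identical")
    if x.size < 5000:
        warnings.warn(
            f"only {x.size} first results; the population fit is recommended "
            "for >= 5000 values",
            stacklevel=2,
        )
    if lambda_grid is None:
        lambda_grid = np.arange(-0.5, 2.5 + 1e-9, 0.05)

    lam0, mu0, sig0 = _robust_grid_fit(x, lambda_grid)

    lo = float(boxcox_inverse(mu0 - Z_99 * sig0, lam0))
    hi = float(boxcox_inverse(mu0 + Z_99 * sig0, lam0))
    xr = x[(x >= lo) & (x <= hi)]
    if xr.size < 100:
        raise EstimationError("fewer than 100 results inside the central window")
    res = optimize.minimize_scalar(
        lambda lam: _truncated_boxcox_nll(lam, xr, lo, hi)[0],
        bounds=(lam0 - 0.6, lam0 + 0.6),
        method="bounded",
        options={"xatol": 5e-4},
    )
    lam = float(res.x)
    _, mu, sigma = _truncated_boxcox_nll(lam, xr, lo, hi)
    if not np.isfinite(mu) or not np.isfinite(sigma) or sigma <= 0:
        raise EstimationError("central-peak fit did not converge")
    return PopulationFit(mu_pop=mu, sigma_pop=sigma, lambda_=lam, n_used=int(x.size))


def central99_filter(values: np.ndarray, fit: PopulationFit) -> np.ndarray:
    """Keep original-scale values whose transform falls in the central 99% window."""
    x = np.asarray(values, dtype=float)
    t = boxcox(x, fit.lambda_)
    lo, hi = fit.central99_bounds
    return x[(t >= lo) & (t <= hi)]


def build_pairs(
    series: list[SubjectSeries],
    min_gap_hours: float = 24.0,
) -> list[ResultPair]:
    """Sequential result pairs per subject with gap > ``min_gap_hours``.

    A subject with k results contributes up to k-1 overlapping pairs
    (1,2), (2,3), ...; a pair is kept only when its own gap exceeds the
    minimum.  Series must already be time-sorted (enforced by SubjectSeries).
    """
    pairs: list[ResultPair] = []
    for s in series:
        gaps = s.gaps_hours()
        for i, g in enumerate(gaps):
            if g > min_gap_hours:
                pairs.append(
                    ResultPair(
                        subject_id=s.subject_id,
                        x_prev=float(s.values[i]),
                        x_next=float(s.values[i + 1]),
                        gap_hours=float(g),
                    )
                )
    return pairs


def _lts_crit(x: np.ndarray, y: np.ndarray, a: float, b: float, h: int) -> float:
    r2 = (y - a - b * x) ** 2
    return float(np.mean(np.partition(r2, h - 1)[:h]))


def _bisquare_irls(
    x: np.ndarray,
    y: np.ndarray,
    start: tuple[float, float],
    scale: float,
    c: float = _TUKEY_C,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[float, float, np.ndarray, bool]:
    """Tukey-bisquare IRLS at a fixed robust residual scale (MM scheme)."""
    a, b = start
    X = np.column_stack([np.ones_like(x), x])
    converged = False
    w = np.ones_like(x)
    for _ in range(max_iter):
        r = (y - a - b * x) / (c * scale)
        w = np.where(np.abs(r) < 1.0, (1.0 - r**2) ** 2, 0.0)
        if w.sum() < 3 or np.ptp(x[w > 0]) == 0:
            return a, b, w, False
        wls = np.linalg.lstsq(X * np.sqrt(w)[:, None], y * np.sqrt(w), rcond=None)[0]
        a_new, b_new = float(wls[0]), float(wls[1])
        if abs(a_new - a) < tol and abs(b_new - b) < tol:
            a, b = a_new, b_new
            converged = True
            break
        a, b = a_new, b_new
    return a, b, w, converged


def _concentrate(
    x: np.ndarray, y: np.ndarray, a: float, b: float, h: int, n_steps: int = 10
) -> tuple[float, float]:
    """Least-trimmed-squares concentration: refit on the best-fitting half.

    Each step keeps the h points with the smallest residuals under the
    current line and refits by least squares; the trimmed criterion is
    non-increasing, so a handful of steps sharpens a crude high-breakdown
    start into a tight one.
    """
    for _ in range(n_steps):
        r2 = (y - a - b * x) ** 2
        keep = np.argpartition(r2, h - 1)[:h]
        if np.ptp(x[keep]) == 0:
            break
        b_new, a_new = np.polyfit(x[keep], y[keep], 1)
        if abs(a_new - a) < 1e-12 and abs(b_new - b) < 1e-12:
            break
        a, b = float(a_new), float(b_new)
    return a, b


def _lts_line(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
    n_candidates: int = 50, n_keep: int = 5,
) -> tuple[float, float, int]:
    """Fast least-trimmed-squares line: multi-start 2-point candidates.

    Every random 2-point line gets two concentration steps; the best few by
    trimmed criterion are concentrated to convergence and the overall winner
    returned.  Multi-start matters: with clustered contamination the trimmed
    criterion has competing local optima, and a single start can land in the
    wrong basin.
    """
    n = x.size
    h = n // 2 + 1
    candidates: list[tuple[float, float, float]] = []
    b_med = (float(np.median(y)), 0.0)
    candidates.append((_lts_crit(x, y, *b_med, h), *b_med))
    for _ in range(n_candidates):
        i, j = rng.choice(n, size=2, replace=False)
        if x[i] == x[j]:
            continue
        b0 = (y[j] - y[i]) / (x[j] - x[i])
        a0 = y[i] - b0 * x[i]
        a1, b1 = _concentrate(x, y, a0, b0, h, n_steps=2)
        candidates.append((_lts_crit(x, y, a1, b1, h), a1, b1))
    candidates.sort(key=lambda t: t[0])
    best = (np.inf, 0.0, 0.0)
    for _, a1, b1 in candidates[:n_keep]:
        a2, b2 = _concentrate(x, y, a1, b1, h)
        crit = _lts_crit(x, y, a2, b2, h)
        if crit < best[0]:
            best = (crit, a2, b2)
    return best[1], best[2], h


#: sd of a standard normal restricted to its central 50% mass
_LTS_CONSISTENCY = math.sqrt(
    1.0 - 2.0 * 0.6744897501960817 * stats.norm.pdf(0.6744897501960817) / 0.5
)


def _robust_line(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[float, float, np.ndarray, bool]:
    a0, b0, h = _lts_line(x, y, rng)

    def lts_scale(a: float, b: float) -> float:
        # residual scale from the best-fitting half, normal-consistent —
        # unlike a full-sample MAD it is not inflated by the contamination
        r2 = (y - a - b * x) ** 2
        s = math.sqrt(float(np.mean(np.partition(r2, h - 1)[:h]))) / _LTS_CONSISTENCY
        return s if s > 0 else max(float(np.std(y - a - b * x)), 1e-12)

    # rejection pass at an aggressive cutoff: tolerant of the moderate scale
    # over-estimate the trimmed criterion produces under contamination
    a, b, w, _ = _bisquare_irls(x, y, (a0, b0), lts_scale(a0, b0), c=3.0)
    # scale re-estimated from the surviving residuals, then the efficient pass
    kept = w > 0
    resid = y[kept] - a - b * x[kept]
    scale = float(stats.median_abs_deviation(resid, scale="normal"))
    if scale == 0:
        scale = lts_scale(a, b)
    return _bisquare_irls(x, y, (a, b), scale)


def robust_slope(
    pairs: list[ResultPair],
    n_boot: int = 1999,
    seed: int = 0,
    compute_ci: bool = True,
) -> RobustSlopeFit:
    """Iteratively reweighted robust regression of x_next on x_prev.

    An MM-type scheme: a high-breakdown least-median-of-squares line from
    2-point subsamples initializes the fit and fixes the residual scale
    (normalized MAD); Tukey-bisquare IRLS (tuning constant 4.685, max 200
    iterations, tolerance 1e-8 on the coefficients) then refines it.  Pairs
    with large residuals — on either axis — are smoothly down-weighted
    instead of excluded, so pathological pairs surviving the central-99%
    filter get little influence on the slope.

    The 95% CI is a percentile bootstrap that resamples *subjects* (not
    pairs), so the overlapping pairs contributed by one patient are kept
    together and within-subject dependence is respected.
    """
    if len(pairs) < 2:
        raise EstimationError(f"robust slope needs >= 2 pairs, got {len(pairs)}")
    if len(pairs) < 100:
        warnings.warn(
            f"only {len(pairs)} pairs; the slope estimate is recommended for >= 100",
            stacklevel=2,
        )
    x = np.array([p.x_prev for p in pairs])
    y = np.array([p.x_next for p in pairs])
    if np.ptp(x) == 0:
        raise EstimationError("degenerate pairs: baseline results have zero variance")

    rng = np.random.default_rng(seed)
    intercept, slope, w, converged = _robust_line(x, y, rng)

    ci = None
    if compute_ci and n_boot > 0:
        subjects = np.array([p.subject_id for p in pairs])
        unique = np.unique(subjects)
        groups = {s: np.flatnonzero(subjects == s) for s in unique}
        slopes = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.choice(unique, size=unique.size, replace=True)
            idx = np.concatenate([groups[s] for s in pick])
            if np.ptp(x[idx]) == 0:
                slopes[b] = np.nan
                continue
            slopes[b] = _robust_line(x[idx], y[idx], rng)[1]
        good = slopes[np.isfinite(slopes)]
        if good.size >= max(20, n_boot // 2):
            ci = (float(np.percentile(good, 2.5)), float(np.percentile(good, 97.5)))

    return RobustSlopeFit(
        slope=float(slope),
        intercept=float(intercept),
        n_pairs=len(pairs),
        ci95=ci,
        converged=bool(converged),
        weights_min=float(np.min(w)),
        weights_median=float(np.median(w)),
    )


def lis_pipeline(
    raw: pd.DataFrame,
    min_gap_hours: float = 24.0,
    reporting_limit: float | None = None,
    diurnal_window: tuple[float, float] | None = None,
    n_boot: int = 1999,
    seed: int = 0,
    analyte_label: str = "",
    subgroup_label: str = "",
) -> tuple[PEBParameters, dict]:
    """Full LIS estimation: filters -> population fit -> pairs -> robust slope.

    ``raw`` must have columns ``subject_id``, ``timestamp``, ``value``.
    Returns the fitted parameters (Box-Cox working scale) and an audit dict
    with the record count surviving each stage.
    """
    from .io import frame_to_series, validate_schema  # local import avoids a cycle

    validate_schema(raw)
    audit: dict[str, object] = {"n_input": int(len(raw))}
    df = raw.copy()
    if df.empty:
        raise DataError("empty input table")

    if reporting_limit is not None:
        kept = df["value"] >= reporting_limit
        audit["n_below_reporting_limit"] = int((~kept).sum())
        df = df[kept]
    if diurnal_window is not None:
        hours = pd.to_datetime(df["timestamp"]).dt.hour + pd.to_datetime(df["timestamp"]).dt.minute / 60.0
        kept = (hours >= diurnal_window[0]) & (hours < diurnal_window[1])
        audit["n_outside_diurnal_window"] = int((~kept).sum())
        df = df[kept]
    audit["n_after_filters"] = int(len(df))
    if df.empty:
        raise DataError("no results remain after reporting-limit/diurnal filters")

    series = frame_to_series(df)
    firsts = np.array([s.values[0] for s in series])
    fit = fit_population(firsts)
    audit["n_first_results"] = int(firsts.size)
    audit["lambda"] = fit.lambda_

    # central-99% filter on every retained result, then transform
    lo, hi = fit.central99_bounds
    filtered: list[SubjectSeries] = []
    n_all = n_kept = 0
    for s in series:
        t = boxcox(s.values, fit.lambda_)
        keep = (t >= lo) & (t <= hi)
        n_all += len(s)
        n_kept += int(keep.sum())
        if keep.sum() >= 1:
            filtered.append(
                SubjectSeries(
                    subject_id=s.subject_id,
                    timestamps=[ts for ts, k in zip(s.timestamps, keep) if k],
                    values=t[keep],
                    subgroup=s.subgroup,
                )
            )
    audit["n_results_total"] = n_all
    audit["n_outside_central99"] = n_all - n_kept
    audit["n_after_central99"] = n_kept

    pairs = build_pairs(filtered, min_gap_hours=min_gap_hours)
    audit["n_pairs"] = len(pairs)
    if not pairs:
        raise EstimationError(
            "no sequential result pairs with sufficient spacing exist; "
            "B_1 cannot be estimated (population fit alone: "
            f"mu={fit.mu_pop:.4g}, sigma={fit.sigma_pop:.4g}, lambda={fit.lambda_:.3g})"
        )
    slope_fit = robust_slope(pairs, n_boot=n_boot, seed=seed)
    audit["slope"] = slope_fit.slope
    audit["slope_ci95"] = slope_fit.ci95
    audit["converged"] = slope_fit.converged

    params = PEBParameters(
        mu_pop=fit.mu_pop,
        sigma_pop=fit.sigma_pop,
        b1=slope_fit.slope,
        scale="boxcox",
        lambda_=fit.lambda_,
        analyte_label=analyte_label,
        subgroup_label=subgroup_label,
    )
    return params, audit
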