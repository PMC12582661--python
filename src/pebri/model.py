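"""Closed-form parametric empirical Bayes (PEB) mathematics.

The PEB framework assumes that, after a normalizing transformation, serial
results of a healthy individual follow a two-level hierarchical normal model:
the individual's homeostatic set point ``mu_I`` is drawn from
``N(mu_pop, sigma_G^2)`` and each result from ``N(mu_I, sigma_I^2)``.  The
posterior set point is a shrinkage compromise between the observed individual
mean and the population mean; the prediction interval for the next result
contracts smoothly from the population reference interval (no prior results)
toward a fully personalized interval (many prior results).

All threshold arithmetic in this module happens on the *working* scale
(Box-Cox or natural log); only final interval limits are mapped back to the
original measurement scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import special

from .errors import DomainError

__all__ = [
    "PEBParameters",
    "ThresholdDecision",
    "shrinkage_factor",
    "posterior_mean",
    "prediction_halfwidth",
    "peb_threshold",
    "boxcox",
    "boxcox_inverse",
    "classic_rcv_interval",
]

#: Default two-sided 95% z-score.
DEFAULT_Z = 1.96


def _as_int_n(n) -> int:
    if isinstance(n, bool) or (not isinstance(n, (int, np.integer)) and float(n) != int(n)):
        raise DomainError(f"n must be a non-negative integer, got {n!r}")
    n = int(n)
    if n < 0:
        raise DomainError(f"n must be a non-negative integer, got {n}")
    return n


@dataclass(frozen=True)
class PEBParameters:
    """Population parameters driving every PEB threshold.

    Parameters
    ----------
    mu_pop : float
        Population mean on the working scale.
    sigma_pop : float
        Population SD on the working scale, ``sqrt(sigma_G^2 + sigma_I^2)``.
    b1 : float
        Intraclass correlation ``sigma_G^2 / (sigma_G^2 + sigma_I^2)``;
        the regression slope of one result on the previous one.  Values
        slightly outside [0, 1] (noisy estimation) are clipped with a warning.
    scale : {"boxcox", "log"}
        Working scale of ``mu_pop`` / ``sigma_pop``.
    lambda_ : float, optional
        Box-Cox exponent; required iff ``scale == "boxcox"``.
    """

    mu_pop: float
    sigma_pop: float
    b1: float
    scale: str = "log"
    lambda_: float | None = None
    analyte_label: str = ""
    subgroup_label: str = ""

    _CLIP_TOL = 0.05  # how far outside [0,1] b1 may stray before it is an error

    def __post_init__(self) -> None:
        if self.sigma_pop <= 0:
            raise DomainError(f"sigma_pop must be > 0, got {self.sigma_pop}")
        if self.scale not in ("boxcox", "log"):
            raise DomainError(f"scale must be 'boxcox' or 'log', got {self.scale!r}")
        if self.scale == "boxcox" and self.lambda_ is None:
            raise DomainError("lambda_ is required when scale='boxcox'")
        b1 = float(self.b1)
        if not -self._CLIP_TOL <= b1 <= 1 + self._CLIP_TOL:
            raise DomainError(f"b1 must lie in [0, 1], got {b1}")
        if not 0.0 <= b1 <= 1.0:
            clipped = min(max(b1, 0.0), 1.0)
            warnings.warn(
                f"b1={b1:.4f} outside [0, 1]; clipped to {clipped:.1f} "
                "(noisy slope estimate)",
                stacklevel=3,
            )
            object.__setattr__(self, "b1", clipped)

    @property
    def var_between(self) -> float:
        """Between-subject variance sigma_G^2 on the working scale."""
        return self.b1 * self.sigma_pop**2

    @property
    def var_within(self) -> float:
        """Within-subject variance sigma_I^2 (incl. analytical) on the working scale."""
        return (1.0 - self.b1) * self.sigma_pop**2

    @property
    def sigma_within(self) -> float:
        return math.sqrt(self.var_within)

    # -- scale transforms ---------------------------------------------------

    def to_working(self, x):
        """Map original-scale values to the working scale."""
        if self.scale == "log":
            return boxcox(x, 0.0)
        return boxcox(x, self.lambda_)

    def to_original(self, t):
        """Map working-scale values back to the original scale."""
        lam = 0.0 if self.scale == "log" else self.lambda_
        return boxcox_inverse(t, lam)

    def with_labels(self, analyte: str = "", subgroup: str = "") -> "PEBParameters":
        return replace(self, analyte_label=analyte, subgroup_label=subgroup)


@dataclass(frozen=True)
class ThresholdDecision:
    """Judgement of one new result against a PEB prediction interval.

    ``lower``/``upper`` are on the original scale; ``y_hat`` is the posterior
    set point on the working scale.  ``x_next_original`` and ``flagged`` are
    ``None`` for an interval that has not yet been applied to a result.
    """

    y_hat: float
    n_prior: int
    b_n: float
    lower: float
    upper: float
    z: float
    x_next_original: float | None = None
    flagged: bool | None = None

    def __post_init__(self) -> None:
        # equality occurs only in the degenerate zero-variance limits
        if self.lower > self.upper:
            raise DomainError(
                f"interval limits must be ordered: lower={self.lower}, upper={self.upper}"
            )

    def evaluate(self, x_next_original: float) -> "ThresholdDecision":
        """Return a copy with the flag for ``x_next_original``.

        A result exactly on a limit is *not* flagged (strict inequality).
        """
        flagged = bool(
            x_next_original < self.lower or x_next_original > self.upper
        )
        return replace(self, x_next_original=float(x_next_original), flagged=flagged)


def shrinkage_factor(b1: float, n) -> float:
    """Shrinkage weight ``B_n`` on the individual mean after ``n`` prior results.

    ``B_n = B_1 * n / (B_1 * n + (1 - B_1))`` — zero at ``n = 0`` (no prior
    information, the posterior set point is the population mean), equal to the
    intraclass correlation ``B_1`` at ``n = 1``, and increasing toward 1 as
    results accumulate.
    """
    b1 = float(b1)
    if not 0.0 <= b1 <= 1.0:
        raise DomainError(f"b1 must lie in [0, 1], got {b1}")
    n = _as_int_n(n)
    if n == 0:
        return 0.0
    if b1 == 1.0:
        return 1.0
    return b1 * n / (b1 * n + (1.0 - b1))


def posterior_mean(x_bar: float | None, params: PEBParameters, n) -> float:
    """Posterior (shrunken) set point ``Y_hat`` on the working scale.

    ``Y_hat = mu_pop + (x_bar - mu_pop) * B_n`` — a weighted average of the
    individual mean of the ``n`` prior results and the population mean.
    ``x_bar`` may be omitted when ``n = 0``.
    """
    n = _as_int_n(n)
    if n == 0:
        return float(params.mu_pop)
    if x_bar is None:
        raise DomainError("x_bar is required when n > 0")
    b_n = shrinkage_factor(params.b1, n)
    return float(params.mu_pop + (float(x_bar) - params.mu_pop) * b_n)


def prediction_halfwidth(params: PEBParameters, n, z: float = DEFAULT_Z) -> float:
    """Half-width ``Z * sqrt(1 - B_1 * B_n) * sigma_pop`` on the working scale.

    At ``n = 0`` this is the population interval half-width ``Z * sigma_pop``;
    as ``n`` grows it contracts monotonically toward ``Z * sigma_I``.
    """
    z = float(z)
    if z <= 0:
        raise DomainError(f"z must be > 0, got {z}")
    b_n = shrinkage_factor(params.b1, n)
    return z * math.sqrt(1.0 - params.b1 * b_n) * params.sigma_pop


def peb_threshold(
    history: Sequence[float],
    params: PEBParameters,
    n_use: int | None = None,
    z: float = DEFAULT_Z,
) -> ThresholdDecision:
    """Prediction interval for the next result, given prior original-scale results.

    The baseline mean uses the ``n_use`` most recent prior results, equally
    weighted (``n_use=None`` uses the full history).  History values are
    transformed to the working scale, the posterior set point and the interval
    ``Y_hat +/- halfwidth`` are computed there, and only the limits are
    back-transformed to the original scale.

    With ``n_use = 0`` the interval is the population reference interval,
    identical for every subject.
    """
    history = list(history)
    if n_use is None:
        n_use = len(history)
    n_use = _as_int_n(n_use)
    if len(history) < n_use:
        raise DomainError(
            f"history has {len(history)} results but n_use={n_use} were requested"
        )
    if n_use == 0:
        y_hat = posterior_mean(None, params, 0)
    else:
        recent = np.asarray(history[-n_use:], dtype=float)
        t = params.to_working(recent)
        y_hat = posterior_mean(float(np.mean(t)), params, n_use)
    hw = prediction_halfwidth(params, n_use, z)
    lower = float(params.to_original(y_hat - hw))
    upper = float(params.to_original(y_hat + hw))
    return ThresholdDecision(
        y_hat=y_hat,
        n_prior=n_use,
        b_n=shrinkage_factor(params.b1, n_use),
        lower=lower,
        upper=upper,
        z=float(z),
    )


def boxcox(value, lambda_: float):
    """Box-Cox transform ``(x^lam - 1)/lam`` (``ln x`` at ``lam = 0``).

    Accepts scalars or arrays of strictly positive values.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        bad = arr[~(np.isfinite(arr) & (arr > 0))].flat[0]
        raise DomainError(f"Box-Cox requires finite positive values, got {bad}")
    out = special.boxcox(arr, float(lambda_))
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out

def boxcox_inverse(t, lambda_: float):
    """Inverse Box-Cox transform; ``t`` must lie in the image of the forward map."""
    arr = np.asarray(t, dtype=float)
    lam = float(lambda_)
    if lam != 0.0 and np.any(1.0 + lam * arr <= 0):
        bad = arr[(1.0 + lam * arr) <= 0].flat[0]
        raise DomainError(
            f"value {bad} is outside the image of the Box-Cox transform (lambda={lam})"
        )
    out = special.inv_boxcox(arr, lam)
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def classic_rcv_interval(
    cv_i_pct: float,
    cv_a_pct: float,
    x_baseline: float,
    z: float = DEFAULT_Z,
) -> tuple[float, float]:
    """Conventional lognormal reference change value limits around a baseline.

    The significant-change band for a new result relative to ``x_baseline``
    is symmetric on the log scale: ``x_baseline * exp(+/- z*sqrt(2)*sigma_ln)``
    with ``sigma_ln^2 = ln(1 + (CV_I^2 + CV_A^2)/100^2)``.  The upper/lower
    ratio is independent of the baseline.  Unlike the PEB interval, this
    band is centered on the baseline itself and does not correct for
    regression toward the population mean.
    """
    if cv_i_pct < 0 or cv_a_pct < 0:
        raise DomainError("coefficients of variation must be non-negative")
    if x_baseline <= 0:
        raise DomainError(f"baseline must be positive, got {x_baseline}")
    if z <= 0:
        raise DomainError(f"z must be > 0, got {z}")
    sigma_ln = math.sqrt(math.log1p((cv_i_pct**2 + cv_a_pct**2) / 100.0**2))
    half = z * math.sqrt(2.0) * sigma_ln
    return (x_baseline * math.exp(-half), x_baseline * math.exp(half))
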