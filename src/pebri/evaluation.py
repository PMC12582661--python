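"""Flagging of serial results under population, pair-wise and personalized thresholds.

Five threshold families are compared on the same serial results:

- ``ri_pop`` — the static population interval (the PEB n = 0 case);
- ``rcv_pair`` — the PEB result-pair threshold (n = 1, baseline = previous
  result), the regression-corrected analogue of a reference change value;
- ``ri_per_dynamic`` — the personalized interval with n incrementing per
  result, so the baseline mean accumulates the subject's prior results;
- ``rcv_ln_formula`` — the conventional lognormal RCV built from CV_I and
  CV_A, centered on the previous result;
- ``rcv_ratio`` — an empirical band of result ratios estimated from a
  calibration set of repeat measurements.

A well-calibrated two-sided 95% threshold should flag about 5% of results
from subjects who actually follow the assumed hierarchical model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DomainError
from .lis import ResultPair
from .model import (
    DEFAULT_Z,
    PEBParameters,
    ThresholdDecision,
    classic_rcv_interval,
    peb_threshold,
)
from .series import SubjectSeries
from .bv import BVEstimates

__all__ = [
    "MODES",
    "FlaggingReport",
    "flag_series",
    "flagging_summary",
    "rcv_ratio_interval",
    "compare_methods",
]

MODES = ("ri_pop", "rcv_pair", "ri_per_dynamic", "rcv_ln_formula", "rcv_ratio")


@dataclass(frozen=True)
class FlaggingReport:
    """Cohort-level flag counts for one threshold family."""

    mode: str
    n_evaluated: int
    n_flagged: int
    per_subject: tuple[tuple[str, int], ...]

    @property
    def proportion_pct(self) -> float:
        if self.n_evaluated == 0:
            return float("nan")
        return 100.0 * self.n_flagged / self.n_evaluated


def flag_series(
    series: SubjectSeries,
    params: PEBParameters | None,
    mode: str,
    z: float = DEFAULT_Z,
    bv: BVEstimates | None = None,
    ratio_band: tuple[float, float] | None = None,
) -> list[ThresholdDecision]:
    """Judge each evaluable result of one subject under the chosen mode.

    ``ri_pop`` evaluates every result against the fixed population interval;
    ``rcv_pair`` evaluates result i against a baseline of result i-1 only;
    ``ri_per_dynamic`` evaluates result i with all i-1 prior results as the
    baseline (the first result is the n = 0 population case, so every result
    is evaluable).  The comparison modes need ``bv`` (lognormal formula) or
    ``ratio_band`` (empirical ratio interval) instead of PEB parameters.
    """
    if mode not in MODES:
        raise DataError(f"unknown mode {mode!r}; expected one of {MODES}")
    values = series.values
    decisions: list[ThresholdDecision] = []

    if mode in ("ri_pop", "rcv_pair", "ri_per_dynamic"):
        if params is None:
            raise DataError(f"mode {mode!r} requires PEB parameters")
        for i, x in enumerate(values):
            if mode == "ri_pop":
                interval = peb_threshold([], params, n_use=0, z=z)
            elif mode == "rcv_pair":
                if i == 0:
                    continue
                interval = peb_threshold([values[i - 1]], params, n_use=1, z=z)
            else:
                interval = peb_threshold(values[:i], params, n_use=i, z=z)
            decisions.append(interval.evaluate(float(x)))
        return decisions

    if mode == "rcv_ln_formula":
        if bv is None:
            raise DataError("mode 'rcv_ln_formula' requires BV estimates")
        for i in range(1, len(values)):
            lower, upper = classic_rcv_interval(
                bv.cv_i_pct, bv.cv_a_pct, float(values[i - 1]), z=z
            )
            if not lower < upper:  # zero-variation degenerate band
                flagged = bool(values[i] != values[i - 1])
                decisions.append(
                    ThresholdDecision(
                        y_hat=float(np.log(values[i - 1])), n_prior=1, b_n=1.0,
                        lower=lower, upper=lower * (1 + 1e-12), z=z,
                        x_next_original=float(values[i]), flagged=flagged,
                    )
                )
                continue
            dec = ThresholdDecision(
                y_hat=float(np.log(values[i - 1])), n_prior=1, b_n=1.0,
                lower=lower, upper=upper, z=z,
            )
            decisions.append(dec.evaluate(float(values[i])))
        return decisions

    # rcv_ratio
    if ratio_band is None:
        raise DataError("mode 'rcv_ratio' requires a calibrated ratio band")
    lo, hi = ratio_band
    for i in range(1, len(values)):
        baseline = float(values[i - 1])
        if baseline <= 0:
            raise DomainError("ratio threshold requires positive baselines")
        dec = ThresholdDecision(
            y_hat=float(np.log(baseline)), n_prior=1, b_n=1.0,
            lower=baseline * lo, upper=baseline * hi, z=z,
        )
        decisions.append(dec.evaluate(float(values[i])))
    return decisions


def flagging_summary(
    cohort: list[SubjectSeries],
    params: PEBParameters | None,
    mode: str,
    z: float = DEFAULT_Z,
    bv: BVEstimates | None = None,
    ratio_band: tuple[float, float] | None = None,
) -> FlaggingReport:
    """Aggregate per-result flags over a cohort into one report."""
    if not cohort:
        raise DataError("empty cohort")
    n_eval = n_flag = 0
    per_subject: list[tuple[str, int]] = []
    for series in cohort:
        decisions = flag_series(series, params, mode, z=z, bv=bv, ratio_band=ratio_band)
        flags = sum(1 for d in decisions if d.flagged)
        n_eval += len(decisions)
        n_flag += flags
        per_subject.append((series.subject_id, flags))
    return FlaggingReport(
        mode=mode, n_evaluated=n_eval, n_flagged=n_flag, per_subject=tuple(per_subject)
    )


def rcv_ratio_interval(
    pairs: list[ResultPair],
    coverage: float = 0.95,
) -> tuple[float, float]:
    """Empirical central band of result ratios from repeat measurements.

    Returns the (2.5th, 97.5th) percentiles (for the default coverage) of
    ``x_next / x_prev`` over a calibration pair set; a new pair is flagged
    when its ratio leaves the band.  The band is scale-invariant.
    """
    if not pairs:
        raise DataError("no pairs supplied")
    if len(pairs) < 200:
        import warnings

        warnings.warn(
            f"only {len(pairs)} calibration pairs; >= 200 recommended", stacklevel=2
        )
    prev = np.array([p.x_prev for p in pairs])
    nxt = np.array([p.x_next for p in pairs])
    if np.any(prev <= 0) or np.any(nxt <= 0):
        raise DomainError("ratio interval requires strictly positive results")
    ratios = nxt / prev
    tail = 100.0 * (1.0 - coverage) / 2.0
    return (
        float(np.percentile(ratios, tail)),
        float(np.percentile(ratios, 100.0 - tail)),
    )


def compare_methods(
    cohort: list[SubjectSeries],
    params: PEBParameters,
    bv: BVEstimates,
    z: float = DEFAULT_Z,
    ratio_calibration: list[ResultPair] | None = None,
) -> dict[str, FlaggingReport]:
    """One flagging report per threshold family, on the same serial results.

    The ratio band is calibrated once, from ``ratio_calibration`` when given,
    otherwise from the consecutive pairs of the evaluation cohort itself.
    """
    if ratio_calibration is None:
        from .lis import build_pairs

        ratio_calibration = build_pairs(cohort, min_gap_hours=0.0)
    band = rcv_ratio_interval(ratio_calibration)
    out: dict[str, FlaggingReport] = {}
    for mode in MODES:
        out[mode] = flagging_summary(
            cohort, params, mode, z=z, bv=bv, ratio_band=band
        )
    return out
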