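"""Series-with-band figures: one subject's results against the dynamic interval."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import flag_series
from .model import DEFAULT_Z, PEBParameters
from .series import SubjectSeries

__all__ = ["plot_series_with_bands"]


def plot_series_with_bands(
    series: SubjectSeries,
    params: PEBParameters,
    mode: str = "ri_per_dynamic",
    z: float = DEFAULT_Z,
    ax=None,
):
    """Plot a subject's serial results with the shaded prediction band.

    Flagged results are marked with open diamonds; the band is the
    original-scale interval the mode produces for each successive result.
    """
    decisions = flag_series(series, params, mode, z=z)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    offset = len(series) - len(decisions)
    idx = list(range(offset, len(series)))
    lows = [d.lower for d in decisions]
    ups = [d.upper for d in decisions]
    ax.fill_between(idx, lows, ups, alpha=0.25, step="mid", label=f"{mode} band")
    ax.plot(range(len(series)), series.values, "o-", ms=4, label="results")
    flagged = [i for i, d in zip(idx, decisions) if d.flagged]
    if flagged:
        ax.plot(
            flagged,
            [series.values[i] for i in flagged],
            "D",
            mfc="none",
            ms=10,
            label="flagged",
        )
    ax.set_xlabel("result index")
    ax.set_ylabel(params.analyte_label or "value")
    ax.set_title(f"subject {series.subject_id}")
    ax.legend(loc="best", fontsize=8)
    return ax
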