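"""Per-subject serial-result container shared by the estimation and evaluation layers."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np

from .errors import DataError

__all__ = ["SubjectSeries"]


@dataclass
class SubjectSeries:
    """One subject's time-ordered results on the original measurement scale."""

    subject_id: str
    timestamps: Sequence[datetime]
    values: np.ndarray
    subgroup: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise DataError(
                f"subject {self.subject_id}: {len(self.timestamps)} timestamps "
                f"but {len(self.values)} values"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError(f"subject {self.subject_id}: non-finite value present")
        for a, b in zip(self.timestamps, self.timestamps[1:]):
            if b <= a:
                raise DataError(
                    f"subject {self.subject_id}: timestamps not strictly increasing "
                    f"({a} followed by {b}); refusing to sort silently"
                )

    def __len__(self) -> int:
        return len(self.values)

    def gaps_hours(self) -> np.ndarray:
        """Hours between consecutive collections."""
        return np.array(
            [(b - a).total_seconds() / 3600.0 for a, b in zip(self.timestamps, self.timestamps[1:])]
        )
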