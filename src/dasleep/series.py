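"""Per-subject epoch-level actigraphy records.

The atomic data unit throughout the package is one night of wrist-worn
actigraphy summarised as activity counts, one scalar per fixed scoring
epoch (30 s by default), optionally paired with epoch-level sleep/wake
ground truth from polysomnography.  Sleep is coded 1 and wake 0
everywhere; a "hypnogram" is simply such a binary integer array.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

WAKE = 0
SLEEP = 1

DEFAULT_START = "2024-01-01T22:00:00"


def as_hypnogram(labels) -> np.ndarray:
    """Coerce a label sequence to a validated int8 sleep/wake array."""
    arr = np.asarray(labels)
    if arr.size and not np.isin(arr, (WAKE, SLEEP)).all():
        raise ValueError("hypnogram labels must be binary (0=wake, 1=sleep)")
    return arr.astype(np.int8)


@dataclass
class EpochSeries:
    """One subject's activity-count record.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    domain : str
        Device/count-type domain tag (e.g. ``"source"`` / ``"target"``).
    counts : ndarray
        Nonnegative activity counts, one per epoch.
    labels : ndarray or None
        Optional sleep/wake ground truth, same length as ``counts``.
    epoch_len : float
        Epoch duration in seconds (default 30).
    start_time : str
        ISO-8601 timestamp of the first epoch.
    """

    subject_id: str
    domain: str
    counts: np.ndarray
    labels: Optional[np.ndarray] = None
    epoch_len: float = 30.0
    start_time: str = DEFAULT_START

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            bad = int(np.flatnonzero(self.counts < 0)[0])
            raise ValueError(
                f"negative count for subject {self.subject_id!r} at epoch {bad}"
            )
        if self.labels is not None:
            self.labels = as_hypnogram(self.labels)
            if len(self.labels) != len(self.counts):
                raise ValueError(
                    f"labels/counts length mismatch for subject {self.subject_id!r}"
                )
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def duration_hours(self) -> float:
        return len(self) * self.epoch_len / 3600.0

    def with_counts(self, counts: np.ndarray) -> "EpochSeries":
        """Copy of the series with counts replaced, labels untouched."""
        return replace(self, counts=np.asarray(counts, dtype=float))

    def without_labels(self) -> "EpochSeries":
        return replace(self, labels=None)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per epoch."""
        n = len(self)
        times = pd.date_range(
            self.start_time, periods=n, freq=pd.Timedelta(seconds=self.epoch_len)
        )
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "domain": self.domain,
                "epoch_index": np.arange(n),
                "timestamp": times.strftime("%Y-%m-%dT%H:%M:%S"),
                "counts": self.counts,
                "label": self.labels if self.labels is not None else np.full(n, np.nan),
            }
        )
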