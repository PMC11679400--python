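"""Epoch-table I/O, model-input windowing, and subject-level splits.

The on-disk interchange format is a delimited text table with columns
``subject_id, domain, epoch_index, timestamp, counts, label`` (label may
be empty).  Model inputs are fixed-length count windows centred on each
epoch; the two canonical schemes are 25 min of context on both sides of
the current epoch (101 samples at 30-s epochs) and 25 min past plus 1 min
future (53 samples).  Record edges are zero-padded, and the padding
positions are carried in an explicit mask so every epoch of a night gets
a prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .series import EpochSeries

TABLE_COLUMNS = ["subject_id", "domain", "epoch_index", "timestamp", "counts", "label"]

#: canonical window lengths (25+25 min and 25+1 min context at 30-s epochs)
CANONICAL_LENGTHS = (101, 53)


@dataclass
class WindowSet:
    """Fixed-length count windows, one per epoch of the parent series.

    ``windows`` has shape (n_windows, L); ``pad_mask`` is True where a
    position falls outside the parent record and was zero-filled.
    ``center_index`` maps each window back to its epoch.
    """

    windows: np.ndarray
    labels: Optional[np.ndarray]
    domain_ids: np.ndarray
    pad_mask: np.ndarray
    center_index: np.ndarray
    past_epochs: int
    future_epochs: int

    @property
    def L(self) -> int:
        return self.windows.shape[1]

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def canonical(self) -> bool:
        return self.L in CANONICAL_LENGTHS

    def without_labels(self) -> "WindowSet":
        return WindowSet(
            self.windows, None, self.domain_ids, self.pad_mask,
            self.center_index, self.past_epochs, self.future_epochs,
        )


def write_epoch_table(series: Iterable[EpochSeries], path, sep: str = ",") -> None:
    """Write one or more subjects to a single delimited epoch table."""
    frames = [s.to_frame() for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_epoch_table(path, sep: str = ",") -> List[EpochSeries]:
    """Parse an epoch table into one :class:`EpochSeries` per
    (subject_id, domain) group.

    An entirely empty label column yields label-free series.  Negative
    counts and non-uniform epoch spacing are rejected with the offending
    subject and epoch named.
    """
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str, "domain": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"epoch table missing columns: {missing}")
    out = []
    for (sid, dom), grp in df.groupby(["subject_id", "domain"], sort=True):
        grp = grp.sort_values("epoch_index")
        counts = grp["counts"].to_numpy(dtype=float)
        if (counts < 0).any():
            bad = int(grp["epoch_index"].to_numpy()[counts < 0][0])
            raise ValueError(f"negative count for subject {sid!r} at epoch {bad}")
        times = pd.to_datetime(grp["timestamp"])
        deltas = times.diff().dropna().dt.total_seconds().to_numpy()
        if len(deltas):
            if not np.allclose(deltas, deltas[0]):
                bad = int(grp["epoch_index"].to_numpy()[1:][deltas != deltas[0]][0])
                raise ValueError(
                    f"non-uniform epoch spacing for subject {sid!r} at epoch {bad}"
                )
            epoch_len = float(deltas[0])
        else:
            epoch_len = 30.0
        labels = grp["label"].to_numpy(dtype=float)
        lab = None if np.isnan(labels).all() else labels.astype(np.int8)
        out.append(
            EpochSeries(
                subject_id=sid,
                domain=dom,
                counts=counts,
                labels=lab,
                epoch_len=epoch_len,
                start_time=str(times.iloc[0].isoformat()),
            )
        )
    return out


def extract_windows(
    series: EpochSeries,
    past_epochs: int,
    future_epochs: int,
    domain_id: int = 0,
) -> WindowSet:
    """Slice a record into one window of length past+1+future per epoch.

    Window k covers epochs ``k-past .. k+future`` of the record; positions
    outside the record are zero-filled and flagged in ``pad_mask``, so
    ``windows[k][past_epochs] == counts[k]`` for every k.
    """
    if past_epochs < 0 or future_epochs < 0:
        raise ValueError("past_epochs and future_epochs must be >= 0")
    n = len(series)
    if n == 0:
        raise ValueError("cannot window an empty series")
    L = past_epochs + 1 + future_epochs
    padded = np.zeros(n + past_epochs + future_epochs, dtype=float)
    padded[past_epochs : past_epochs + n] = series.counts
    valid = np.zeros_like(padded, dtype=bool)
    valid[past_epochs : past_epochs + n] = True
    win = np.lib.stride_tricks.sliding_window_view(padded, L).copy()
    mask = ~np.lib.stride_tricks.sliding_window_view(valid, L)
    labels = series.labels.copy() if series.labels is not None else None
    return WindowSet(
        windows=win,
        labels=labels,
        domain_ids=np.full(n, domain_id, dtype=np.int8),
        pad_mask=mask.copy(),
        center_index=np.arange(n),
        past_epochs=past_epochs,
        future_epochs=future_epochs,
    )


def stack_windows(sets: Sequence[WindowSet]) -> WindowSet:
    """Concatenate WindowSets from several subjects (same scheme)."""
    if not sets:
        raise ValueError("no window sets to stack")
    p, f = sets[0].past_epochs, sets[0].future_epochs
    if any(ws.past_epochs != p or ws.future_epochs != f for ws in sets):
        raise ValueError("window schemes differ between sets")
    labels = None
    if all(ws.labels is not None for ws in sets):
        labels = np.concatenate([ws.labels for ws in sets])
    return WindowSet(
        windows=np.concatenate([ws.windows for ws in sets]),
        labels=labels,
        domain_ids=np.concatenate([ws.domain_ids for ws in sets]),
        pad_mask=np.concatenate([ws.pad_mask for ws in sets]),
        center_index=np.concatenate([ws.center_index for ws in sets]),
        past_epochs=p,
        future_epochs=f,
    )


def windows_for_cohort(
    cohort: Sequence[EpochSeries],
    past_epochs: int,
    future_epochs: int,
    domain_id: int = 0,
) -> WindowSet:
    return stack_windows(
        [extract_windows(s, past_epochs, future_epochs, domain_id) for s in cohort]
    )


@dataclass
class SplitSpec:
    """Subject-level train/validation/test fractions (default 65-20-15)."""

    fractions: Tuple[float, float, float] = (0.65, 0.20, 0.15)
    seed: int = 0

    def validate(self) -> None:
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be nonnegative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def split_subjects(
    subject_ids: Sequence[str], spec: SplitSpec
) -> Tuple[set, set, set]:
    """Partition subject ids into disjoint train/validation/test sets.

    Splitting is always by subject, never by epoch, so no test subject's
    data can leak into training windows.  Validation and test sizes are
    ``round(n * fraction)``; the remainder goes to train.  Deterministic
    per seed.
    """
    spec.validate()
    ids = sorted(set(subject_ids))
    if len(ids) < 3:
        raise ValueError("need at least 3 subjects to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(ids))
    n = len(ids)
    n_val = int(round(n * spec.fractions[1]))
    n_test = int(round(n * spec.fractions[2]))
    shuffled = [ids[i] for i in order]
    val = set(shuffled[:n_val])
    test = set(shuffled[n_val : n_val + n_test])
    train = set(shuffled[n_val + n_test :])
    return train, val, test
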