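"""Small interval utilities on plain numpy arrays (0-based, half-open)."""

from __future__ import annotations

import numpy as np


class IntervalSet:
    """Possibly-overlapping intervals on one chromosome, queryable for overlap.

    Sorted by start with a running maximum of ends, so an overlap query is a
    single searchsorted plus one prefix-max lookup.
    """

    def __init__(self, starts, ends):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(ends <= starts):
            raise ValueError("interval with end <= start")
        order = np.argsort(starts, kind="stable")
        self.starts = starts[order]
        self.ends = ends[order]
        self.max_end = (
            np.maximum.accumulate(self.ends) if len(self.ends) else self.ends
        )

    def __len__(self) -> int:
        return len(self.starts)

    def overlaps(self, start: int, end: int) -> bool:
        i = np.searchsorted(self.starts, end, side="left")
        if i == 0:
            return False
        return bool(self.max_end[i - 1] > start)

    def overlaps_many(self, starts, ends) -> np.ndarray:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        idx = np.searchsorted(self.starts, ends, side="left")
        out = idx > 0
        safe = np.clip(idx - 1, 0, None)
        if len(self.max_end):
            out &= self.max_end[safe] > starts
        else:
            out[:] = False
        return out


def assign_points(pos, starts, ends) -> np.ndarray:
    """Index of the non-overlapping sorted interval containing each point; -1 if none."""
    pos = np.asarray(pos, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if len(starts) == 0:
        return np.full(len(pos), -1, dtype=np.int64)
    idx = np.searchsorted(starts, pos, side="right") - 1
    safe = np.clip(idx, 0, None)
    ok = (idx >= 0) & (pos < ends[safe])
    return np.where(ok, idx, -1)


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Half-open gap in bp between two intervals; 0 when they overlap or touch-overlap."""
    if b_start >= a_end:
        return int(b_start - a_end)
    if a_start >= b_end:
        return int(a_start - b_end)
    return 0
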