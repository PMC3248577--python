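"""Vectorized half-open interval overlap queries.

All coordinates are 0-based half-open. The only primitive exported is an
existence query: for each query interval, does any subject interval share
at least one base pair with it. Implemented as a sorted sweep: subjects are
sorted by start and a running prefix-maximum of their ends is kept; a query
[s, e) overlaps some subject iff among subjects with start < e the maximum
end exceeds s.
"""

from __future__ import annotations

import numpy as np


class SubjectIndex:
    """Per-chromosome sorted subject intervals with prefix-max ends."""

    def __init__(self, by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends) in by_chrom.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            self._idx[chrom] = (starts[order], np.maximum.accumulate(ends[order]))

    def any_overlap(self, chrom: str, starts, ends) -> np.ndarray:
        """Boolean mask: query i overlaps >=1 subject interval on chrom."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._idx:
            return np.zeros(starts.shape, dtype=bool)
        s_starts, s_maxend = self._idx[chrom]
        pos = np.searchsorted(s_starts, ends, side="left")
        hit = pos > 0
        hit[hit] = s_maxend[pos[hit] - 1] > starts[hit]
        return hit


def count_overlapping(q_starts, q_ends, s_starts, s_ends) -> int:
    """Number of query intervals overlapping >=1 subject interval.

    Single-chromosome arrays; subjects need not be pre-sorted.
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    s_starts = np.asarray(s_starts, dtype=np.int64)
    s_ends = np.asarray(s_ends, dtype=np.int64)
    order = np.argsort(s_starts, kind="stable")
    ss = s_starts[order]
    se = np.maximum.accumulate(s_ends[order])
    pos = np.searchsorted(ss, q_ends, side="left")
    hit = pos > 0
    hit[hit] = se[pos[hit] - 1] > q_starts[hit]
    return int(hit.sum())
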