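"""Closed-interval utilities on 1-based, both-inclusive genomic coordinates.

Every interval in this package is a ``(start, end)`` pair of positive
integers with ``start <= end``; the span covers ``end - start + 1`` bases.
BED input/output converts at the boundary (see :mod:`svscape.io`).
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or bookended (adjacent) closed intervals.

    Returns a sorted, disjoint list covering the same base set.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if s > e:
            raise ValueError(f"interval start {s} > end {e}")
        if merged and s <= merged[-1][1] + 1:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: Iterable[Interval]) -> int:
    """Number of distinct bases covered by a set of closed intervals."""
    return sum(e - s + 1 for s, e in merge_intervals(intervals))


def overlap_length(a: Interval, b: Interval) -> int:
    """Bases shared by two closed intervals (0 if disjoint)."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    return max(0, hi - lo + 1)


def intersect_length(a: Iterable[Interval], b: Iterable[Interval]) -> int:
    """Bases covered by both interval sets (each internally unioned first)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    i = j = total = 0
    while i < len(ma) and j < len(mb):
        total += overlap_length(ma[i], mb[j])
        if ma[i][1] < mb[j][1]:
            i += 1
        else:
            j += 1
    return total


def subtract_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Closed-interval difference a \\ b, both sides unioned first."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    out: list[Interval] = []
    j = 0
    for s, e in ma:
        cur = s
        while j < len(mb) and mb[j][1] < cur:
            j += 1
        k = j
        while k < len(mb) and mb[k][0] <= e:
            bs, be = mb[k]
            if bs > cur:
                out.append((cur, bs - 1))
            cur = max(cur, be + 1)
            if cur > e:
                break
            k += 1
        if cur <= e:
            out.append((cur, e))
    return out


class IntervalSet:
    """Per-chromosome merged closed intervals with fast overlap queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):  # (chrom, start, end)
        by_chrom: dict[str, list[Interval]] = {}
        for chrom, s, e in intervals:
            by_chrom.setdefault(str(chrom), []).append((int(s), int(e)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            merged = merge_intervals(ivs)
            self._starts[chrom] = np.array([s for s, _ in merged], dtype=np.int64)
            self._ends[chrom] = np.array([e for _, e in merged], dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def intervals(self, chrom: str | None = None) -> Iterator[tuple[str, int, int]]:
        for c in self.chroms if chrom is None else ([chrom] if chrom in self._starts else []):
            for s, e in zip(self._starts[c], self._ends[c]):
                yield c, int(s), int(e)

    def total_length(self) -> int:
        return int(sum((self._ends[c] - self._starts[c] + 1).sum() for c in self._starts))

    def __len__(self) -> int:
        return int(sum(len(self._starts[c]) for c in self._starts))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.overlap_length(chrom, start, end) > 0

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Bases of [start, end] covered by the set on `chrom`."""
        if chrom not in self._starts:
            return 0
        starts, ends = self._starts[chrom], self._ends[chrom]
        # candidate intervals: start <= end_query and end >= start_query
        lo = int(np.searchsorted(ends, start, side="left"))
        hi = int(np.searchsorted(starts, end, side="right"))
        if lo >= hi:
            return 0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return int(np.maximum(0, e - s + 1).sum())

    def intersection_length(self, other: "IntervalSet") -> int:
        total = 0
        for c in self._starts:
            if c not in other._starts:
                continue
            a = list(zip(self._starts[c].tolist(), self._ends[c].tolist()))
            b = list(zip(other._starts[c].tolist(), other._ends[c].tolist()))
            total += intersect_length(a, b)
        return total
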