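"""Sorted-array interval search shared by the overlap/context/timing modules."""

from __future__ import annotations

import numpy as np
import pandas as pd


class IntervalIndex:
    """Overlap queries against a fixed set of 0-based half-open intervals.

    Intervals are sorted by start per chromosome; a running maximum of ends
    bounds the candidate window, so queries are near-logarithmic on
    non-pathological data and exact in all cases.
    """

    def __init__(self, chroms, starts, ends):
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if not (len(chroms) == len(starts) == len(ends)):
            raise ValueError("chroms/starts/ends length mismatch")
        if len(starts) and (starts >= ends).any():
            raise ValueError("intervals must satisfy start < end")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            s = starts[mask]
            e = ends[mask]
            idx = np.nonzero(mask)[0]
            order = np.argsort(s, kind="mergesort")
            s, e, idx = s[order], e[order], idx[order]
            cummax_end = np.maximum.accumulate(e)
            self._by_chrom[str(chrom)] = (s, e, idx, cummax_end)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntervalIndex":
        return cls(df["chrom"].to_numpy(), df["start"].to_numpy(),
                   df["end"].to_numpy())

    def __len__(self) -> int:
        return sum(len(v[0]) for v in self._by_chrom.values())

    def query(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Original row indices of intervals overlapping [start, end)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return np.empty(0, dtype=np.int64)
        s, e, idx, cummax_end = entry
        hi = np.searchsorted(s, end, side="left")      # starts < end
        lo = np.searchsorted(cummax_end, start, side="right")
        if lo >= hi:
            return np.empty(0, dtype=np.int64)
        sl = slice(lo, hi)
        hits = e[sl] > start
        return idx[sl][hits]

    def overlap_lengths(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """(row indices, overlap bp) for intervals overlapping [start, end)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        s, e, idx, cummax_end = entry
        hi = np.searchsorted(s, end, side="left")
        lo = np.searchsorted(cummax_end, start, side="right")
        if lo >= hi:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        sl = slice(lo, hi)
        ov = np.minimum(e[sl], end) - np.maximum(s[sl], start)
        keep = ov > 0
        return idx[sl][keep], ov[keep]

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        return len(self.query(chrom, start, end)) > 0

    def count_overlapping(self, regions: pd.DataFrame) -> np.ndarray:
        """Per-region count of indexed intervals overlapping it."""
        out = np.zeros(len(regions), dtype=np.int64)
        for i, row in enumerate(regions.itertuples(index=False)):
            out[i] = len(self.query(row.chrom, int(row.start), int(row.end)))
        return out


def merge_bookended(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or bookended intervals (bedtools-merge style)."""
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    cur_chrom, cur_start, cur_end = None, None, None
    for row in df.itertuples(index=False):
        if row.chrom != cur_chrom or row.start > cur_end:
            if cur_chrom is not None:
                rows.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = row.chrom, int(row.start), int(row.end)
        else:
            cur_end = max(cur_end, int(row.end))
    rows.append((cur_chrom, cur_start, cur_end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def points_in_intervals(chroms, points, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: is each 0-based point inside any interval?"""
    index = IntervalIndex.from_frame(intervals)
    out = np.zeros(len(points), dtype=bool)
    for i, (c, p) in enumerate(zip(chroms, points)):
        out[i] = index.any_overlap(str(c), int(p), int(p) + 1)
    return out
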