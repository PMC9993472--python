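"""Interval-overlap engine, TSS windows and piecewise-constant signal tracks."""

from __future__ import annotations

from collections import defaultdict
from typing import Any, Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .types import GeneModel, GenomicInterval


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def tss_window(gene: GeneModel, flank: int) -> GenomicInterval:
    """Promoter window ``[tss - flank, tss + flank + 1)`` clamped at the origin."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    tss = gene.tss
    return GenomicInterval(gene.chrom, max(0, tss - flank), tss + flank + 1)


class GenomicIndex:
    """Chromosome-partitioned interval index for overlap queries."""

    def __init__(self, items: Iterable[tuple[GenomicInterval, Any]] = ()):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._n = 0
        for region, payload in items:
            self.add(region, payload)

    def add(self, region: GenomicInterval, payload: Any) -> None:
        self._trees[region.chrom].addi(region.start, region.end, payload)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, region: GenomicInterval) -> list[Any]:
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(region.start, region.end)]

    def any_overlap(self, region: GenomicInterval) -> bool:
        tree = self._trees.get(region.chrom)
        return bool(tree and tree.overlaps(region.start, region.end))


def merge_intervals(
    regions: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= ``gap`` bp (0 merges overlap/adjacency-0)."""
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for r in regions:
        by_chrom[r.chrom].append(r)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start <= cur_end + gap:
                cur_end = max(cur_end, r.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = r.start, r.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


class SignalTrack:
    """Sparse piecewise-constant coverage, bedGraph style.

    Bases not covered by any record have signal 0 (bedGraph sparsity
    convention).  Records on one chromosome must not overlap each other.
    """

    def __init__(self, records: Iterable[tuple[str, int, int, float]]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
        for chrom, start, end, value in records:
            if not (0 <= start < end):
                raise ValueError(f"invalid signal span {chrom}:{start}-{end}")
            by_chrom[chrom].append((start, end, value))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping signal records on {chrom}")
            self._chroms[chrom] = (starts, ends, values)

    def mean_in(self, window: GenomicInterval) -> float:
        """Length-weighted mean signal over ``window`` (uncovered bases = 0)."""
        entry = self._chroms.get(window.chrom)
        if entry is None:
            return 0.0
        starts, ends, values = entry
        lo = int(np.searchsorted(ends, window.start, side="right"))
        hi = int(np.searchsorted(starts, window.end, side="left"))
        if lo >= hi:
            return 0.0
        seg_starts = np.maximum(starts[lo:hi], window.start)
        seg_ends = np.minimum(ends[lo:hi], window.end)
        weights = np.maximum(seg_ends - seg_starts, 0)
        return float(np.dot(weights, values[lo:hi]) / len(window))
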