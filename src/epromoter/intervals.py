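"""Genomic interval primitives shared across the pipeline.

All in-memory coordinates are 0-based half-open ([start, end)), BED-style.
The 1-based VCF dialect is converted at the reader boundary.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np
from intervaltree import IntervalTree


class GenomicInterval(NamedTuple):
    """A chromosome span; the unit of all overlap arithmetic."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0


def merge_intervals(
    intervals: Sequence[GenomicInterval],
) -> tuple[list[GenomicInterval], list[int]]:
    """Single-linkage merge of intervals sharing >= 1 bp (per chromosome).

    Abutting half-open intervals ([a,b) and [b,c)) share zero bases and are
    *not* merged. Returns the merged intervals sorted by (chrom, start) and,
    for every input interval, the index of the merged interval containing it.
    """
    order = sorted(
        range(len(intervals)),
        key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end),
    )
    merged: list[GenomicInterval] = []
    assignment = [0] * len(intervals)
    for i in order:
        iv = intervals[i]
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        assignment[i] = len(merged) - 1
    return merged, assignment


def interval_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    """Index intervals by chromosome for overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(intervals):
        if iv.end <= iv.start:
            raise ValueError(f"empty interval cannot be indexed: {iv}")
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees


def query_overlaps(trees: dict[str, IntervalTree], iv: GenomicInterval) -> list[int]:
    """Indices of indexed intervals overlapping ``iv`` by >= 1 bp."""
    tree = trees.get(iv.chrom)
    if tree is None:
        return []
    return sorted(hit.data for hit in tree.overlap(iv.start, iv.end))


def coverage_bp(
    region: GenomicInterval, merged_sorted: Sequence[GenomicInterval]
) -> int:
    """Bases of ``region`` covered by a pre-merged, sorted interval list."""
    total = 0
    for iv in merged_sorted:
        if iv.chrom != region.chrom:
            continue
        if iv.start >= region.end:
            break
        total += region.overlap_len(iv)
    return total


def count_overlapping(
    regions: Sequence[GenomicInterval],
    frag_chrom: np.ndarray,
    frag_start: np.ndarray,
    frag_end: np.ndarray,
) -> np.ndarray:
    """Per-region count of fragments overlapping by >= 1 bp (vectorized).

    Works for arbitrary (possibly overlapping) regions: a fragment overlaps
    [s, e) iff fragment.start < e and fragment.end > s, counted per region via
    sorted searches over the fragment coordinate arrays of each chromosome.
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(frag_chrom):
        mask = frag_chrom == chrom
        by_chrom[str(chrom)] = (
            np.sort(frag_start[mask]),
            np.sort(frag_end[mask]),
        )
    for i, region in enumerate(regions):
        got = by_chrom.get(region.chrom)
        if got is None:
            continue
        starts, ends = got
        n = starts.size
        n_right = n - np.searchsorted(starts, region.end, side="left")
        n_left = np.searchsorted(ends, region.start, side="right")
        counts[i] = n - n_right - n_left
    return counts
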