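"""Genome definitions and strand-agnostic interval algebra.

All coordinates are 0-based half-open (BED convention). Every operation in
the pipeline — category construction, hotspot overlap, LAD merging — goes
through the small set of primitives defined here, so the half-open
convention is enforced in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeDef",
    "Interval",
    "merge_intervals",
    "subtract_intervals",
    "complement_intervals",
    "intersect_any",
    "total_bp",
    "overlap_bp",
]


@dataclass(frozen=True)
class GenomeDef:
    """Ordered chromosome names and lengths (bp), as in a chrom.sizes file."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(L <= 0 for L in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeDef":
        return cls(tuple(sizes.keys()), tuple(int(v) for v in sizes.values()))

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def length_of(self, chrom: str) -> int:
        return self.sizes[chrom]


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _by_chrom(intervals: Iterable[Interval]) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Merge overlapping and book-ended intervals into a sorted disjoint set.

    Adjacent intervals (``end == start``) are merged, mirroring
    ``bedtools merge`` defaults. Names/scores/strands are dropped: the
    result is a strand-agnostic base-pair set.
    """
    merged: list[Interval] = []
    for chrom in sorted(_by_chrom(intervals)):
        ivs = sorted(_by_chrom(intervals)[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(Interval(chrom, cur_s, cur_e))
    return merged


def subtract_intervals(
    a: Sequence[Interval], b: Sequence[Interval]
) -> list[Interval]:
    """Base-pair set difference ``a \\ b`` as merged intervals."""
    a_m = merge_intervals(a)
    b_by = _by_chrom(merge_intervals(b))
    out: list[Interval] = []
    for iv in a_m:
        cuts = b_by.get(iv.chrom, [])
        pos = iv.start
        for c in cuts:
            if c.end <= iv.start or c.start >= iv.end:
                continue
            if c.start > pos:
                out.append(Interval(iv.chrom, pos, c.start))
            pos = max(pos, c.end)
        if pos < iv.end:
            out.append(Interval(iv.chrom, pos, iv.end))
    return out


def complement_intervals(
    a: Sequence[Interval], genome: GenomeDef
) -> list[Interval]:
    """Base-pair complement of ``a`` over every chromosome of ``genome``."""
    for iv in a:
        if iv.chrom not in genome:
            raise ValueError(f"interval on unknown chromosome: {iv.chrom}")
        if iv.end > genome.length_of(iv.chrom):
            raise ValueError(f"interval beyond chromosome end: {iv}")
    whole = [
        Interval(c, 0, L) for c, L in zip(genome.chrom_names, genome.chrom_lengths)
    ]
    return subtract_intervals(whole, a)


def intersect_any(
    query: Sequence[Interval], subject: Sequence[Interval]
) -> list[Interval]:
    """Query intervals with >= 1 bp overlap against the subject set.

    Any-overlap semantics (``bedtools intersect -u``): each query interval
    is reported at most once, in sorted order, preserving its metadata.
    """
    subj = _by_chrom(merge_intervals(subject)) if subject else {}
    hits: list[Interval] = []
    for iv in sorted(query, key=lambda v: (v.chrom, v.start, v.end)):
        merged = subj.get(iv.chrom)
        if not merged:
            continue
        starts = np.fromiter((m.start for m in merged), dtype=np.int64)
        ends = np.fromiter((m.end for m in merged), dtype=np.int64)
        # candidate: last merged interval starting before iv.end
        k = int(np.searchsorted(starts, iv.end, side="left")) - 1
        if k >= 0 and ends[k] > iv.start:
            hits.append(iv)
    return hits


def total_bp(intervals: Sequence[Interval]) -> int:
    """Total base pairs covered by the merged union of ``intervals``."""
    return sum(len(iv) for iv in merge_intervals(intervals)) if intervals else 0


def overlap_bp(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    """Base pairs in the intersection of the two merged sets."""
    if not a or not b:
        return 0
    b_by = _by_chrom(merge_intervals(b))
    bp = 0
    for iv in merge_intervals(a):
        for m in b_by.get(iv.chrom, []):
            lo = max(iv.start, m.start)
            hi = min(iv.end, m.end)
            if hi > lo:
                bp += hi - lo
    return bp
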