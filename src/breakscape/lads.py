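"""Lamina-associated-domain (LAD) harmonization and concordance.

LAD interval sets from different sources are projected onto a common bin
grid (10-kb bins for the multi-dataset mouse consensus; 100-kb bins for
ChIP-signal domain calling). A bin belongs to a dataset when the dataset's
merged intervals cover at least ``min_frac`` of the bin (default 0.5;
``min_frac=0`` gives any-overlap membership). Constitutive LADs (cLADs)
are bins present in every dataset; facultative LADs (fLADs) are bins
present in a proper, non-empty subset. Concordance between datasets is
quantified by the Jaccard index on bin memberships and by base-pair
overlap fractions on the raw intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import (
    GenomeDef,
    Interval,
    merge_intervals,
    overlap_bp,
    total_bp,
)

__all__ = [
    "BinGrid",
    "LADConsensus",
    "intervals_to_bins",
    "bins_to_intervals",
    "jaccard",
    "bp_overlap_fraction",
    "consensus_lads",
    "lad_coverage",
    "hotspot_lad_partition",
    "call_chip_domains",
]


@dataclass
class BinGrid:
    """Fixed-size bins tiling a genome; the last bin per chromosome may be short."""

    genome: GenomeDef
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self._nbins = {
            c: -(-L // self.bin_size)
            for c, L in zip(self.genome.chrom_names, self.genome.chrom_lengths)
        }
        self._offsets: dict[str, int] = {}
        off = 0
        for c in self.genome.chrom_names:
            self._offsets[c] = off
            off += self._nbins[c]
        self.n_bins = off

    def bin_lengths(self) -> np.ndarray:
        out = np.full(self.n_bins, self.bin_size, dtype=np.int64)
        for c, L in zip(self.genome.chrom_names, self.genome.chrom_lengths):
            rem = L % self.bin_size
            if rem:
                out[self._offsets[c] + self._nbins[c] - 1] = rem
        return out

    def bin_interval(self, idx: int) -> Interval:
        for c in self.genome.chrom_names:
            if idx < self._offsets[c] + self._nbins[c]:
                local = idx - self._offsets[c]
                start = local * self.bin_size
                end = min(start + self.bin_size, self.genome.length_of(c))
                return Interval(c, start, end)
        raise IndexError(idx)


@dataclass
class LADConsensus:
    grid: BinGrid
    memberships: list[np.ndarray]  # per dataset, boolean per bin
    clad: np.ndarray  # present in all datasets
    flad: np.ndarray  # present in >=1 but not all


def intervals_to_bins(
    lads: Sequence[Interval], grid: BinGrid, min_frac: float = 0.5
) -> np.ndarray:
    """Boolean bin membership: covered fraction >= min_frac (any overlap if 0)."""
    covered = np.zeros(grid.n_bins, dtype=np.int64)
    for iv in merge_intervals(lads) if lads else []:
        if iv.chrom not in grid.genome:
            raise ValueError(f"interval on unknown chromosome: {iv.chrom}")
        off = grid._offsets[iv.chrom]
        first = iv.start // grid.bin_size
        last = (iv.end - 1) // grid.bin_size
        for b in range(first, last + 1):
            lo = max(iv.start, b * grid.bin_size)
            hi = min(iv.end, (b + 1) * grid.bin_size)
            covered[off + b] += hi - lo
    lens = grid.bin_lengths()
    if min_frac <= 0:
        return covered > 0
    return covered >= min_frac * lens


def bins_to_intervals(member: np.ndarray, grid: BinGrid) -> list[Interval]:
    """Merged intervals spanned by member bins."""
    ivs = [grid.bin_interval(int(i)) for i in np.flatnonzero(member)]
    return merge_intervals(ivs) if ivs else []


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |a & b| / |a | b| over bin memberships (1.0 if both empty)."""
    if a.shape != b.shape:
        raise ValueError("bin grids differ")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def bp_overlap_fraction(
    a_intervals: Sequence[Interval], b_intervals: Sequence[Interval]
) -> float:
    """Fraction of a's merged base pairs overlapped by b."""
    a_bp = total_bp(a_intervals)
    if a_bp == 0:
        raise ValueError("reference interval set is empty")
    return overlap_bp(a_intervals, b_intervals) / a_bp


def consensus_lads(memberships: Sequence[np.ndarray], grid: BinGrid) -> LADConsensus:
    """Partition the union of memberships into constitutive and facultative bins."""
    if len(memberships) < 2:
        raise ValueError("consensus requires >= 2 datasets")
    stack = np.vstack([np.asarray(m, dtype=bool) for m in memberships])
    if stack.shape[1] != grid.n_bins:
        raise ValueError("membership length does not match grid")
    clad = stack.all(axis=0)
    flad = stack.any(axis=0) & ~clad
    return LADConsensus(grid, [m.copy() for m in stack], clad, flad)


def lad_coverage(lads: Sequence[Interval], genome: GenomeDef) -> float:
    """Merged LAD base pairs divided by total genome length."""
    for iv in lads:
        if iv.chrom not in genome or iv.end > genome.length_of(iv.chrom):
            raise ValueError(f"interval outside genome: {iv}")
    return total_bp(lads) / genome.total_length


def _any_overlap(iv: Interval, merged_by_chrom: dict[str, list[Interval]]) -> bool:
    return any(iv.overlaps(m) for m in merged_by_chrom.get(iv.chrom, []))


def _group(intervals: Sequence[Interval]) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def hotspot_lad_partition(
    hotspots,
    lads: Sequence[Interval] | None = None,
    consensus: LADConsensus | None = None,
) -> dict:
    """Partition hotspots inside/outside LADs (any-overlap).

    With a plain interval set: {inside, outside}. With a consensus:
    {cLAD, fLAD, outside}, cLAD taking precedence when a hotspot overlaps
    both. Percentages sum to 100.
    """
    items = getattr(hotspots, "hotspots", hotspots)
    ivs = [h.interval if hasattr(h, "interval") else h for h in items]
    n = len(ivs)
    if consensus is not None:
        clad_ivs = _group(bins_to_intervals(consensus.clad, consensus.grid))
        flad_ivs = _group(bins_to_intervals(consensus.flad, consensus.grid))
        counts = {"cLAD": 0, "fLAD": 0, "outside": 0}
        for iv in ivs:
            if _any_overlap(iv, clad_ivs):
                counts["cLAD"] += 1
            elif _any_overlap(iv, flad_ivs):
                counts["fLAD"] += 1
            else:
                counts["outside"] += 1
    elif lads is not None:
        merged = _group(merge_intervals(lads)) if lads else {}
        counts = {"inside": 0, "outside": 0}
        for iv in ivs:
            counts["inside" if _any_overlap(iv, merged) else "outside"] += 1
    else:
        raise ValueError("provide lads or consensus")
    pct = {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()}
    return {"n_hotspots": n, "counts": counts, "percent": pct}


def call_chip_domains(
    chip: np.ndarray,
    grid: BinGrid,
    input_track: np.ndarray | None = None,
    factor: float = 1.5,
) -> list[Interval]:
    """Enriched domains from binned ChIP coverage.

    A bin is enriched when its (input-normalized, if an input track is
    given) signal exceeds ``factor`` times the genome-wide median signal;
    adjacent enriched bins are merged into domains.
    """
    chip = np.asarray(chip, dtype=float)
    if chip.shape != (grid.n_bins,):
        raise ValueError("coverage length does not match grid")
    if not chip.any():
        raise ValueError("all-zero ChIP coverage")
    if input_track is not None:
        inp = np.asarray(input_track, dtype=float)
        if inp.shape != chip.shape:
            raise ValueError("input track length mismatch")
        scale = inp / inp[inp > 0].mean() if (inp > 0).any() else np.ones_like(inp)
        signal = np.where(scale > 0, chip / np.where(scale > 0, scale, 1.0), chip)
    else:
        signal = chip
    enriched = signal > factor * np.median(signal)
    return bins_to_intervals(enriched, grid)
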