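"""Seven-way exclusive genomic feature catalog and precedence assignment.

The catalog holds strand-agnostic, internally merged interval sets for
CDS, 5'UTR, 3'UTR, TSS windows (+/-250 bp by default), promoters
(-2000..+500 bp relative to the TSS, oriented by strand), exon-only
sequence (exonic bp not in CDS or UTRs) and intergenic space (complement
of gene bodies). A point is assigned to exactly one category by a fixed
precedence: CDS > UTR5 > UTR3 > TSS > Promoter > ExonOnly > Intergenic.

Points inside a gene body that fall in none of the above (introns) get an
explicit "Intronic/other" label; they can optionally be folded into
Intergenic for seven-way summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import GenomeDef, Interval, merge_intervals, subtract_intervals, complement_intervals, total_bp
from .io import GeneAnnotation

__all__ = [
    "CATEGORIES",
    "INTRONIC",
    "RegionParams",
    "RegionCatalog",
    "build_region_catalog",
    "assign_category",
    "hotspot_category_counts",
]

CATEGORIES = ("CDS", "UTR5", "UTR3", "TSS", "Promoter", "ExonOnly", "Intergenic")
INTRONIC = "Intronic/other"


@dataclass(frozen=True)
class RegionParams:
    tss_up: int = 250
    tss_down: int = 250
    prom_up: int = 2000
    prom_down: int = 500


class _IndexedSet:
    """Merged intervals of one chromosome as sorted arrays, for O(log n) lookup."""

    def __init__(self, intervals: Sequence[Interval]):
        by: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        cur: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            cur.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in cur.items():
            pairs.sort()
            by[chrom] = (
                np.array([p[0] for p in pairs], dtype=np.int64),
                np.array([p[1] for p in pairs], dtype=np.int64),
            )
        self._by = by

    def contains(self, chrom: str, pos: int) -> bool:
        entry = self._by.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        return k >= 0 and pos < ends[k]

    def contains_many(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        entry = self._by.get(chrom)
        if entry is None:
            return np.zeros(len(pos), dtype=bool)
        starts, ends = entry
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = k >= 0
        out = np.zeros(len(pos), dtype=bool)
        out[ok] = pos[ok] < ends[k[ok]]
        return out


@dataclass
class RegionCatalog:
    """Merged interval sets for the seven exclusive categories."""

    categories: dict[str, list[Interval]]
    params: RegionParams
    genome: GenomeDef
    _index: dict[str, _IndexedSet] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.categories)
        if missing:
            raise ValueError(f"catalog missing categories: {sorted(missing)}")
        self._index = {c: _IndexedSet(self.categories[c]) for c in CATEGORIES}

    def category_bp(self) -> dict[str, int]:
        return {c: total_bp(self.categories[c]) for c in CATEGORIES}


def _clip(chrom: str, start: int, end: int, genome: GenomeDef) -> Interval | None:
    L = genome.length_of(chrom)
    s, e = max(0, start), min(end, L)
    return Interval(chrom, s, e) if e > s else None


def build_region_catalog(
    annotation: GeneAnnotation,
    genome: GenomeDef,
    params: RegionParams = RegionParams(),
) -> RegionCatalog:
    """Construct the seven merged category interval sets from an annotation.

    TSS and promoter windows are computed strand-aware (upstream = 5' of
    the TSS) and then stored strand-agnostic; every set is clipped to
    chromosome bounds and internally merged.
    """
    if not annotation.transcripts:
        raise ValueError("annotation has no transcripts")

    tss_ivs: list[Interval] = []
    prom_ivs: list[Interval] = []
    cds: list[Interval] = []
    utr5: list[Interval] = []
    utr3: list[Interval] = []
    exons: list[Interval] = []
    for t in annotation.transcripts:
        if t.strand == "+":
            tss_win = (t.tss - params.tss_up, t.tss + params.tss_down)
            prom = (t.tss - params.prom_up, t.tss + params.prom_down)
        else:
            # upstream lies to the right of a minus-strand TSS
            tss_win = (t.tss - params.tss_down, t.tss + params.tss_up)
            prom = (t.tss - params.prom_down, t.tss + params.prom_up)
        for target, (s, e) in ((tss_ivs, tss_win), (prom_ivs, prom)):
            iv = _clip(t.chrom, s, e, genome)
            if iv is not None:
                target.append(iv)
        for target, pairs in ((cds, t.cds), (utr5, t.utr5),
                              (utr3, t.utr3), (exons, t.exons)):
            for s, e in pairs:
                iv = _clip(t.chrom, s, e, genome)
                if iv is not None:
                    target.append(iv)

    coding_or_utr = cds + utr5 + utr3
    exon_only = subtract_intervals(exons, coding_or_utr) if exons else []
    gene_bodies = [Interval(g.chrom, g.start, g.end)
                   for g in annotation.genes.values()]
    intergenic = complement_intervals(merge_intervals(gene_bodies), genome)

    categories = {
        "CDS": merge_intervals(cds) if cds else [],
        "UTR5": merge_intervals(utr5) if utr5 else [],
        "UTR3": merge_intervals(utr3) if utr3 else [],
        "TSS": merge_intervals(tss_ivs) if tss_ivs else [],
        "Promoter": merge_intervals(prom_ivs) if prom_ivs else [],
        "ExonOnly": exon_only,
        "Intergenic": intergenic,
    }
    return RegionCatalog(categories, params, genome)


def assign_category(
    chrom: str,
    pos: int,
    catalog: RegionCatalog,
    intronic_as_intergenic: bool = False,
) -> str:
    """Assign a single genomic point to its highest-precedence category."""
    for cat in CATEGORIES[:-1]:
        if catalog._index[cat].contains(chrom, pos):
            return cat
    if catalog._index["Intergenic"].contains(chrom, pos):
        return "Intergenic"
    return "Intergenic" if intronic_as_intergenic else INTRONIC


def assign_categories(
    chroms: np.ndarray,
    positions: np.ndarray,
    catalog: RegionCatalog,
    intronic_as_intergenic: bool = False,
) -> np.ndarray:
    """Vectorized precedence assignment for arrays of points."""
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    labels = np.full(len(positions), "", dtype=object)
    fallback = "Intergenic" if intronic_as_intergenic else INTRONIC
    for chrom in set(chroms.astype(str)):
        sel = np.flatnonzero(chroms == chrom)
        pos = positions[sel]
        unassigned = np.ones(len(sel), dtype=bool)
        for cat in CATEGORIES:
            if not unassigned.any():
                break
            hit = catalog._index[cat].contains_many(chrom, pos) & unassigned
            labels[sel[hit]] = cat
            unassigned &= ~hit
        labels[sel[unassigned]] = fallback
    return labels


def break_category_counts(
    profile, catalog: RegionCatalog, intronic_as_intergenic: bool = False
) -> dict[str, int]:
    """Exclusive per-category break-event counts for a profile."""
    labels = list(CATEGORIES) + ([] if intronic_as_intergenic else [INTRONIC])
    counts = dict.fromkeys(labels, 0)
    assigned = assign_categories(
        profile.chroms, profile.positions, catalog, intronic_as_intergenic
    )
    for lab, n in zip(*np.unique(assigned.astype(str), return_counts=True)):
        counts[str(lab)] = int(n)
    return counts


def hotspot_category_counts(
    hotspots,
    catalog: RegionCatalog,
    intronic_as_intergenic: bool = False,
) -> dict[str, int]:
    """Count hotspots per category via their summit (peak center).

    Accepts a :class:`~breakscape.hotspots.HotspotSet` or any sequence of
    intervals; intervals without a summit use the midpoint (rounded down).
    Counts sum to the number of hotspots — each hotspot is assigned once.
    """
    labels = list(CATEGORIES) + ([] if intronic_as_intergenic else [INTRONIC])
    counts = {c: 0 for c in labels}
    items = getattr(hotspots, "hotspots", hotspots)
    for h in items:
        if hasattr(h, "summit"):
            chrom, pos = h.interval.chrom, h.summit
        else:
            chrom, pos = h.chrom, (h.start + h.end - 1) // 2
        counts[assign_category(chrom, pos, catalog, intronic_as_intergenic)] += 1
    return counts
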