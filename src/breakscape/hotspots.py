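"""DSB hotspot calling from break profiles.

Each break is turned into a shift/extend fragment (defaults: shift -100 bp,
extend 200 bp, i.e. the 200-bp window centered on the break). The pileup at
a base is the number of fragments covering it. Candidate peaks are maximal
runs of pileup >= 2; each candidate is tested at its maximum pileup against
a single genome-wide Poisson expectation

    lambda = n_events * extend / total_genome_length

(no local background model, strands ignored), p-values are BH-adjusted
across the candidates of one sample, and hotspots are the candidates with
q < q_max, fold enrichment > fe_min and pileup > pileup_min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeDef, Interval, merge_intervals
from .io import BreakProfile

__all__ = [
    "HotspotParams",
    "Hotspot",
    "HotspotSet",
    "build_pileup",
    "call_hotspots",
    "unique_hotspots",
    "dsb_density_per_chrom",
    "dsb_density_per_region",
]

# minimum pileup for a base to seed a candidate peak
CANDIDATE_MIN_PILEUP = 2


@dataclass(frozen=True)
class HotspotParams:
    shift: int = -100
    extend: int = 200
    q_max: float = 0.05
    fe_min: float = 4.0
    pileup_min: int = 10

    def __post_init__(self) -> None:
        if self.extend <= 0:
            raise ValueError("extend must be positive")
        if not 0 < self.q_max < 1:
            raise ValueError("q_max must be in (0, 1)")
        if self.fe_min <= 0 or self.pileup_min < 1:
            raise ValueError("invalid fold-enrichment / pileup thresholds")


@dataclass(frozen=True)
class Hotspot:
    interval: Interval
    summit: int
    pileup: int
    fold_enrichment: float
    p_value: float
    q_value: float


@dataclass
class HotspotSet:
    sample_id: str
    params: HotspotParams
    hotspots: list[Hotspot]

    def __len__(self) -> int:
        return len(self.hotspots)

    def intervals(self) -> list[Interval]:
        return [h.interval for h in self.hotspots]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": h.interval.chrom,
                "start": h.interval.start,
                "end": h.interval.end,
                "summit": h.summit,
                "pileup": h.pileup,
                "fold_enrichment": h.fold_enrichment,
                "p_value": h.p_value,
                "q_value": h.q_value,
            }
            for h in self.hotspots
        ]
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "summit", "pileup",
                     "fold_enrichment", "p_value", "q_value"],
        )


@dataclass
class PileupTrack:
    """Piecewise-constant coverage: value ``values[i]`` on [edges[i], edges[i+1])."""

    chrom: str
    length: int
    edges: np.ndarray  # int64, first = 0, last = length
    values: np.ndarray  # int64, len(edges) - 1

    def at(self, pos: int) -> int:
        k = int(np.searchsorted(self.edges, pos, side="right")) - 1
        return int(self.values[k])

    def to_array(self) -> np.ndarray:
        """Dense per-bp coverage (small chromosomes only)."""
        return np.repeat(self.values, np.diff(self.edges))


def build_pileup(
    profile: BreakProfile, genome: GenomeDef, params: HotspotParams = HotspotParams()
) -> dict[str, PileupTrack]:
    """Shift/extend fragment coverage per chromosome.

    A break at x contributes one fragment [x+shift, x+shift+extend), clipped
    to chromosome bounds rather than discarded.
    """
    per_chrom = profile.per_chrom()
    tracks: dict[str, PileupTrack] = {}
    for chrom, L in zip(genome.chrom_names, genome.chrom_lengths):
        pos = per_chrom.get(chrom, np.array([], dtype=np.int64))
        starts = np.clip(pos + params.shift, 0, L)
        ends = np.clip(pos + params.shift + params.extend, 0, L)
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
        bnd = np.concatenate(([0], starts, ends, [L]))
        edges = np.unique(bnd)
        delta = np.zeros(len(edges), dtype=np.int64)
        np.add.at(delta, np.searchsorted(edges, starts), 1)
        np.add.at(delta, np.searchsorted(edges, ends), -1)
        values = np.cumsum(delta)[:-1]
        tracks[chrom] = PileupTrack(chrom, L, edges, values)
    return tracks


def _candidates(track: PileupTrack) -> list[tuple[int, int, int, int]]:
    """Maximal runs with pileup >= CANDIDATE_MIN_PILEUP.

    Returns (start, end, max_pileup, summit) per run; the summit is the
    midpoint of the leftmost segment attaining the max pileup.
    """
    above = track.values >= CANDIDATE_MIN_PILEUP
    if not above.any():
        return []
    out = []
    i = 0
    n = len(track.values)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        seg_vals = track.values[i : j + 1]
        k = i + int(np.argmax(seg_vals))
        maxp = int(track.values[k])
        summit = int((track.edges[k] + track.edges[k + 1] - 1) // 2)
        out.append((int(track.edges[i]), int(track.edges[j + 1]), maxp, summit))
        i = j + 1
    return out


def call_hotspots(
    profile: BreakProfile, genome: GenomeDef, params: HotspotParams = HotspotParams()
) -> HotspotSet:
    """Call hotspots against the global Poisson fragment-coverage expectation."""
    if genome.total_length <= 0:
        raise ValueError("genome has zero length")
    if profile.n_events == 0:
        return HotspotSet(profile.sample_id, params, [])

    lam = profile.n_events * params.extend / genome.total_length
    tracks = build_pileup(profile, genome, params)
    cands: list[tuple[str, int, int, int, int]] = []
    for chrom in genome.chrom_names:
        for s, e, maxp, summit in _candidates(tracks[chrom]):
            cands.append((chrom, s, e, maxp, summit))
    if not cands:
        return HotspotSet(profile.sample_id, params, [])

    maxps = np.array([c[3] for c in cands], dtype=np.int64)
    pvals = stats.poisson.sf(maxps - 1, lam)  # P(X >= maxp)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    hotspots = []
    for (chrom, s, e, maxp, summit), p, q in zip(cands, pvals, qvals):
        fe = maxp / lam
        if q < params.q_max and fe > params.fe_min and maxp > params.pileup_min:
            hotspots.append(
                Hotspot(Interval(chrom, s, e), summit, maxp, float(fe),
                        float(p), float(q))
            )
    hotspots.sort(key=lambda h: (h.interval.chrom, h.interval.start))
    return HotspotSet(profile.sample_id, params, hotspots)


def unique_hotspots(a: HotspotSet, b: HotspotSet) -> HotspotSet:
    """Hotspots of ``a`` with no any-overlap against hotspots of ``b``."""
    if not b.hotspots:
        return HotspotSet(a.sample_id, a.params, list(a.hotspots))
    b_merged = merge_intervals(b.intervals())
    by_chrom: dict[str, list[Interval]] = {}
    for iv in b_merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    unique = []
    for h in a.hotspots:
        ivs = by_chrom.get(h.interval.chrom, [])
        if not any(h.interval.overlaps(m) for m in ivs):
            unique.append(h)
    return HotspotSet(a.sample_id, a.params, unique)


def dsb_density_per_chrom(profile: BreakProfile, genome: GenomeDef) -> pd.DataFrame:
    """Breaks per megabase per chromosome."""
    per_chrom = profile.per_chrom()
    rows = []
    for chrom, L in zip(genome.chrom_names, genome.chrom_lengths):
        n = len(per_chrom.get(chrom, ()))
        rows.append({"chrom": chrom, "n_breaks": n, "length_bp": L,
                     "breaks_per_mb": n / (L / 1e6)})
    return pd.DataFrame(rows)


def dsb_density_per_region(profile: BreakProfile, catalog) -> pd.DataFrame:
    """Per-category break counts and breaks/Mb under exclusive assignment."""
    from .regions import CATEGORIES, INTRONIC, break_category_counts

    labels = list(CATEGORIES) + [INTRONIC]
    counts = break_category_counts(profile, catalog)
    bp = catalog.category_bp()
    rows = []
    for c in labels:
        n = counts[c]
        cat_bp = bp.get(c, 0)
        rows.append({
            "category": c,
            "n_breaks": n,
            "category_bp": cat_bp,
            "breaks_per_mb": n / (cat_bp / 1e6) if cat_bp else float("nan"),
        })
    return pd.DataFrame(rows)
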