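"""IUPAC motif scanning and central enrichment around break summits.

AID (activation-induced cytidine deaminase) preferentially deaminates
cytosines in WRC / WRCY contexts and in the overlapping-hotspot motif WGCW
(W = A/T, R = A/G, Y = C/T). If breaks originate at such motifs, motif
matches inside windows centered on break summits should concentrate at the
window center; a motif unrelated to the process (e.g. GAGA) should not.
This module scans IUPAC motifs in +/-W-bp windows around summits, records
one best (closest-to-center) site per window, and tests central enrichment
with a one-sided binomial test against the uniform-placement null.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats

from .genome import Interval

__all__ = [
    "IUPAC_CODES",
    "reverse_complement",
    "iupac_scan",
    "MotifPositionProfile",
    "positional_profile",
    "CentralEnrichment",
    "central_enrichment",
    "motif_site_genomic_distribution",
    "peak_overlap_percentage",
]

IUPAC_CODES = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "W": frozenset("AT"), "S": frozenset("CG"), "R": frozenset("AG"),
    "Y": frozenset("CT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "W": "W", "S": "S", "R": "Y", "Y": "R", "K": "M", "M": "K", "N": "N",
}


def reverse_complement(motif: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(motif.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in {motif!r}") from exc


@lru_cache(maxsize=256)
def _motif_regex(motif: str):
    try:
        classes = ["[" + "".join(sorted(IUPAC_CODES[c])) + "]" for c in motif]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in {motif!r}") from exc
    # lookahead so overlapping matches are all reported
    return re.compile("(?=" + "".join(classes) + ")")


def _forward_offsets(seq: str, motif: str) -> list[int]:
    return [m.start() for m in _motif_regex(motif).finditer(seq)]


def iupac_scan(
    sequence: str, motif: str, both_strands: bool = True
) -> list[tuple[int, str]]:
    """All (offset, strand) matches of an IUPAC motif in a sequence.

    Matching is case-insensitive; a minus-strand match at offset i means
    the reverse complement of the motif matches the forward sequence at i.
    """
    seq = sequence.upper()
    motif = motif.upper()
    hits = [(o, "+") for o in _forward_offsets(seq, motif)]
    if both_strands:
        rc = reverse_complement(motif)
        fwd = {o for o, _ in hits}
        for o in _forward_offsets(seq, rc):
            if o not in fwd:  # palindromic motifs match once per offset
                hits.append((o, "-"))
    return sorted(hits)


def extract_windows(
    sequences, summits: Sequence[tuple[str, int]], half_width: int = 100
) -> list[str]:
    """Sequence windows of 2*half_width+1 bp centered on summits.

    ``sequences`` is a mapping chrom -> sequence (a plain dict or a
    pyfaidx.Fasta). Windows truncated by a chromosome edge are returned
    short; :func:`positional_profile` drops and counts them.
    """
    out = []
    for chrom, pos in summits:
        seq = sequences[chrom]
        L = len(seq)
        lo, hi = max(0, pos - half_width), min(L, pos + half_width + 1)
        out.append(str(seq[lo:hi]).upper())
    return out


@dataclass
class MotifPositionProfile:
    motif: str
    half_width: int
    n_windows: int
    n_with_site: int
    best_offsets: np.ndarray  # start offset of the best site per window with a site
    site_counts: np.ndarray  # distinct match offsets per window with a site
    curve: np.ndarray  # smoothed fraction of windows with best site at each offset
    raw_curve: np.ndarray
    n_dropped: int = 0


def _best_offset(offsets: Sequence[int], motif_len: int, center: float) -> int:
    """Offset whose site midpoint is closest to the window center; ties -> lower."""
    mid = lambda o: o + (motif_len - 1) / 2.0
    return min(offsets, key=lambda o: (abs(mid(o) - center), o))


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.copy()
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: len(x)]


def positional_profile(
    windows: Sequence[str],
    motif: str,
    half_width: int = 100,
    both_strands: bool = True,
    smooth_width: int = 11,
    all_sites: bool = False,
) -> MotifPositionProfile:
    """Best-site-per-window positional profile of a motif.

    ``windows`` are sequences of length 2*half_width + 1 (summit at the
    center); shorter windows (truncated flanks) are dropped and counted.
    Each window contributes at most one count: the match whose midpoint is
    closest to the center (``all_sites=True`` counts every match instead).
    The curve has one entry per possible match start offset
    (2*half_width - len(motif) + 2 values); smoothing is for display, the
    raw curve is retained.
    """
    if not windows:
        raise ValueError("no windows to profile")
    wlen = 2 * half_width + 1
    m = len(motif)
    n_offsets = wlen - m + 1
    center = half_width
    counts = np.zeros(n_offsets, dtype=float)
    best: list[int] = []
    n_sites: list[int] = []
    kept = 0
    dropped = 0
    for seq in windows:
        if len(seq) != wlen:
            dropped += 1
            continue
        kept += 1
        offsets = sorted({o for o, _ in iupac_scan(seq, motif, both_strands)})
        if not offsets:
            continue
        n_sites.append(len(offsets))
        if all_sites:
            for o in offsets:
                counts[o] += 1
            best.append(_best_offset(offsets, m, center))
        else:
            o = _best_offset(offsets, m, center)
            counts[o] += 1
            best.append(o)
    if kept == 0:
        raise ValueError("all windows dropped (wrong length)")
    raw = counts / kept
    return MotifPositionProfile(
        motif=motif,
        half_width=half_width,
        n_windows=kept,
        n_with_site=len(best),
        best_offsets=np.array(best, dtype=np.int64),
        site_counts=np.array(n_sites, dtype=np.int64),
        curve=_smooth(raw, smooth_width),
        raw_curve=raw,
        n_dropped=dropped,
    )


@dataclass
class CentralEnrichment:
    p_value: float
    ratio: float  # observed central proportion / null proportion
    n_central: int
    n_with_site: int
    null_prob: float
    central_half_width: int


def central_enrichment(
    profile: MotifPositionProfile, central_half_width: int = 25
) -> CentralEnrichment:
    """One-sided binomial test for concentration of best sites at the center.

    k = windows whose best-site midpoint lies within +/-central_half_width
    of the window center, n = windows with any site. The per-site null
    probability is the fraction of possible placements that are central;
    because the recorded site is the *closest-to-center* of a window's
    matches, a window with s_i sites is central under uniform placement
    with probability 1 - (1 - p)^{s_i}, and the test uses the mean of
    these multiplicity-corrected probabilities as the binomial null.
    Without the correction, motifs with frequent chance matches (short or
    degenerate patterns) would look centrally enriched in random sequence.
    """
    if profile.n_with_site == 0:
        raise ValueError("profile has no sites")
    m = len(profile.motif)
    center = profile.half_width
    n_offsets = 2 * profile.half_width - m + 2
    mids = np.arange(n_offsets) + (m - 1) / 2.0
    central_mask = np.abs(mids - center) <= central_half_width
    p_site = central_mask.sum() / n_offsets
    null_p = float(np.mean(1.0 - (1.0 - p_site) ** profile.site_counts))

    best_mids = profile.best_offsets + (m - 1) / 2.0
    k = int((np.abs(best_mids - center) <= central_half_width).sum())
    n = profile.n_with_site
    res = stats.binomtest(k, n, null_p, alternative="greater")
    ratio = (k / n) / null_p if null_p > 0 else float("inf")
    return CentralEnrichment(float(res.pvalue), float(ratio), k, n,
                             float(null_p), central_half_width)


def motif_site_genomic_distribution(
    sites: Sequence[tuple[str, int]], catalog
) -> dict[str, float]:
    """Percentage of motif sites per genomic category (hierarchical assignment).

    Uses the same precedence machinery as hotspot annotation, with intronic
    points reported under an explicit "Intron" label. Percentages sum to
    100 over nonempty input.
    """
    from .regions import CATEGORIES, INTRONIC, assign_category

    labels = list(CATEGORIES) + ["Intron"]
    counts = {c: 0 for c in labels}
    for chrom, pos in sites:
        lab = assign_category(chrom, pos, catalog)
        counts["Intron" if lab == INTRONIC else lab] += 1
    n = sum(counts.values())
    return {c: (100.0 * v / n if n else 0.0) for c, v in counts.items()}


def peak_overlap_percentage(hotspots, peaks: Sequence[Interval]) -> dict:
    """Fraction of hotspots with any-overlap against a peak set."""
    from .genome import intersect_any

    items = getattr(hotspots, "hotspots", hotspots)
    ivs = [h.interval if hasattr(h, "interval") else h for h in items]
    if not ivs:
        raise ValueError("empty hotspot set")
    n_overlap = len(intersect_any(ivs, list(peaks))) if peaks else 0
    return {
        "n_overlapping": n_overlap,
        "n_total": len(ivs),
        "percent": 100.0 * n_overlap / len(ivs),
    }
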