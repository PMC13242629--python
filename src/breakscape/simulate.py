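"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of break-labeling
sequencing (sBLISS) experiments and their companion datasets: Poisson
background break density with spiked high-density hotspot clusters,
paired control/perturbed profiles whose category composition differs by
known redistribution factors, multi-dataset LAD bin memberships with a
target pairwise Jaccard, SNV lists with planted kataegis foci and a set
C>T fraction, and sequence windows with motif instances planted at
controlled distances from the window center.

Every generator is a pure function of its parameters and a seed. The
global seed expands to fixed per-component child streams (counter-based
spawn keys), so adding a new generator never perturbs existing streams,
and ground truth is returned alongside every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeDef, Interval
from .io import BreakProfile, Gene, GeneAnnotation, Transcript, VariantSet
import pandas as pd

__all__ = [
    "child_rng",
    "make_toy_genome",
    "make_toy_annotation",
    "simulate_breaks",
    "HotspotSpec",
    "simulate_condition_pair",
    "simulate_lad_sets",
    "KataegisSpec",
    "simulate_variants",
    "simulate_motif_windows",
]

# fixed stream indices per component (append-only)
STREAMS = {
    "genome": 0,
    "annotation": 1,
    "breaks": 2,
    "condition_pair": 3,
    "lads": 4,
    "variants": 5,
    "motif_windows": 6,
}


def child_rng(seed: int, stream: int | str) -> np.random.Generator:
    """Independent child stream of a global seed (counter-based spawn key)."""
    key = STREAMS[stream] if isinstance(stream, str) else int(stream)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


# ---------------------------------------------------------------------------
# genome & annotation


def make_toy_genome(
    chrom_lengths: dict[str, int] | list[int],
    seed: int,
    gc_fraction: float | None = None,
    with_sequence: bool = True,
) -> tuple[GenomeDef, dict[str, str]]:
    """A toy genome with i.i.d. random nucleotide sequence per chromosome.

    Bases are uniform over A/C/G/T unless ``gc_fraction`` is given, in
    which case G and C each carry gc_fraction/2 probability.
    """
    if isinstance(chrom_lengths, dict):
        sizes = dict(chrom_lengths)
    else:
        sizes = {f"chr{i + 1}": int(L) for i, L in enumerate(chrom_lengths)}
    genome = GenomeDef.from_dict(sizes)
    sequences: dict[str, str] = {}
    if with_sequence:
        rng = child_rng(seed, "genome")
        if gc_fraction is None:
            probs = np.full(4, 0.25)
        else:
            at = (1.0 - gc_fraction) / 2.0
            gc = gc_fraction / 2.0
            probs = np.array([at, gc, gc, at])
        bases = np.array(list("ACGT"))
        for chrom, L in sizes.items():
            sequences[chrom] = "".join(rng.choice(bases, size=L, p=probs))
    return genome, sequences


# plus-strand gene layout, offsets relative to gene start:
#   exon1 [0,600): UTR5 [0,200) + CDS [200,600)
#   intron [600,1100)
#   exon2 [1100,1300): noncoding (exon-only sequence)
#   intron [1300,1600)
#   exon3 [1600,2400): CDS [1600,2100) + UTR3 [2100,2400)
_GENE_LEN = 2400
_PLUS_LAYOUT = {
    "exons": ((0, 600), (1100, 1300), (1600, 2400)),
    "cds": ((200, 600), (1600, 2100)),
    "utr5": ((0, 200),),
    "utr3": ((2100, 2400),),
}


def _mirror(pairs, gene_len):
    return tuple(sorted((gene_len - e, gene_len - s) for s, e in pairs))


def make_toy_annotation(
    genome: GenomeDef, n_genes: int, seed: int, min_gap: int = 5000
) -> GeneAnnotation:
    """Non-overlapping genes with full transcript structure on both strands.

    Every gene has one transcript with a 5'UTR, two CDS exons, a noncoding
    middle exon (exon-only sequence), a 3'UTR and two introns; strands
    alternate with random jitter in gene placement. Raises if the genes
    cannot be packed with ``min_gap`` spacing.
    """
    rng = child_rng(seed, "annotation")
    slot = _GENE_LEN + min_gap
    capacity = [max(0, (L - min_gap) // slot) for L in genome.chrom_lengths]
    if sum(capacity) < n_genes:
        raise ValueError(
            f"cannot pack {n_genes} genes into genome (capacity {sum(capacity)})"
        )
    # distribute genes over chromosomes proportionally to capacity
    genes: dict[str, Gene] = {}
    transcripts: list[Transcript] = []
    gi = 0
    remaining = n_genes
    for chrom, cap in zip(genome.chrom_names, capacity):
        take = min(cap, remaining)
        remaining -= take
        for k in range(take):
            jitter = int(rng.integers(0, min_gap // 2 + 1))
            start = min_gap // 2 + k * slot + jitter
            end = start + _GENE_LEN
            strand = "+" if gi % 2 == 0 else "-"
            gid = f"gene{gi:04d}"
            sym = f"G{gi:04d}"
            genes[gid] = Gene(gid, sym, chrom, strand, start, end)
            if strand == "+":
                exons = tuple((start + s, start + e) for s, e in _PLUS_LAYOUT["exons"])
                cds = tuple((start + s, start + e) for s, e in _PLUS_LAYOUT["cds"])
                utr5 = tuple((start + s, start + e) for s, e in _PLUS_LAYOUT["utr5"])
                utr3 = tuple((start + s, start + e) for s, e in _PLUS_LAYOUT["utr3"])
                tss = start
            else:
                exons = tuple((start + s, start + e)
                              for s, e in _mirror(_PLUS_LAYOUT["exons"], _GENE_LEN))
                cds = tuple((start + s, start + e)
                            for s, e in _mirror(_PLUS_LAYOUT["cds"], _GENE_LEN))
                utr5 = tuple((start + s, start + e)
                             for s, e in _mirror(_PLUS_LAYOUT["utr5"], _GENE_LEN))
                utr3 = tuple((start + s, start + e)
                             for s, e in _mirror(_PLUS_LAYOUT["utr3"], _GENE_LEN))
                tss = end - 1
            transcripts.append(
                Transcript(f"tx{gi:04d}", gid, chrom, strand, tss,
                           exons, cds, utr5, utr3)
            )
            gi += 1
    if remaining:
        raise ValueError("gene packing failed")
    return GeneAnnotation(genes, transcripts)


# ---------------------------------------------------------------------------
# break profiles


@dataclass(frozen=True)
class HotspotSpec:
    """A spiked break cluster: n_hotspots clusters of events_per_hotspot
    events each, within width bp, placed in a category or explicit interval."""

    n_hotspots: int
    events_per_hotspot: int
    width: int
    category: str | None = None
    interval: Interval | None = None


def _sample_interval_positions(
    rng: np.random.Generator, intervals: list[Interval], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """n positions uniform over the base pairs of an interval set."""
    lengths = np.array([len(iv) for iv in intervals], dtype=np.int64)
    probs = lengths / lengths.sum()
    which = rng.choice(len(intervals), size=n, p=probs)
    chroms = np.array([intervals[i].chrom for i in which], dtype=object)
    offs = rng.integers(0, lengths[which])
    starts = np.array([intervals[i].start for i in which], dtype=np.int64)
    return chroms, starts + offs


def simulate_breaks(
    genome: GenomeDef,
    background_rate: float,
    hotspot_specs: list[HotspotSpec] | None = None,
    seed: int = 0,
    catalog=None,
    sample_id: str = "sim",
) -> tuple[BreakProfile, list[Interval]]:
    """Poisson background breaks plus spiked hotspot clusters.

    Background events are Poisson(rate * length) per chromosome, uniform
    within it. Each spiked hotspot places exactly ``events_per_hotspot``
    events uniformly within its width. Returns the profile and the ground
    truth hotspot intervals.
    """
    if background_rate < 0:
        raise ValueError("background rate must be >= 0")
    rng = child_rng(seed, "breaks")
    chroms: list = []
    positions: list = []
    truth: list[Interval] = []
    for chrom, L in zip(genome.chrom_names, genome.chrom_lengths):
        n = rng.poisson(background_rate * L)
        if n:
            chroms.extend([chrom] * n)
            positions.extend(rng.integers(0, L, size=n).tolist())
    for spec in hotspot_specs or []:
        for _ in range(spec.n_hotspots):
            if spec.interval is not None:
                iv = spec.interval
                if iv.chrom not in genome or iv.end > genome.length_of(iv.chrom):
                    raise ValueError(f"hotspot interval outside genome: {iv}")
                chrom = iv.chrom
                lo = int(rng.integers(iv.start, max(iv.start + 1, iv.end - spec.width)))
            elif spec.category is not None:
                if catalog is None:
                    raise ValueError("category hotspot spec requires a catalog")
                cat_ivs = [iv for iv in catalog.categories[spec.category]
                           if len(iv) >= spec.width]
                if not cat_ivs:
                    raise ValueError(f"no {spec.category} interval >= {spec.width} bp")
                c, p = _sample_interval_positions(rng, cat_ivs, 1)
                chrom = str(c[0])
                # anchor so the whole cluster stays inside the chosen interval
                host = next(iv for iv in cat_ivs
                            if iv.chrom == chrom and iv.start <= p[0] < iv.end)
                lo = int(min(max(host.start, p[0]), host.end - spec.width))
            else:
                raise ValueError("hotspot spec needs a category or interval")
            hi = lo + spec.width
            chroms.extend([chrom] * spec.events_per_hotspot)
            positions.extend(rng.integers(lo, hi, size=spec.events_per_hotspot).tolist())
            truth.append(Interval(chrom, lo, hi))
    if not positions:
        return BreakProfile.from_events(sample_id, []), truth
    strands = np.where(rng.random(len(positions)) < 0.5, "+", "-")
    profile = BreakProfile(
        sample_id,
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
        strands.astype(object),
    )
    return profile, truth


def simulate_condition_pair(
    catalog,
    total_events: int,
    control_props: dict[str, float],
    factors: dict[str, float],
    seed: int = 0,
    return_categories: bool = False,
):
    """Paired control/perturbed profiles with known category redistribution.

    Control events are drawn by category with ``control_props``; perturbed
    events with probabilities proportional to control_props * factors,
    renormalized. Within a category, an interval is sampled
    length-weighted, then a position uniform within it. With
    ``return_categories`` the sampled category label of every event is
    returned as ground truth (note: a position sampled inside category r's
    interval set may still be *assigned* to a higher-precedence category,
    because the raw interval sets overlap).
    """
    cats = list(control_props)
    p_ctrl = np.array([control_props[c] for c in cats], dtype=float)
    if not np.isclose(p_ctrl.sum(), 1.0):
        raise ValueError("control proportions must sum to 1")
    f = np.array([factors.get(c, 1.0) for c in cats], dtype=float)
    if (f <= 0).any():
        raise ValueError("redistribution factors must be positive")
    for c, pc in zip(cats, p_ctrl):
        if pc > 0 and not catalog.categories[c]:
            raise ValueError(f"category {c} is empty but has positive probability")
    p_pert = p_ctrl * f
    p_pert = p_pert / p_pert.sum()

    rng = child_rng(seed, "condition_pair")
    profiles = []
    labels = []
    for sample, probs in (("control", p_ctrl), ("perturbed", p_pert)):
        counts = rng.multinomial(total_events, probs)
        chroms_all = []
        pos_all = []
        labs_all = []
        for c, n in zip(cats, counts):
            if n == 0:
                continue
            ch, po = _sample_interval_positions(rng, catalog.categories[c], int(n))
            chroms_all.append(ch)
            pos_all.append(po)
            labs_all.append(np.full(int(n), c, dtype=object))
        chroms = np.concatenate(chroms_all) if chroms_all else np.array([], dtype=object)
        pos = np.concatenate(pos_all) if pos_all else np.array([], dtype=np.int64)
        strands = np.full(len(pos), ".", dtype=object)
        profiles.append(BreakProfile(sample, chroms, pos, strands))
        labels.append(np.concatenate(labs_all) if labs_all
                      else np.array([], dtype=object))
    if return_categories:
        return profiles[0], profiles[1], (labels[0], labels[1])
    return profiles[0], profiles[1]


# ---------------------------------------------------------------------------
# LAD sets


def simulate_lad_sets(
    genome: GenomeDef,
    bin_size: int,
    coverage: float,
    target_jaccard: float,
    n_sets: int,
    seed: int = 0,
):
    """Bin-grid LAD memberships with a target Jaccard against the first set.

    Set 1 is Bernoulli(coverage) per bin. Each further set rewires set 1:
    members are kept with probability k = 2J/(1+J) and non-members added
    with probability a = coverage*(1-k)/(1-coverage), which preserves the
    expected coverage and gives expected Jaccard J against set 1.

    Returns (grid, memberships, realized_jaccards_vs_set1).
    """
    from .lads import BinGrid, jaccard

    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    if not 0 <= target_jaccard <= 1:
        raise ValueError("target Jaccard must be in [0, 1]")
    grid = BinGrid(genome, bin_size)
    rng = child_rng(seed, "lads")
    base = rng.random(grid.n_bins) < coverage
    k = 2 * target_jaccard / (1 + target_jaccard)
    a = coverage * (1 - k) / (1 - coverage)
    if a > 1:
        raise ValueError("target Jaccard infeasible at this coverage")
    memberships = [base]
    for _ in range(n_sets - 1):
        u = rng.random(grid.n_bins)
        m = np.where(base, u < k, u < a)
        memberships.append(m)
    realized = [jaccard(base, m) for m in memberships[1:]]
    return grid, memberships, realized


# ---------------------------------------------------------------------------
# variants


@dataclass(frozen=True)
class KataegisSpec:
    n_foci: int
    variants_per_focus: int
    span: int  # bp


_SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def simulate_variants(
    genome: GenomeDef,
    n_background: int,
    ct_fraction: float,
    kataegis_spec: KataegisSpec | None = None,
    seed: int = 0,
    sample_id: str = "sim",
) -> tuple[VariantSet, list[Interval]]:
    """SNVs with a set pyrimidine-collapsed C>T share and planted foci.

    Background positions are uniform over the genome; each planted focus
    places ``variants_per_focus`` variants within ``span`` bp. Substitution
    classes are drawn so the collapsed C>T proportion equals
    ``ct_fraction`` in expectation, with random strand orientation
    (a C>T may be emitted as G>A). Returns the variants (1-based
    positions) and ground-truth focus intervals.
    """
    if not 0 <= ct_fraction <= 1:
        raise ValueError("ct_fraction must be in [0, 1]")
    rng = child_rng(seed, "variants")
    lengths = np.array(genome.chrom_lengths, dtype=np.int64)
    names = list(genome.chrom_names)

    chroms: list[str] = []
    positions: list[int] = []
    truth: list[Interval] = []

    if n_background:
        probs = lengths / lengths.sum()
        which = rng.choice(len(names), size=n_background, p=probs)
        for w in which:
            chroms.append(names[w])
            positions.append(int(rng.integers(1, lengths[w] + 1)))
    if kataegis_spec is not None:
        for _ in range(kataegis_spec.n_foci):
            w = int(rng.choice(len(names), p=lengths / lengths.sum()))
            L = int(lengths[w])
            span = min(kataegis_spec.span, L - 1)
            lo = int(rng.integers(1, L - span + 1))
            # spread variants evenly with jitter so the run is tight
            k = kataegis_spec.variants_per_focus
            base = np.linspace(0, span, k).astype(np.int64)
            pos = np.unique(lo + base)
            while len(pos) < k:  # resolve collisions deterministically
                extra = lo + rng.integers(0, span + 1, size=k - len(pos))
                pos = np.unique(np.concatenate([pos, extra]))
            pos = pos[:k]
            chroms.extend([names[w]] * k)
            positions.extend(int(p) for p in pos)
            truth.append(Interval(names[w], int(pos.min()) - 1, int(pos.max())))

    n = len(positions)
    if n == 0:
        rec = pd.DataFrame(columns=list(VariantSet.COLUMNS))
        rec["pos"] = rec["pos"].astype(np.int64) if len(rec) else rec.get("pos")
        return VariantSet(pd.DataFrame(
            {"chrom": [], "pos": np.array([], dtype=np.int64),
             "ref": [], "alt": [], "sample": []})), truth

    other = [c for c in _SPECTRUM_CLASSES if c != "C>T"]
    probs = [ct_fraction if c == "C>T" else (1 - ct_fraction) / 5
             for c in _SPECTRUM_CLASSES]
    classes = rng.choice(_SPECTRUM_CLASSES, size=n, p=probs)
    flips = rng.random(n) < 0.5
    refs, alts = [], []
    for cls, flip in zip(classes, flips):
        ref, alt = cls.split(">")
        if flip:
            ref, alt = _COMP[ref], _COMP[alt]
        refs.append(ref)
        alts.append(alt)

    rec = pd.DataFrame({
        "chrom": chroms,
        "pos": np.array(positions, dtype=np.int64),
        "ref": refs,
        "alt": alts,
        "sample": sample_id,
    })
    return VariantSet(rec), truth


# ---------------------------------------------------------------------------
# motif windows


def _realize_motif(motif: str, rng: np.random.Generator) -> str:
    from .motifs import IUPAC_CODES

    return "".join(rng.choice(sorted(IUPAC_CODES[c.upper()])) for c in motif)


def simulate_motif_windows(
    n: int,
    half_width: int,
    motif: str,
    placement_prob: float,
    central_sd: float,
    seed: int = 0,
) -> tuple[list[str], list[float | None]]:
    """Random windows with motif instances planted near the center.

    Each window is 2*half_width+1 random bases. With probability
    ``placement_prob`` a concrete realization of the IUPAC motif is written
    so that its midpoint sits at center + round(N(0, central_sd)),
    truncated to the window. Returns the windows and, per window, the
    realized midpoint offset from the center (None when nothing was
    planted).
    """
    if len(motif) >= 2 * half_width + 1:
        raise ValueError("motif must be shorter than the window")
    rng = child_rng(seed, "motif_windows")
    bases = np.array(list("ACGT"))
    wlen = 2 * half_width + 1
    m = len(motif)
    windows: list[str] = []
    offsets: list[float | None] = []
    for _ in range(n):
        seq = rng.choice(bases, size=wlen)
        planted: float | None = None
        if rng.random() < placement_prob:
            delta = int(round(rng.normal(0.0, central_sd)))
            start = half_width + delta - (m - 1) // 2
            start = min(max(start, 0), wlen - m)
            inst = _realize_motif(motif, rng)
            seq[start : start + m] = list(inst)
            planted = (start + (m - 1) / 2.0) - half_width
        windows.append("".join(seq))
        offsets.append(planted)
    return windows, offsets
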