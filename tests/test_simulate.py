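"""Synthetic-data generators: determinism, construction guarantees, bounds."""

import numpy as np
import pytest

from breakscape.genome import GenomeDef, Interval
from breakscape.regions import CATEGORIES, build_region_catalog
from breakscape.simulate import (
    HotspotSpec,
    KataegisSpec,
    make_toy_annotation,
    make_toy_genome,
    simulate_breaks,
    simulate_condition_pair,
    simulate_lad_sets,
    simulate_motif_windows,
    simulate_variants,
)


def test_genome_deterministic_and_lengths():
    g1, s1 = make_toy_genome([100_000, 80_000], seed=1)
    g2, s2 = make_toy_genome([100_000, 80_000], seed=1)
    assert g1 == g2 and s1 == s2
    assert all(len(s1[c]) == g1.length_of(c) for c in g1.chrom_names)
    g3, s3 = make_toy_genome([100_000, 80_000], seed=2)
    assert s3 != s1


def test_genome_gc_fraction_within_binomial_bound():
    L = 100_000
    _, seqs = make_toy_genome([L], seed=3, gc_fraction=0.5)
    gc = sum(seqs["chr1"].count(b) for b in "GC")
    sd = np.sqrt(L * 0.5 * 0.5)
    assert abs(gc - L * 0.5) <= 3 * sd


def test_annotation_structure_guarantees(toy_genome):
    ann = make_toy_annotation(toy_genome, 10, seed=4)
    assert len(ann.genes) == 10
    spans = sorted((g.chrom, g.start, g.end) for g in ann.genes.values())
    for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
        assert c1 != c2 or e1 <= s2  # non-overlapping
    assert {g.strand for g in ann.genes.values()} == {"+", "-"}
    for t in ann.transcripts:
        assert len(t.cds) >= 2 and t.utr5 and t.utr3 and len(t.exons) >= 3
        # exons contain CDS and UTRs
        exon_bp = {p for s, e in t.exons for p in range(s, e)}
        for pairs in (t.cds, t.utr5, t.utr3):
            for s, e in pairs:
                assert set(range(s, e)) <= exon_bp


def test_annotation_infeasible_packing_errors():
    tiny, _ = make_toy_genome([20_000], seed=5, with_sequence=False)
    with pytest.raises(ValueError, match="pack"):
        make_toy_annotation(tiny, 50, seed=5)


def test_catalog_from_synthetic_covers_all_categories(toy_catalog):
    bp = toy_catalog.category_bp()
    assert all(bp[c] > 0 for c in CATEGORIES)


def test_breaks_empty_when_rate_zero(toy_genome):
    prof, truth = simulate_breaks(toy_genome, 0.0, seed=6)
    assert prof.n_events == 0 and truth == []


def test_breaks_poisson_bound():
    genome = GenomeDef(("chr1",), (100_000,))
    prof, _ = simulate_breaks(genome, 5e-4, seed=7)
    mean = 50
    assert abs(prof.n_events - mean) <= 4 * np.sqrt(mean)


def test_spiked_hotspot_events_inside_window(toy_genome):
    iv = Interval("chr1", 50_000, 60_000)
    prof, truth = simulate_breaks(
        toy_genome, 0.0, [HotspotSpec(1, 30, 50, interval=iv)], seed=8)
    assert len(truth) == 1
    t = truth[0]
    assert t.end - t.start == 50
    inside = ((prof.chroms == t.chrom)
              & (prof.positions >= t.start) & (prof.positions < t.end)).sum()
    assert inside == 30


def test_hotspot_outside_genome_errors(toy_genome):
    with pytest.raises(ValueError):
        simulate_breaks(toy_genome, 0.0,
                        [HotspotSpec(1, 5, 50, interval=Interval("chrZ", 0, 100))],
                        seed=9)


def test_condition_pair_deterministic_and_null(toy_catalog):
    props = {c: 1 / 7 for c in CATEGORIES}
    a1, b1 = simulate_condition_pair(toy_catalog, 1_000, props, {}, seed=10)
    a2, b2 = simulate_condition_pair(toy_catalog, 1_000, props, {}, seed=10)
    assert (a1.positions == a2.positions).all()
    assert (b1.positions == b2.positions).all()
    assert a1.n_events == b1.n_events == 1_000


def test_condition_pair_redistribution_factor(toy_catalog):
    """f_TSS = 3 shifts the perturbed TSS share to 3p/(1+2p) = 1/3 of events."""
    props = {c: 1 / 7 for c in CATEGORIES}
    n = 20_000
    _, _, (ctrl_cats, pert_cats) = simulate_condition_pair(
        toy_catalog, n, props, {"TSS": 3.0}, seed=11, return_categories=True)
    expected_share = 3 / 9  # renormalized multinomial: 3p / (1 + 2p), p = 1/7
    share = (pert_cats == "TSS").mean()
    sd = np.sqrt(expected_share * (1 - expected_share) / n)
    assert abs(share - expected_share) <= 5 * sd
    ctrl_share = (ctrl_cats == "TSS").mean()
    assert abs(ctrl_share - 1 / 7) <= 5 * np.sqrt((1 / 7) * (6 / 7) / n)


def test_condition_pair_empty_category_errors(toy_catalog):
    props = {c: 0.0 for c in CATEGORIES}
    props["TSS"] = 1.0
    bad = dict(props)
    # construct a catalog copy with an emptied category
    import copy

    cat2 = copy.deepcopy(toy_catalog)
    cat2.categories["TSS"] = []
    with pytest.raises(ValueError, match="empty"):
        simulate_condition_pair(cat2, 100, bad, {}, seed=12)


def test_lad_sets_extremes(toy_genome):
    _, mems, realized = simulate_lad_sets(toy_genome, 10_000, 0.4, 1.0, 3, seed=13)
    assert all((m == mems[0]).all() for m in mems[1:])
    assert realized == [1.0, 1.0]
    _, mems0, realized0 = simulate_lad_sets(toy_genome, 1_000, 0.3, 0.0, 2, seed=13)
    assert realized0[0] <= 0.05


def test_variants_construction():
    genome = GenomeDef(("chr1",), (10_000_000,))
    vs, foci = simulate_variants(genome, 0, 0.7, KataegisSpec(1, 6, 2_500), seed=14)
    assert vs.n_variants == 6 and len(foci) == 1
    f = foci[0]
    # half-open interval over k variants spread across <= 2500 bp
    assert f.end - f.start <= 2_501
    # mean IMD of the planted run is at most span/(k-1) <= 500
    pos = np.sort(vs.records["pos"].to_numpy())
    assert np.diff(pos).mean() <= 500
    empty, none = simulate_variants(genome, 0, 0.5, None, seed=15)
    assert empty.n_variants == 0 and none == []


def test_motif_windows_constructions():
    wins, offs = simulate_motif_windows(50, 100, "WGCW", 0.0, 5.0, seed=16)
    assert all(o is None for o in offs)
    wins, offs = simulate_motif_windows(50, 100, "WGCW", 1.0, 0.0, seed=17)
    assert all(o == 0.5 or o == -0.5 or abs(o) < 1 for o in offs)  # even-length motif
    assert all(len(w) == 201 for w in wins)


def test_motif_planted_offsets_clt_bound():
    _, offs = simulate_motif_windows(500, 100, "WGCW", 1.0, 10.0, seed=18)
    planted = np.array([o for o in offs if o is not None])
    assert abs(planted.mean()) <= 4 * 10.0 / np.sqrt(len(planted))


def test_generators_replayable_from_same_seed(toy_genome):
    p1, _ = simulate_breaks(toy_genome, 3e-4, seed=19)
    p2, _ = simulate_breaks(toy_genome, 3e-4, seed=19)
    assert (p1.positions == p2.positions).all()
    v1, _ = simulate_variants(toy_genome, 100, 0.6, None, seed=19)
    v2, _ = simulate_variants(toy_genome, 100, 0.6, None, seed=19)
    assert v1.records.equals(v2.records)
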