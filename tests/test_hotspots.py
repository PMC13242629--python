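"""Hotspot calling: pileup oracle, filters, recovery and densities."""

import numpy as np
import pytest

from breakscape.genome import GenomeDef, Interval
from breakscape.hotspots import (
    HotspotParams,
    HotspotSet,
    build_pileup,
    call_hotspots,
    dsb_density_per_chrom,
    dsb_density_per_region,
    unique_hotspots,
)
from breakscape.io import BreakProfile
from breakscape.simulate import HotspotSpec, simulate_breaks

G100K = GenomeDef(("chr1",), (100_000,))


def profile_at(positions, chrom="chr1", sample="s"):
    return BreakProfile.from_events(sample, [(chrom, p, ".") for p in positions])


def test_pileup_single_break_default_params():
    tracks = build_pileup(profile_at([1000]), G100K)
    t = tracks["chr1"]
    dense = t.to_array()
    assert (dense[900:1100] == 1).all()
    assert dense[:900].sum() == 0 and dense[1100:].sum() == 0


def test_pileup_two_breaks_same_position():
    t = build_pileup(profile_at([1000, 1000]), G100K)["chr1"]
    assert t.to_array().max() == 2


def test_pileup_clipped_at_chromosome_edges():
    t = build_pileup(profile_at([10]), G100K)["chr1"]
    dense = t.to_array()
    assert (dense[0:110] == 1).all()  # fragment [-90,110) clipped to [0,110)
    assert dense[110:].sum() == 0


def test_pileup_matches_brute_force_oracle(rng):
    tiny = GenomeDef(("chr1",), (10_000,))
    params = HotspotParams(shift=-100, extend=200)
    pos = rng.integers(0, 10_000, size=80)
    prof = profile_at(pos.tolist())
    dense = build_pileup(prof, tiny, params)["chr1"].to_array()
    oracle = np.zeros(10_000, dtype=int)
    for x in pos:
        s = max(0, x + params.shift)
        e = min(10_000, x + params.shift + params.extend)
        oracle[s:e] += 1
    assert (dense == oracle).all()


def test_call_hotspots_empty_profile():
    hs = call_hotspots(profile_at([]), G100K)
    assert len(hs) == 0


def test_call_hotspots_spiked_cluster(rng):
    """50 uniform breaks (lambda=0.1) plus 30 breaks in 50 bp -> one hotspot."""
    bg = rng.integers(0, 100_000, size=50).tolist()
    cluster = rng.integers(50_000, 50_050, size=30).tolist()
    hs = call_hotspots(profile_at(bg + cluster), G100K)
    assert len(hs) == 1
    h = hs.hotspots[0]
    assert h.pileup >= 30
    # lambda = 80 events * 200 bp / 100 kb = 0.16, so FE >= 30/0.16
    assert h.fold_enrichment >= 30 / 0.16
    assert h.interval.start <= 50_025 <= h.interval.end

    # same cluster, pileup filter raised above attainable pileup
    strict = HotspotParams(pileup_min=200)
    assert len(call_hotspots(profile_at(bg + cluster), G100K, strict)) == 0


def test_filter_monotonicity(rng):
    prof, _ = simulate_breaks(
        G100K, 5e-4,
        [HotspotSpec(3, 25, 50, interval=Interval("chr1", k, k + 5_000))
         for k in (10_000, 40_000, 80_000)],
        seed=5,
    )
    base = len(call_hotspots(prof, G100K))
    for params in (
        HotspotParams(q_max=0.01),
        HotspotParams(fe_min=8),
        HotspotParams(pileup_min=20),
    ):
        assert len(call_hotspots(prof, G100K, params)) <= base


def test_hotspot_recovery_on_spiked_profiles():
    """Sensitivity and precision >= 0.95 against planted clusters."""
    genome = GenomeDef(("chr1", "chr2"), (500_000, 500_000))
    tp = fp = fn = 0
    for seed in range(10):
        prof, truth = simulate_breaks(
            genome, 2e-4,  # lambda = 0.2 * 200/1000 => 0.04 frag coverage
            [HotspotSpec(4, 20, 50, interval=Interval("chr1", 50_000 + 100_000 * k,
                                                      50_000 + 100_000 * k + 10_000))
             for k in range(4)]
            + [HotspotSpec(4, 20, 50, interval=Interval("chr2", 50_000 + 100_000 * k,
                                                        50_000 + 100_000 * k + 10_000))
               for k in range(4)],
            seed=seed,
        )
        hs = call_hotspots(prof, genome)
        for t in truth:
            if any(h.interval.overlaps(t) for h in hs.hotspots):
                tp += 1
            else:
                fn += 1
        for h in hs.hotspots:
            if not any(h.interval.overlaps(t) for t in truth):
                fp += 1
    sensitivity = tp / (tp + fn)
    precision = tp / (tp + fp)
    assert sensitivity >= 0.95
    assert precision >= 0.95


def test_unique_hotspots():
    prof = profile_at([1000] * 20 + [5000] * 20)
    hs = call_hotspots(prof, G100K)
    assert len(hs) == 2
    empty = HotspotSet("b", hs.params, [])
    assert len(unique_hotspots(hs, empty)) == 2
    assert len(unique_hotspots(hs, hs)) == 0
    only_first = HotspotSet("b", hs.params, hs.hotspots[:1])
    assert unique_hotspots(hs, only_first).hotspots == hs.hotspots[1:]


def test_unique_hotspots_matches_pairwise_oracle(rng):
    def random_set(n):
        spots = []
        for _ in range(n):
            s = int(rng.integers(0, 99_000))
            iv = Interval("chr1", s, s + int(rng.integers(50, 500)))
            spots.append(
                __import__("breakscape.hotspots", fromlist=["Hotspot"]).Hotspot(
                    iv, (iv.start + iv.end) // 2, 12, 10.0, 1e-9, 1e-8)
            )
        return HotspotSet("x", HotspotParams(), sorted(
            spots, key=lambda h: h.interval.start))

    for _ in range(5):
        a, b = random_set(15), random_set(15)
        got = {h.interval for h in unique_hotspots(a, b).hotspots}
        want = {
            h.interval for h in a.hotspots
            if not any(h.interval.overlaps(x.interval) for x in b.hotspots)
        }
        assert got == want


def test_dsb_density_per_chrom():
    genome = GenomeDef(("chr1", "chr2"), (2_000_000, 1_000_000))
    prof = BreakProfile.from_events(
        "s", [("chr1", i, ".") for i in range(100)] + [("chr2", 5, ".")]
    )
    df = dsb_density_per_chrom(prof, genome).set_index("chrom")
    assert df.loc["chr1", "breaks_per_mb"] == pytest.approx(50.0)
    assert df.loc["chr2", "breaks_per_mb"] == pytest.approx(1.0)
    # conservation: densities recombine to the total event count
    total = (df["breaks_per_mb"] * df["length_bp"] / 1e6).sum()
    assert total == pytest.approx(prof.n_events)


def test_dsb_density_per_region_counts_sum(toy_genome, toy_catalog):
    prof, _ = simulate_breaks(toy_genome, 1e-3, seed=3)
    df = dsb_density_per_region(prof, toy_catalog)
    assert df["n_breaks"].sum() == prof.n_events
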