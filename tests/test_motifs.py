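"""IUPAC scanning, positional profiles and central enrichment."""

import numpy as np
import pytest

from breakscape.genome import GenomeDef, Interval
from breakscape.motifs import (
    central_enrichment,
    iupac_scan,
    motif_site_genomic_distribution,
    peak_overlap_percentage,
    positional_profile,
    reverse_complement,
)
from breakscape.simulate import simulate_motif_windows


def test_scan_wgcw_example():
    hits = iupac_scan("TTGCAA", "WGCW", both_strands=False)
    assert [o for o, _ in hits] == [1]  # "TGCA"


def test_wgcw_is_revcomp_palindromic():
    assert reverse_complement("WGCW") == "WGCW"
    seq = "ATGCATTGCAATGCTT"
    fwd = {o for o, _ in iupac_scan(seq, "WGCW", both_strands=False)}
    both = {o for o, _ in iupac_scan(seq, "WGCW", both_strands=True)}
    assert fwd == both


def test_scan_no_matches_and_invalid_code():
    assert iupac_scan("CCCCCC", "WRC") == []
    with pytest.raises(ValueError):
        iupac_scan("ACGT", "WXC")


def test_strand_closure_property(rng):
    bases = np.array(list("ACGT"))
    for motif in ("WRC", "WRCY", "WGCW", "GAGA", "RYN"):
        seq = "".join(rng.choice(bases, size=300))
        both = {o for o, _ in iupac_scan(seq, motif, both_strands=True)}
        fwd = {o for o, _ in iupac_scan(seq, motif, both_strands=False)}
        rc = {o for o, _ in iupac_scan(seq, reverse_complement(motif),
                                       both_strands=False)}
        assert both == fwd | rc


def test_case_insensitive_matching():
    assert iupac_scan("ttgcaa", "wgcw", both_strands=False)


def test_profile_centered_motifs_peak_at_center():
    windows, _ = simulate_motif_windows(300, 50, "WGCW", 1.0, 0.0, seed=3)
    prof = positional_profile(windows, "WGCW", half_width=50)
    # planted exactly centered: raw curve maximal at the centered start offset
    center_start = 50 - (len("WGCW") - 1) // 2
    assert int(np.argmax(prof.raw_curve)) == center_start


def test_profile_no_matches_gives_zero_curve():
    windows = ["C" * 201 for _ in range(5)]
    prof = positional_profile(windows, "WGCW")
    assert prof.n_with_site == 0
    assert not prof.raw_curve.any()


def test_profile_curve_length_and_truncated_windows():
    windows, _ = simulate_motif_windows(50, 100, "WGCW", 1.0, 5.0, seed=4)
    prof = positional_profile(windows + ["ACGT"], "WGCW")
    assert prof.n_dropped == 1
    assert len(prof.raw_curve) == 2 * 100 - 4 + 2


def test_profile_mode_near_center_with_spread(rng):
    windows, _ = simulate_motif_windows(500, 100, "WGCW", 1.0, 10.0, seed=5)
    prof = positional_profile(windows, "WGCW")
    m = len("WGCW")
    mode_mid = int(np.argmax(prof.curve)) + (m - 1) / 2
    assert abs(mode_mid - 100) <= 5


def test_central_enrichment_all_central():
    windows, _ = simulate_motif_windows(200, 100, "WGCW", 1.0, 0.0, seed=6)
    prof = positional_profile(windows, "WGCW")
    ce = central_enrichment(prof, central_half_width=25)
    assert ce.p_value < 1e-6
    assert ce.ratio == pytest.approx(1 / ce.null_prob, rel=0.2)


def test_central_enrichment_specific_vs_control():
    """Centered WGCW is significant; uniformly placed GAGA control is not."""
    rng = np.random.default_rng(8)
    windows, _ = simulate_motif_windows(300, 100, "WGCW", 0.9, 8.0, seed=7)
    prof = positional_profile(windows, "WGCW")
    assert central_enrichment(prof).p_value < 1e-6
    # GAGA occurrences in the same windows arise only by chance -> uniform
    ctrl = positional_profile(windows, "GAGA")
    if ctrl.n_with_site >= 10:
        assert central_enrichment(ctrl).p_value > 1e-4


def test_central_enrichment_null_calibration():
    """Uniform placement: p < 0.05 in <= 10% of replicates, ratio near 1."""
    hits = 0
    ratios = []
    for seed in range(60):
        windows, _ = simulate_motif_windows(150, 100, "GAGA", 0.0, 1.0, seed=seed)
        prof = positional_profile(windows, "GAGA")
        if prof.n_with_site < 10:
            continue
        ce = central_enrichment(prof)
        ratios.append(ce.ratio)
        if ce.p_value < 0.05:
            hits += 1
    assert hits / 60 <= 0.1
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.25)


def test_best_site_tie_breaks_toward_lower_offset():
    # two equidistant matches around the center: lower offset wins
    from breakscape.motifs import _best_offset

    assert _best_offset([40, 56], 4, 49.5) == 40


def test_site_distribution_sums_to_100(toy_catalog):
    sites = [("chr1", 100), ("chr1", 50_000), ("chr2", 30_000)]
    dist = motif_site_genomic_distribution(sites, toy_catalog)
    assert sum(dist.values()) == pytest.approx(100.0)
    desert = motif_site_genomic_distribution([("chr1", 100)], toy_catalog)
    assert desert["Intergenic"] == pytest.approx(100.0)


def test_extract_windows_from_sequences():
    from breakscape.motifs import extract_windows

    seqs = {"chr1": "ACGT" * 100}
    wins = extract_windows(seqs, [("chr1", 200), ("chr1", 2)], half_width=10)
    assert len(wins[0]) == 21
    assert wins[0][10] == seqs["chr1"][200]
    assert len(wins[1]) == 13  # truncated at the chromosome start


def test_motifs_cli_fasta_path(tmp_path):
    import numpy as np
    from click.testing import CliRunner

    from breakscape.cli import main

    rng = np.random.default_rng(9)
    seq = list(rng.choice(list("ACGT"), size=5_000))
    for s in range(300, 4_700, 220):
        seq[s : s + 4] = list("AGCA")  # WGCW instance at each summit
    (tmp_path / "g.fa").write_text(">chr1\n" + "".join(seq) + "\n")
    with open(tmp_path / "s.bed", "w") as fh:
        for s in range(300, 4_700, 220):
            fh.write(f"chr1\t{s}\t{s+4}\n")
    res = CliRunner().invoke(main, [
        "motifs", "--summits", str(tmp_path / "s.bed"),
        "--fasta", str(tmp_path / "g.fa"), "--motif", "WGCW",
        "--out", str(tmp_path / "curve.tsv")])
    assert res.exit_code == 0, res.output
    assert "central_p" in res.output


def test_peak_overlap_percentage():
    spots = [Interval("chr1", 0, 100), Interval("chr1", 1_000, 1_100)]
    everywhere = [Interval("chr1", 0, 10_000)]
    assert peak_overlap_percentage(spots, everywhere)["percent"] == 100.0
    assert peak_overlap_percentage(spots, [Interval("chr1", 5_000, 5_100)])["percent"] == 0.0
    res = peak_overlap_percentage(spots, [Interval("chr1", 50, 60)])
    assert res == {"n_overlapping": 1, "n_total": 2, "percent": 50.0}
    with pytest.raises(ValueError):
        peak_overlap_percentage([], everywhere)
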