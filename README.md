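# breakscape

Downstream analysis of genome-wide DNA double-strand-break (DSB) maps, as
produced by break-labeling sequencing protocols such as sBLISS (one BED
record per unique break after UMI deduplication). The package covers the
full post-alignment workflow used to ask where breaks concentrate in the
genome and how a perturbation — e.g. Lamin B1 depletion in B cells —
redistributes them:

- **Hotspot calling** — each break is turned into a shift/extend fragment
  (defaults −100 bp / 200 bp, the 200-bp window centered on the break);
  candidate peaks are tested against a single genome-wide Poisson
  expectation λ = n·extend/G, and hotspots must satisfy q < 0.05 (BH),
  fold enrichment > 4 and pileup > 10.
- **Exclusive feature annotation** — seven merged, strand-agnostic
  categories (CDS, 5′UTR, 3′UTR, TSS ±250 bp, promoter −2000..+500 bp,
  exon-only, intergenic) with a fixed assignment precedence
  CDS → 5′UTR → 3′UTR → TSS → Promoter → Exon → Intergenic, so every
  hotspot center is counted exactly once.
- **Control-baseline O/E enrichment** — with per-category counts C_r
  (control) and O_r (perturbed), p_r = C_r/ΣC, E_r = p_r·ΣO and
  O/E_r = (O_r + ε)/(E_r + ε) with ε = 0.5, reported as log₂(O/E_r)
  with per-category exact tests and BH q-values.
- **LAD analysis** — lamina-associated-domain interval sets harmonized to
  a common bin grid (10-kb bins), constitutive/facultative consensus
  (cLAD = in all datasets, fLAD = proper subset), Jaccard and base-pair
  concordance, genome coverage, and hotspot partition inside/outside LADs.
- **Gene-level burden** — per-gene break counts (zeros retained), DSB- and
  hotspot-positive driver-gene classification, and paired TSS-vs-gene-body
  break density with a Wilcoxon signed-rank test.
- **Motif centrality** — IUPAC scanning of AID hotspot motifs
  (WRC / WRCY / WGCW; W={A,T}, R={A,G}, Y={C,T}) in ±100-bp windows
  around summits, best-site positional profiles, and a
  multiplicity-corrected binomial test for central enrichment.
- **Mutation analysis** — pyrimidine-collapsed substitution spectra (C>T
  share), inter-mutation distances, and kataegis detection under the
  classical (≥6 variants, mean IMD ≤ 1 kb) and relaxed (≥3, ≤ 50 kb)
  criteria.
- **Synthetic data** — every input the pipeline consumes can be generated
  with known ground truth (spiked hotspots, known redistribution factors,
  target Jaccard, planted kataegis foci, centrally planted motifs), which
  is how the whole pipeline is tested without external downloads.

## Worked example

```python
from breakscape.simulate import (make_toy_genome, make_toy_annotation,
                                 simulate_breaks, HotspotSpec)
from breakscape.regions import build_region_catalog, hotspot_category_counts
from breakscape.hotspots import call_hotspots
from breakscape.enrichment import oe_enrichment, enrichment_report

genome, _ = make_toy_genome([200_000, 150_000], seed=1, with_sequence=False)
annotation = make_toy_annotation(genome, 20, seed=1)
catalog = build_region_catalog(annotation, genome)

profile, truth = simulate_breaks(
    genome, background_rate=2e-4,
    hotspot_specs=[HotspotSpec(n_hotspots=4, events_per_hotspot=30,
                               width=50, category="TSS")],
    seed=1, catalog=catalog)
hotspots = call_hotspots(profile, genome)
print(f"{profile.n_events} breaks -> {len(hotspots)} hotspots")
print(hotspots.to_frame().round(3).to_string(index=False))
```

prints

```
181 breaks -> 4 hotspots
chrom  start    end  summit  pileup  fold_enrichment  p_value  q_value
 chr1  13178  13425   13291      31          299.724      0.0      0.0
 chr1 106167 106413  106290      30          290.055      0.0      0.0
 chr1 121817 122055  121937      30          290.055      0.0      0.0
 chr1 147553 147797  147675      30          290.055      0.0      0.0
```

All four planted 30-break clusters are recovered: each has pileup ≈ 30
against an expected background coverage of ~0.1 fragments/bp, hence fold
enrichment near 300 and vanishing q. Annotating the summits
(`hotspot_category_counts(hotspots, catalog)`) assigns three to TSS
windows and one to a 5′UTR — the cluster centers were planted inside TSS
windows, and the precedence rule hands overlapping exonic positions to
the higher-ranked category.

The O/E engine on a hand-computable table:

```python
table = oe_enrichment({"TSS": 10, "Prom": 30, "Inter": 60},
                      {"TSS": 40, "Prom": 30, "Inter": 30})
print(enrichment_report(table).round(4).to_string())
```

```
           C   O  p_r     E      oe  log2_oe  p_value  q_value significance
category
TSS       10  40  0.1  10.0  3.8571   1.9475      0.0      0.0          ***
Inter     60  30  0.6  60.0  0.5041  -0.9881      0.0      0.0          ***
Prom      30  30  0.3  30.0  1.0000   0.0000      1.0      1.0
```

TSS hotspots are ~4× over-represented relative to the control composition
(log₂ O/E = +1.95), intergenic hotspots depleted (−0.99), promoters
unchanged.

## Command line

Every stage is also a subcommand of the `breakscape` CLI:
`simulate`, `hotspots`, `annotate`, `enrich`, `lads`, `genes`, `motifs`,
`mutations`, and `run-all`, which executes the full workflow from a YAML
config and writes per-stage tables, a `summary.json`, the resolved config
and a MANIFEST of completed stages:

```sh
breakscape run-all --config config.yaml --out-dir results/
```

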