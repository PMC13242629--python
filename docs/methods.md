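# Methods

This note documents the statistical model behind every stage, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical choices that matter for reproducing results.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention) internally; VCF
positions are converted on read and back on write. All region arithmetic is
strand-agnostic; break strand is retained but unused by default. Interval
merge treats book-ended intervals (`end == start`) as mergeable, matching
`bedtools merge`. Chromosome-name harmonization ("1" → "chr1") is an
explicit reader flag, off by default; records on chromosomes absent from
the genome definition are dropped with a logged count rather than failing,
since real break files routinely carry unplaced scaffolds.

## Hotspot calling

Each break at position x contributes one fragment [x−100, x+100) by
default (shift −100 bp, extend 200 bp), clipped at chromosome edges rather
than discarded. The pileup at a base is the number of covering fragments.

There is no local background model: the expectation is the single
genome-wide rate λ = n_events · extend / G (expected fragment coverage per
bp). Candidate peaks are maximal runs of pileup ≥ 2 — the simplest
candidate definition that keeps the Benjamini–Hochberg correction
well-defined over a finite list — and each candidate is tested at its
maximum pileup with an upper-tail Poisson p-value. BH runs across the
candidates of one sample, never across samples. Retained hotspots satisfy
all of q < 0.05, fold enrichment = pileup/λ > 4, and pileup > 10 (strict
inequalities, as conventionally printed). The summit is the midpoint of
the leftmost segment attaining the maximum pileup; midpoints of
even-length spans round down. This is a deliberately minimal peak model,
not a re-implementation of any external caller's internals (no local
lambda, no model building, no paired-control lambda).

Fold enrichment uses fragment coverage for λ, not events/bp, so that the
ratio is on the same scale as pileup.

## Exclusive region catalog

Seven merged, strand-agnostic interval categories are built from a gene
annotation: CDS, 5′UTR, 3′UTR from transcripts directly; TSS windows
±250 bp around transcript starts; promoters −2000..+500 bp relative to the
TSS, oriented by strand before being stored strand-agnostic; exon-only
sequence = exons minus (CDS ∪ UTRs); intergenic = genome complement of
gene bodies. A point is assigned to exactly one label by the fixed
precedence CDS → 5′UTR → 3′UTR → TSS → Promoter → Exon → Intergenic.

Intronic positions — inside a gene body but in none of the above — are a
gap in the seven-way scheme. They receive an explicit "Intronic/other"
label, reported separately and excluded from seven-way summaries by
default; `intronic_as_intergenic=True` folds them into Intergenic
instead. Both behaviors are exposed because either reading of the
seven-way scheme is defensible. Hotspots are assigned via a single
coordinate (summit when available, else interval midpoint, rounding down).

## Observed/Expected enrichment

With per-category counts C_r (control) and O_r (perturbed):
p_r = C_r/ΣC, E_r = p_r·ΣO, O/E_r = (O_r + ε)/(E_r + ε) with pseudocount
ε = 0.5, reported as log₂(O/E_r). The pseudocount stabilizes
low-expectation categories and enters the ratio only — never the test
counts. ΣE = ΣO holds exactly before the pseudocount, and the baseline is
scale-invariant in the control counts.

Per-category significance defaults to **Fisher's exact test** on the 2×2
table (O_r vs ΣO−O_r; C_r vs ΣC−C_r). The natural alternative — an exact
binomial test of O_r against p_r treated as a fixed probability — ignores
that the control composition is itself estimated from ΣC events; the
neglected variance roughly doubles the variance of the observed-vs-expected
contrast when both arms are the same size, and measured calibration under
the package's own null simulation (equal redistribution, 5,000 events per
arm, 200 replicates) shows ~7.4% of categories at q < 0.05 versus ~0.8%
for Fisher. The binomial variant is retained behind `test="binomial"` for
comparison. q-values are BH across the categories of one comparison (7
tests), not across comparisons. Significance tiers are strict:
\* q < 0.05, \*\* q < 0.01, \*\*\* q < 0.001.

## LAD consensus and concordance

LAD interval sets are projected onto a fixed bin grid (10-kb bins for the
multi-dataset consensus; 100-kb bins for ChIP-signal domains; the last bin
of a chromosome may be short). A bin belongs to a dataset when the merged
intervals cover ≥ `min_frac` of it; the default 0.5 is a top-level knob
because published concordance numbers are sensitive to this unstated
choice — `min_frac=0` gives any-overlap membership. cLADs are bins present
in all datasets, fLADs bins in a proper non-empty subset; the partition
identities (cLAD ∩ fLAD = ∅, cLAD ∪ fLAD = union) are checked exactly.
Concordance is the Jaccard index on bin memberships (defined as 1 when
both sets are empty) plus base-pair overlap fractions on the raw merged
intervals. Hotspot–LAD partition uses any-overlap semantics; when a
hotspot touches both cLAD and fLAD bins, cLAD wins (the consensus is the
stronger claim). ChIP domains on the coarse grid use an invented but
simple rule — a bin is enriched when its (optionally input-normalized)
signal exceeds 1.5× the genome-wide median; adjacent enriched bins merge —
exposed as parameters because only the bin size is standard.

## Gene-level burden

Gene body = annotated gene span including introns. Break counts are summed
per gene with zero-count genes retained. Driver summaries use the full
curated gene list as denominator by default, so symbols that fail to
resolve against the annotation count as negatives (configurable to exclude
them). A gene is DSB-positive with ≥1 break in the body and
hotspot-positive with ≥1 overlapping called hotspot. The TSS-vs-body
density comparison pairs breaks/kb in the ±250-bp TSS window against the
gene body on the same genes and reports a two-sided Wilcoxon signed-rank
p-value (the two densities are measured on the same genes); an unpaired
rank-sum variant is available. When no gene has a nonzero difference the
test is undefined and reported as NaN. DEG filtering implements both
printed threshold presets — A: padj < 0.05 and |log₂FC| > 0.5; B:
padj < 0.05 and log₂FC > 1 (up-regulated only) — with strict inequalities;
neither is treated as canonical.

## Motif centrality

IUPAC motifs are scanned case-insensitively; both-strand scanning is the
union of the forward scan and the forward scan of the reverse-complement
motif, so reverse-palindromic motifs like WGCW yield identical offset sets
either way. In ±100-bp windows around summits, each window contributes one
best site — the match whose midpoint is closest to the window center, ties
to the lower offset (an all-sites mode exists behind a flag). The
positional curve is the per-offset fraction of windows whose best site
starts there; an 11-bp moving average is applied for display only and the
raw curve is retained for testing.

Central enrichment is a one-sided binomial test of k = windows with a
central best site (midpoint within ±25 bp of the center by default; the
width is a reported parameter) out of n = windows with any site. Because
the best site is the *minimum-distance* statistic over a window's matches,
the naive null probability (central placements / all placements) is only
valid for single-match windows; a window with s matches is central under
uniform placement with probability 1 − (1 − p)^s. The test therefore uses
the mean of these multiplicity-corrected probabilities as its binomial
null. Without the correction, short degenerate patterns with frequent
chance matches (e.g. a GAGA control) appear centrally enriched in purely
random sequence; with it, the null simulation is calibrated (≤10% of
uniform replicates at p < 0.05) while centrally planted motifs remain
overwhelmingly significant.

## Mutation spectra and kataegis

SNVs are collapsed to the pyrimidine-reference convention (G>A counted as
C>T, etc.), giving six classes that sum to 1; non-SNV records are skipped
and counted. Inter-mutation distances are per-chromosome differences of
sorted positions; the first variant of a chromosome has no IMD and
cross-chromosome pairs never form one.

Kataegis detection is a deterministic greedy maximal-run scan: starting at
the leftmost unconsumed variant of a chromosome, the run extends right
while the mean of its internal consecutive IMDs stays within the bound; a
run with at least the minimum variant count becomes a focus and scanning
resumes after it, otherwise the start advances one variant. Presets:
classical ≥6 variants with mean IMD ≤ 1 kb; relaxed ≥3 with ≤ 50 kb. The
mean IMD of a k-variant run uses its k−1 internal distances only
(flanking distances are not included — a documented choice, since either
convention satisfies the printed criteria). This is a behavioral
implementation of the printed criteria, not a changepoint model; foci are
disjoint and earliest-start wins among overlapping candidates.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its parameters and a seed; one
global seed expands into fixed per-component child streams
(counter-indexed spawn keys), so adding a generator never perturbs
existing streams, and ground truth is returned with every dataset.

- Genomes are i.i.d. uniform A/C/G/T (optional GC fraction); annotations
  pack identical-layout genes (5′UTR, two CDS exons, a noncoding middle
  exon, 3′UTR, two introns) on alternating strands with random jitter, so
  every one of the seven categories is non-empty by construction.
- Break profiles are uniform Poisson background plus spiked clusters of a
  fixed event count and width; condition pairs draw event categories from
  a multinomial (perturbed probabilities ∝ control × redistribution
  factors, renormalized), then an interval length-weighted within the
  category and a position uniform within it. "Breaks in category r" means
  exactly this sampling law; a sampled position can still be *assigned* to
  a higher-precedence category where the raw interval sets overlap, which
  attenuates recovered effects slightly relative to the pure multinomial
  value (the effect-recovery acceptance band accounts for this).
- LAD sets are Bernoulli bin memberships; derived sets rewire the first
  set, keeping members with probability k = 2J/(1+J) and adding
  non-members with probability coverage·(1−k)/(1−coverage), which
  preserves expected coverage and gives expected Jaccard J against the
  first set.
- Variant sets place background SNVs uniformly and planted foci as evenly
  spread runs within a span, so a 6-variant/2.5-kb focus has mean IMD
  ≤ 500 bp by construction; substitution classes are drawn so the
  collapsed C>T share equals the requested fraction in expectation, with
  random strand orientation.
- Motif windows plant one concrete IUPAC realization per window with the
  requested probability, midpoint at center + round(N(0, sd)) truncated to
  the window.

None of this emulates chromatin state, replication timing, mappability,
sequence-composition bias, or read-level noise — upstream of the BED
files is out of scope. Passing tests therefore demonstrate the
correctness and calibration of the *methods* under their stated
assumptions, not the biological effect sizes of any real dataset; the
published headline fractions (LAD overlap percentages, driver-gene
positivity, etc.) depend on restricted-access data and are not
reproduced here.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately small
problems chosen to give tight statistical bounds at interactive runtimes:
two-chromosome toy genomes of a few hundred kb for pipeline stages,
100-Mb single-chromosome genomes (10,000 bins) for LAD and kataegis rate
measurements, 200 replicates for calibration rates, 50 for effect
recovery, and 100 genomes for kataegis sensitivity. All stochastic tests
are seeded; rerunning any entry point with the same seed is byte-identical.
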