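"""Readers and writers for the formats the pipeline touches.

BED (break profiles, LADs, peaks, hotspots), 2-column chrom.sizes, GTF gene
annotation (via :mod:`gffutils`), variants as VCF (via :mod:`cyvcf2`) or a
5-column TSV, and plain TSV result tables. All writers emit a deterministic
column order and sort so that reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeDef, Interval

logger = logging.getLogger(__name__)

__all__ = [
    "BreakProfile",
    "VariantSet",
    "Gene",
    "Transcript",
    "GeneAnnotation",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_breaks",
    "write_breaks",
    "read_gtf",
    "write_gtf",
    "read_variants",
    "write_variants",
    "read_deg_table",
]

VALID_STRANDS = {"+", "-", "."}
_BASES = {"A", "C", "G", "T"}


@dataclass
class BreakProfile:
    """Per-sample set of single-base DSB events.

    ``positions`` are 0-based; one row per break event (events may repeat a
    position — each record is one independent break).
    """

    sample_id: str
    chroms: np.ndarray  # dtype object/str
    positions: np.ndarray  # int64, 0-based
    strands: np.ndarray  # str, in {+,-,.}
    n_dropped: int = 0  # records on unknown chromosomes / out of bounds

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype=object)
        if not (len(self.chroms) == len(self.positions) == len(self.strands)):
            raise ValueError("event arrays must have equal length")

    @property
    def n_events(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "pos": self.positions, "strand": self.strands}
        )

    def per_chrom(self) -> dict[str, np.ndarray]:
        """Sorted event positions per chromosome."""
        out: dict[str, np.ndarray] = {}
        for chrom in np.unique(self.chroms.astype(str)):
            out[chrom] = np.sort(self.positions[self.chroms == chrom])
        return out

    @classmethod
    def from_events(
        cls, sample_id: str, events: Sequence[tuple[str, int, str]]
    ) -> "BreakProfile":
        if not events:
            return cls(sample_id, np.array([], dtype=object),
                       np.array([], dtype=np.int64), np.array([], dtype=object))
        c, p, s = zip(*events)
        return cls(sample_id, np.array(c, dtype=object),
                   np.array(p, dtype=np.int64), np.array(s, dtype=object))


@dataclass
class VariantSet:
    """Single-nucleotide variants; positions are 1-based (VCF convention)."""

    records: pd.DataFrame  # columns: chrom, pos, ref, alt, sample

    COLUMNS = ("chrom", "pos", "ref", "alt", "sample")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        self.records = self.records.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 0-based position of the 5' end
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...]
    utr3: tuple[tuple[int, int], ...]


@dataclass
class GeneAnnotation:
    genes: dict[str, Gene]
    transcripts: list[Transcript]

    def gene_by_symbol(self) -> dict[str, Gene]:
        return {g.symbol: g for g in self.genes.values()}

    def gene_spans(self) -> list[Interval]:
        return [
            Interval(g.chrom, g.start, g.end, name=g.gene_id, strand=g.strand)
            for g in self.genes.values()
        ]


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path) -> GenomeDef:
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            names.append(fields[0])
            lengths.append(int(fields[1]))
    return GenomeDef(tuple(names), tuple(lengths))


def write_chrom_sizes(genome: GenomeDef, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, L in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{c}\t{L}\n")


# ---------------------------------------------------------------------------
# BED


def _harmonized(chrom: str) -> str:
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


def read_bed(
    path: str | Path,
    genome: GenomeDef | None = None,
    harmonize_chroms: bool = False,
) -> list[Interval]:
    """Read a BED3/BED6 file into a list of intervals.

    Records on chromosomes absent from ``genome`` (or out of bounds) are
    dropped with a logged count rather than raising.
    """
    out: list[Interval] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = _harmonized(fields[0]) if harmonize_chroms else fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if genome is not None and (
                chrom not in genome or end > genome.length_of(chrom) or start < 0
            ):
                dropped += 1
                continue
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
            out.append(Interval(chrom, start, end, name=name, score=score, strand=strand))
    if dropped:
        logger.warning("%s: dropped %d records outside the genome", path, dropped)
    return out


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    ivs = sorted(intervals, key=lambda v: (v.chrom, v.start, v.end))
    with open(path, "w") as fh:
        for iv in ivs:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_breaks(
    path: str | Path,
    genome: GenomeDef,
    sample_id: str | None = None,
    harmonize_chroms: bool = False,
) -> BreakProfile:
    """Read a BED file of unique DSB locations into a :class:`BreakProfile`.

    One event per BED record; the break position is the record's start
    coordinate. Records on chromosomes absent from the genome, or with a
    start at/beyond the chromosome end, are dropped and counted in
    ``n_dropped``.
    """
    chroms: list[str] = []
    positions: list[int] = []
    strands: list[str] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = _harmonized(fields[0]) if harmonize_chroms else fields[0]
            try:
                start = int(fields[1])
                int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if chrom not in genome or start < 0 or start >= genome.length_of(chrom):
                dropped += 1
                continue
            strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
            chroms.append(chrom)
            positions.append(start)
            strands.append(strand)
    if dropped:
        logger.warning("%s: dropped %d break records outside the genome", path, dropped)
    sample = sample_id if sample_id is not None else Path(path).stem
    return BreakProfile(
        sample,
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(strands, dtype=object),
        n_dropped=dropped,
    )


def write_breaks(profile: BreakProfile, path: str | Path) -> None:
    df = profile.to_frame().sort_values(["chrom", "pos"], kind="stable")
    with open(path, "w") as fh:
        for chrom, pos, strand in df.itertuples(index=False):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# GTF


def _pairs(features) -> tuple[tuple[int, int], ...]:
    # gffutils is 1-based inclusive; convert to 0-based half-open
    return tuple(sorted((f.start - 1, f.end) for f in features))


def read_gtf(path: str | Path) -> GeneAnnotation:
    """Parse a GTF into genes and transcripts with exon/CDS/UTR structure."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, Gene] = {}
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        symbol = g.attributes.get("gene_name", [gid])[0]
        genes[gid] = Gene(gid, symbol, g.seqid, g.strand, g.start - 1, g.end)

    transcripts: list[Transcript] = []
    for t in db.features_of_type("transcript"):
        tid = t.attributes["transcript_id"][0]
        gid = t.attributes["gene_id"][0]
        exons = _pairs(db.children(t, featuretype="exon"))
        cds = _pairs(db.children(t, featuretype="CDS"))
        utr5 = _pairs(db.children(t, featuretype="five_prime_utr"))
        utr3 = _pairs(db.children(t, featuretype="three_prime_utr"))
        if t.strand == "+":
            tss = t.start - 1
        elif t.strand == "-":
            tss = t.end - 1
        else:
            raise ValueError(f"transcript {tid} has no strand; TSS undefined")
        transcripts.append(
            Transcript(tid, gid, t.seqid, t.strand, tss, exons, cds, utr5, utr3)
        )
    return GeneAnnotation(genes, transcripts)


def write_gtf(annotation: GeneAnnotation, path: str | Path) -> None:
    def row(chrom, src, ftype, s0, e0, strand, attrs):
        # emit 1-based inclusive coordinates
        return f"{chrom}\t{src}\t{ftype}\t{s0 + 1}\t{e0}\t.\t{strand}\t.\t{attrs}\n"

    by_tx = {t.transcript_id: t for t in annotation.transcripts}
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            g = annotation.genes[gid]
            fh.write(
                row(g.chrom, "breakscape", "gene", g.start, g.end, g.strand,
                    f'gene_id "{gid}"; gene_name "{g.symbol}";')
            )
            for tid in sorted(t.transcript_id for t in annotation.transcripts
                              if t.gene_id == gid):
                t = by_tx[tid]
                attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                span = (min(s for s, _ in t.exons), max(e for _, e in t.exons))
                fh.write(row(t.chrom, "breakscape", "transcript",
                             span[0], span[1], t.strand, attrs))
                for label, pairs in (
                    ("exon", t.exons), ("CDS", t.cds),
                    ("five_prime_utr", t.utr5), ("three_prime_utr", t.utr3),
                ):
                    for s, e in pairs:
                        fh.write(row(t.chrom, "breakscape", label, s, e, t.strand, attrs))


# ---------------------------------------------------------------------------
# Variants


def read_variants(path: str | Path, sample_id: str | None = None) -> VariantSet:
    """Read SNVs from a VCF (``.vcf``) or a 5-column TSV.

    TSV columns: chrom, pos (1-based), ref, alt, sample (header optional).
    """
    path = Path(path)
    sample = sample_id if sample_id is not None else path.stem
    rows: list[tuple[str, int, str, str, str]] = []
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        import cyvcf2

        for v in cyvcf2.VCF(str(path)):
            for alt in v.ALT:
                rows.append((v.CHROM, int(v.POS), v.REF, alt, sample))
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        cols = [c.lower() for c in df.columns]
        if not {"chrom", "pos", "ref", "alt"}.issubset(cols):
            # headerless: assume positional
            df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
            df.columns = list(VariantSet.COLUMNS)[: len(df.columns)]
        else:
            df.columns = cols
        if "sample" not in df.columns:
            df["sample"] = sample
        rows = [
            (r.chrom, int(r.pos), r.ref, r.alt, r.sample)
            for r in df.itertuples(index=False)
        ]
    rec = pd.DataFrame(rows, columns=list(VariantSet.COLUMNS))
    rec["pos"] = rec["pos"].astype(np.int64)
    return VariantSet(rec)


def write_variants(variants: VariantSet, path: str | Path) -> None:
    df = variants.records.sort_values(["chrom", "pos"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DEG tables


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table with gene, log2FC and padj columns."""
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for col in df.columns:
        low = col.lower()
        if low in ("gene", "symbol", "gene_symbol", "gene_id"):
            rename[col] = "gene"
        elif low in ("log2fc", "log2foldchange", "lfc"):
            rename[col] = "log2FC"
        elif low in ("padj", "adj_pval", "fdr", "qvalue"):
            rename[col] = "padj"
    df = df.rename(columns=rename)
    if "padj" not in df.columns:
        raise ValueError(f"{path}: missing padj column")
    if "log2FC" not in df.columns:
        raise ValueError(f"{path}: missing log2FC column")
    return df
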