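"""Gene-level DSB burden, driver-gene classification and TSS-vs-body density.

Break counts are summed over gene bodies (annotated span including introns)
with zero-count genes retained. Driver genes are DSB-positive when they
overlap >= 1 break and hotspot-positive when they overlap >= 1 called
hotspot; percentages use the full curated list as denominator by default,
so symbols that fail to resolve against the annotation count as negatives.
The TSS-vs-body comparison pairs the two densities per gene and reports a
two-sided Wilcoxon signed-rank p-value (a rank-sum alternative is
available for unpaired designs).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Interval, merge_intervals
from .io import BreakProfile, GeneAnnotation

__all__ = [
    "gene_dsb_counts",
    "classify_drivers",
    "tss_vs_body_density",
    "filter_degs",
    "DEG_PRESETS",
]

# preset -> (padj threshold, log2FC rule); both inequalities strict
DEG_PRESETS = {
    "A": {"padj": 0.05, "abs_log2fc": 0.5},
    "B": {"padj": 0.05, "log2fc": 1.0},
}


def _counts_in_spans(profile: BreakProfile, spans: list[Interval]) -> np.ndarray:
    per_chrom = profile.per_chrom()
    out = np.zeros(len(spans), dtype=np.int64)
    for i, iv in enumerate(spans):
        pos = per_chrom.get(iv.chrom)
        if pos is None:
            continue
        out[i] = np.searchsorted(pos, iv.end, side="left") - np.searchsorted(
            pos, iv.start, side="left"
        )
    return out


def _tss_of_gene(annotation: GeneAnnotation, gene_id: str) -> int | None:
    tss = [t.tss for t in annotation.transcripts if t.gene_id == gene_id]
    return min(tss) if tss else None  # deterministic pick for multi-transcript genes


def gene_dsb_counts(
    profile: BreakProfile,
    annotation: GeneAnnotation,
    gene_list: Sequence[str] | None = None,
    tss_flank: int = 250,
) -> pd.DataFrame:
    """Per-gene break counts over gene bodies and TSS windows.

    ``gene_list`` selects genes by symbol; unresolved symbols are kept as
    rows with ``resolved=False`` so the caller controls the denominator.
    With no list, every annotated gene is quantified.
    """
    by_symbol = annotation.gene_by_symbol()
    if gene_list is not None:
        if len(gene_list) == 0:
            raise ValueError("empty gene list")
        symbols = list(gene_list)
    else:
        symbols = sorted(by_symbol)

    rows = []
    spans: list[Interval | None] = []
    for sym in symbols:
        g = by_symbol.get(sym)
        if g is None:
            rows.append({"gene_id": None, "symbol": sym, "chrom": None,
                         "start": -1, "end": -1, "resolved": False})
            spans.append(None)
        else:
            rows.append({"gene_id": g.gene_id, "symbol": sym, "chrom": g.chrom,
                         "start": g.start, "end": g.end, "resolved": True})
            spans.append(Interval(g.chrom, g.start, g.end))
    df = pd.DataFrame(rows)

    body_counts = np.zeros(len(df), dtype=np.int64)
    tss_counts = np.zeros(len(df), dtype=np.int64)
    body_kb = np.full(len(df), np.nan)
    tss_kb = np.full(len(df), np.nan)
    for i, (row, span) in enumerate(zip(rows, spans)):
        if span is None:
            continue
        body_counts[i] = _counts_in_spans(profile, [span])[0]
        body_kb[i] = len(span) / 1e3
        tss = _tss_of_gene(annotation, row["gene_id"])
        if tss is not None:
            win = Interval(span.chrom, max(0, tss - tss_flank), tss + tss_flank)
            tss_counts[i] = _counts_in_spans(profile, [win])[0]
            tss_kb[i] = len(win) / 1e3

    df["n_breaks"] = body_counts
    df["breaks_per_kb_body"] = body_counts / body_kb
    df["n_breaks_tss"] = tss_counts
    df["breaks_per_kb_tss"] = tss_counts / tss_kb
    df["dsb_positive"] = df["resolved"] & (df["n_breaks"] >= 1)
    return df


def classify_drivers(
    table: pd.DataFrame,
    hotspots,
    unresolved: str = "denominator",
) -> dict:
    """Summarize DSB- and hotspot-positivity over a driver-gene table.

    ``unresolved='denominator'`` keeps unresolved symbols in the
    denominator (full curated list); ``'exclude'`` drops them.
    """
    if unresolved not in ("denominator", "exclude"):
        raise ValueError("unresolved must be 'denominator' or 'exclude'")
    tab = table if unresolved == "denominator" else table[table["resolved"]]
    n = len(tab)

    hs_items = getattr(hotspots, "hotspots", hotspots)
    hs_ivs = merge_intervals(
        [h.interval if hasattr(h, "interval") else h for h in hs_items]
    ) if len(hs_items) else []
    by_chrom: dict[str, list[Interval]] = {}
    for iv in hs_ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    hotspot_pos = []
    for row in tab.itertuples(index=False):
        if not row.resolved:
            hotspot_pos.append(False)
            continue
        span = Interval(row.chrom, row.start, row.end)
        hotspot_pos.append(any(span.overlaps(m) for m in by_chrom.get(row.chrom, [])))
    n_dsb = int(tab["dsb_positive"].sum())
    n_hs = int(sum(hotspot_pos))
    return {
        "n_genes": n,
        "n_dsb_positive": n_dsb,
        "pct_dsb_positive": 100.0 * n_dsb / n if n else 0.0,
        "n_hotspot_positive": n_hs,
        "pct_hotspot_positive": 100.0 * n_hs / n if n else 0.0,
    }


def tss_vs_body_density(
    profile: BreakProfile,
    annotation: GeneAnnotation,
    deg_genes: Sequence[str],
    tss_flank: int = 250,
    test: str = "wilcoxon",
) -> tuple[pd.DataFrame, float]:
    """Paired per-gene breaks/kb at TSS windows vs gene bodies, plus a p-value.

    Returns (per-gene table restricted to resolved genes, p). p is NaN when
    the test is undefined (no breaks anywhere, or all paired differences
    zero).
    """
    if len(deg_genes) == 0:
        raise ValueError("empty DEG gene set")
    tab = gene_dsb_counts(profile, annotation, gene_list=deg_genes,
                          tss_flank=tss_flank)
    tab = tab[tab["resolved"]].reset_index(drop=True)
    x = tab["breaks_per_kb_tss"].to_numpy(float)
    y = tab["breaks_per_kb_body"].to_numpy(float)
    p = float("nan")
    if len(tab) and (x.sum() + y.sum()) > 0:
        try:
            if test == "wilcoxon":
                p = float(stats.wilcoxon(x, y).pvalue)
            elif test == "ranksum":
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
        except ValueError:
            p = float("nan")  # all differences zero
    return tab, p


def filter_degs(deg_table: pd.DataFrame, preset: str = "A") -> list[str]:
    """Differentially expressed genes under a threshold preset.

    Preset A: padj < 0.05 and |log2FC| > 0.5 (two-sided).
    Preset B: padj < 0.05 and log2FC > 1 (up-regulated only).
    All inequalities strict.
    """
    if "padj" not in deg_table.columns:
        raise ValueError("missing padj column")
    if "log2FC" not in deg_table.columns:
        raise ValueError("missing log2FC column")
    rule = DEG_PRESETS.get(preset)
    if rule is None:
        raise ValueError(f"unknown preset {preset!r}")
    keep = deg_table["padj"] < rule["padj"]
    if "abs_log2fc" in rule:
        keep &= deg_table["log2FC"].abs() > rule["abs_log2fc"]
    else:
        keep &= deg_table["log2FC"] > rule["log2fc"]
    return deg_table.loc[keep, "gene"].tolist()
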