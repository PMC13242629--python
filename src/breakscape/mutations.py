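"""Substitution spectra, inter-mutation distances and kataegis detection.

SNVs are collapsed to the pyrimidine-reference convention (a G>A call is
counted as C>T on the opposite strand), giving six substitution classes.
Kataegis — localized hypermutation — is detected per chromosome as maximal
runs of consecutive sorted variants whose mean internal inter-mutation
distance (IMD) stays within a bound: the classical criterion requires
>= 6 variants with mean IMD <= 1 kb, the relaxed criterion >= 3 variants
with mean IMD <= 50 kb. The scan is greedy left-to-right (earliest start
wins; scanning resumes after an accepted focus), a deterministic
behavioral implementation of the printed criteria rather than a
changepoint model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import VariantSet

__all__ = [
    "SUBSTITUTION_CLASSES",
    "KataegisCriteria",
    "KataegisFocus",
    "CLASSICAL",
    "RELAXED",
    "substitution_spectrum",
    "intermutation_distances",
    "detect_kataegis",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class KataegisCriteria:
    min_variants: int
    max_mean_imd: float  # bp

    def __post_init__(self) -> None:
        if self.min_variants < 2:
            raise ValueError("min_variants must be >= 2")
        if self.max_mean_imd <= 0:
            raise ValueError("max_mean_imd must be positive")


CLASSICAL = KataegisCriteria(6, 1_000)
RELAXED = KataegisCriteria(3, 50_000)


@dataclass(frozen=True)
class KataegisFocus:
    chrom: str
    start: int  # 1-based position of the first member variant
    end: int  # 1-based position of the last member variant
    n_variants: int
    mean_imd: float
    member_index: tuple[int, ...]  # row indices into the variant table


def substitution_spectrum(variants: VariantSet) -> tuple[pd.Series, int]:
    """Pyrimidine-collapsed six-class substitution proportions.

    Returns (proportions summing to 1 over the six classes, n_skipped)
    where skipped records are non-SNVs or calls with invalid bases.
    """
    if variants.n_variants == 0:
        raise ValueError("empty variant set")
    counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
    skipped = 0
    for rec in variants.records.itertuples(index=False):
        ref, alt = str(rec.ref).upper(), str(rec.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _COMP or alt not in _COMP \
                or ref == alt:
            skipped += 1
            continue
        if ref in ("G", "A"):
            ref, alt = _COMP[ref], _COMP[alt]
        counts[f"{ref}>{alt}"] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no valid SNVs in variant set")
    props = pd.Series({k: v / total for k, v in counts.items()},
                      name="proportion")
    return props, skipped


def intermutation_distances(variants: VariantSet) -> dict[str, dict]:
    """Per-chromosome sorted positions and consecutive distances.

    IMD_i = pos_i - pos_{i-1}; the first variant of each chromosome has no
    IMD, and positions on different chromosomes never pair.
    """
    out: dict[str, dict] = {}
    for chrom, grp in variants.records.groupby("chrom", sort=True):
        pos = np.sort(grp["pos"].to_numpy(np.int64))
        out[str(chrom)] = {"positions": pos, "imd": np.diff(pos)}
    return out


def detect_kataegis(
    variants: VariantSet, criteria: KataegisCriteria
) -> list[KataegisFocus]:
    """Greedy maximal-run kataegis scan per chromosome.

    Starting at the leftmost unconsumed variant, the run is extended right
    while the mean of its internal consecutive IMDs stays within the
    bound; a run with >= min_variants becomes a focus and scanning resumes
    after it, otherwise the start advances by one. Foci are disjoint and
    the result is deterministic.
    """
    foci: list[KataegisFocus] = []
    df = variants.records.reset_index(drop=True)
    for chrom, grp in df.groupby("chrom", sort=True):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        idx = grp.index.to_numpy()[order]
        pos = grp["pos"].to_numpy(np.int64)[order]
        n = len(pos)
        i = 0
        while i < n - 1:
            j = i
            total_imd = 0
            # extend while the run mean stays within the bound
            while j + 1 < n:
                cand = total_imd + (pos[j + 1] - pos[j])
                if cand / (j + 1 - i) <= criteria.max_mean_imd:
                    total_imd = cand
                    j += 1
                else:
                    break
            count = j - i + 1
            if count >= criteria.min_variants:
                foci.append(
                    KataegisFocus(
                        chrom=str(chrom),
                        start=int(pos[i]),
                        end=int(pos[j]),
                        n_variants=count,
                        mean_imd=total_imd / (count - 1),
                        member_index=tuple(int(k) for k in idx[i : j + 1]),
                    )
                )
                i = j + 1
            else:
                i += 1
    return foci
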