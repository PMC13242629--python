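"""Control-baseline Observed/Expected enrichment across genomic categories.

Given per-category hotspot counts in a control sample (C_r) and a perturbed
sample (O_r), the control composition p_r = C_r / sum(C) defines the
expected counts E_r = p_r * sum(O). The redistribution statistic is

    O/E_r = (O_r + eps) / (E_r + eps),        eps = 0.5 by default,

reported as log2(O/E_r): positive values mean the perturbed sample places
more hotspots in category r than the control composition predicts.

Per-category significance defaults to Fisher's exact test on the 2x2
table (O_r vs the rest of O; C_r vs the rest of C), which treats the
control composition as the noisy sample it is and stays calibrated under
the null. A two-sided exact binomial test of O_r out of sum(O) against a
fixed success probability p_r is available (``test="binomial"``); it is
anticonservative because it ignores the sampling noise in C. q-values are
Benjamini-Hochberg across the table's categories, and the pseudocount
enters the ratio only, never the test counts.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["oe_enrichment", "enrichment_report", "SIGNIFICANCE_TIERS"]

# q-value thresholds and their stars (strict <, as conventionally printed)
SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def oe_enrichment(
    control_counts: Mapping[str, int],
    observed_counts: Mapping[str, int],
    eps: float = 0.5,
    test: str = "fisher",
) -> pd.DataFrame:
    """Observed/Expected enrichment table over matching category keys.

    Returns a DataFrame indexed by category with columns
    C, O, p_r, E, oe, log2_oe, p_value, q_value. ``test`` selects the
    per-category significance test: "fisher" (two-sample exact, default)
    or "binomial" (one-sample against the control composition).
    """
    if set(control_counts) != set(observed_counts):
        raise ValueError("control and observed category keys differ")
    cats = list(control_counts.keys())
    C = np.array([control_counts[c] for c in cats], dtype=float)
    O = np.array([observed_counts[c] for c in cats], dtype=float)
    if (C < 0).any() or (O < 0).any():
        raise ValueError("counts must be non-negative")
    if C.sum() == 0:
        raise ValueError("expected baseline undefined: all control counts are zero")
    if O.sum() == 0:
        raise ValueError("no observed events")

    p_r = C / C.sum()
    E = p_r * O.sum()
    oe = (O + eps) / (E + eps)
    log2_oe = np.log2(oe)

    n_obs = int(O.sum())
    n_ctrl = int(C.sum())
    if test == "binomial":
        pvals = np.array([
            stats.binomtest(int(o), n_obs, p, alternative="two-sided").pvalue
            for o, p in zip(O, p_r)
        ])
    elif test == "fisher":
        pvals = np.array([
            stats.fisher_exact(
                [[int(o), n_obs - int(o)], [int(c), n_ctrl - int(c)]]
            )[1]
            for o, c in zip(O, C)
        ])
    else:
        raise ValueError(f"unknown test {test!r}")
    qvals = multipletests(pvals, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "C": C.astype(int),
            "O": O.astype(int),
            "p_r": p_r,
            "E": E,
            "oe": oe,
            "log2_oe": log2_oe,
            "p_value": pvals,
            "q_value": qvals,
        },
        index=pd.Index(cats, name="category"),
    )


def _stars(q: float) -> str:
    for thr, label in SIGNIFICANCE_TIERS:
        if q < thr:
            return label
    return ""


def enrichment_report(table: pd.DataFrame) -> pd.DataFrame:
    """Annotate an enrichment table with significance stars.

    FDR tiers: * q < 0.05, ** q < 0.01, *** q < 0.001 (strict).
    Rows are ordered by |log2 O/E| descending.
    """
    out = table.copy()
    out["significance"] = [_stars(q) for q in out["q_value"]]
    return out.reindex(out["log2_oe"].abs().sort_values(ascending=False).index)
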