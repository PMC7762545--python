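"""Pair-wise relevance (PWR) and transcriptomic landscapes.

PWR ranks gene pairs by the product of three factors: joint expression
level relative to the region average, squared coordination, and joint
expression control (inverse variability) relative to the region average:

    PWR_ij = (AVE_i * AVE_j / AVE_mean**2) * rho_ij**2
             * (REV_mean**2 / (REV_i * REV_j))

The region means AVE_mean/REV_mean are taken over *all* quantified
unigenes of the region, even when a landscape is restricted to a pathway,
so pathway landscapes remain comparable.  A landscape is the top-n pairs
by PWR with deterministic tie-breaking.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

__all__ = ["pwr", "pwr_table", "landscape"]


def pwr(
    ave_i: float,
    ave_j: float,
    rev_i: float,
    rev_j: float,
    rho_ij: float,
    ave_mean: float,
    rev_mean: float,
) -> float:
    """Pair-wise relevance of one gene pair (see module docstring)."""
    if rev_i <= 0 or rev_j <= 0 or ave_mean <= 0 or rev_mean <= 0:
        raise ValueError("REVs and region means must be positive")
    return float(
        (ave_i * ave_j) / ave_mean**2
        * rho_ij**2
        * rev_mean**2 / (rev_i * rev_j)
    )


def pwr_table(
    stats: pd.DataFrame,
    rho: pd.DataFrame,
    genes=None,
    ave_mean: float | None = None,
    rev_mean: float | None = None,
) -> pd.DataFrame:
    """PWR for every unordered gene pair in ``genes`` (long format).

    ``stats`` is a region_stats frame over the full quantified universe —
    its means define AVE_mean/REV_mean unless given explicitly; ``rho`` is
    a correlation matrix (from expression.correlation_matrix).  Pairs with
    undefined ρ or REV are excluded.
    """
    usable = stats[(stats["AVE"] > 0) & np.isfinite(stats["REV"]) & (stats["REV"] > 0)]
    if ave_mean is None:
        ave_mean = float(usable["AVE"].mean())
    if rev_mean is None:
        rev_mean = float(usable["REV"].mean())
    genes = sorted(usable.index if genes is None else
                   [g for g in genes if g in usable.index])
    rows = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            if ga not in rho.index or gb not in rho.index:
                continue
            r = rho.loc[ga, gb]
            if not np.isfinite(r):
                continue
            rows.append(
                {
                    "gene_a": ga,
                    "gene_b": gb,
                    "pwr": pwr(
                        usable.loc[ga, "AVE"], usable.loc[gb, "AVE"],
                        usable.loc[ga, "REV"], usable.loc[gb, "REV"],
                        r, ave_mean, rev_mean,
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pwr"])


def landscape(scores: pd.DataFrame, top_n: int) -> tuple[pd.DataFrame, Counter]:
    """Top-n pairs by PWR plus per-gene participation counts.

    Ties break deterministically: descending PWR, then lexicographic
    (gene_a, gene_b).  Returns the ranked table (with a 1-based ``rank``
    column) and a Counter of how often each gene appears in the top pairs.
    """
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    ranked = scores.sort_values(
        ["pwr", "gene_a", "gene_b"], ascending=[False, True, True]
    ).head(top_n)
    ranked = ranked.reset_index(drop=True)
    ranked.insert(0, "rank", ranked.index + 1)
    participation = Counter(ranked["gene_a"]) + Counter(ranked["gene_b"])
    return ranked, participation
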