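"""Gene commanding height (GCH) hierarchies and master regulators.

GCH scores a gene by two multiplicative factors: how tightly its
expression is controlled relative to the region at large (the median REV
over its own REV) and how strongly it is coordinated with the rest of the
transcriptome (exp of 4 times the mean squared correlation with every
other quantified gene, bounded in [1, e^4]).  Ranking the region's genes
by GCH yields its hierarchy; the top gene is the region's gene master
regulator (GMR) — the gene whose expression manipulation is predicted to
perturb the region's transcriptome the most.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GCHRanking",
    "gch",
    "mean_square_correlation",
    "gch_table",
    "rank_hierarchy",
    "region_hierarchy",
    "cross_region_report",
]


def gch(rev_i: float, rev_median: float, rho_squared_mean: float) -> dict[str, float]:
    """GCH score of one gene from its REV and mean squared correlation.

    Returns the two factors and their product:
    transcription_control = rev_median / rev_i,
    coordination_factor = exp(4 * rho_squared_mean) in [1, e^4].
    """
    if rev_i <= 0:
        raise ValueError("rev_i must be > 0")
    if not 0.0 <= rho_squared_mean <= 1.0:
        raise ValueError("rho_squared_mean must be in [0, 1]")
    control = rev_median / rev_i
    coordination = float(np.exp(4.0 * rho_squared_mean))
    return {
        "transcription_control": control,
        "coordination_factor": coordination,
        "gch": control * coordination,
    }


def mean_square_correlation(
    log2_matrix: np.ndarray, block_size: int | None = None
) -> np.ndarray:
    """Per-gene mean squared Pearson correlation against all other genes.

    ``log2_matrix`` is genes × replicates; rows containing NaN or with zero
    variance are excluded (NaN result, and dropped from every other gene's
    mean).  ``block_size`` streams the computation in row blocks — results
    are identical to the full-matrix path, only memory differs.
    """
    X = np.asarray(log2_matrix, dtype=float)
    n_genes, n_obs = X.shape
    valid = ~np.isnan(X).any(axis=1)
    valid &= X.std(axis=1) > 0
    out = np.full(n_genes, np.nan)
    idx = np.where(valid)[0]
    m = len(idx)
    if m < 2:
        return out
    Z = X[idx] - X[idx].mean(axis=1, keepdims=True)
    Z /= np.linalg.norm(Z, axis=1, keepdims=True)
    if block_size is None:
        block_size = m
    sums = np.empty(m)
    for start in range(0, m, block_size):
        block = Z[start:start + block_size]
        r = block @ Z.T  # (b, m) correlations
        r = np.clip(r, -1.0, 1.0)
        sums[start:start + block_size] = (r**2).sum(axis=1) - 1.0  # drop self
    out[idx] = sums / (m - 1)
    return np.clip(out, 0.0, 1.0)


def gch_table(
    stats: pd.DataFrame,
    rho_squared_mean: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """GCH factors for every scoreable gene of one region.

    ``stats`` is a region_stats frame; genes with REV undefined or 0, or
    with an undefined mean squared correlation, are excluded (with their
    count retained by the caller via the index difference).  The median
    REV is taken over the scoreable genes.
    """
    r2 = pd.Series(np.asarray(rho_squared_mean, dtype=float), index=stats.index)
    ok = np.isfinite(stats["REV"]) & (stats["REV"] > 0) & np.isfinite(r2)
    sub = stats.loc[ok]
    rev_median = float(sub["REV"].median())
    control = rev_median / sub["REV"]
    coordination = np.exp(4.0 * r2.loc[ok])
    out = pd.DataFrame(
        {
            "REV": sub["REV"],
            "transcription_control": control,
            "coordination_factor": coordination,
            "gch": control * coordination,
        }
    )
    out.index.name = "gene"
    return out


@dataclass(frozen=True)
class GCHRanking:
    region: str
    scores: pd.DataFrame  # descending gch; columns incl. gch, REV
    gmr: str


def rank_hierarchy(scores: pd.DataFrame, region: str = "") -> GCHRanking:
    """Order genes by descending GCH; ties go to the lower-REV gene, then name."""
    if len(scores) == 0:
        raise ValueError("need at least one score")
    ordered = (
        scores.rename_axis("gene")
        .reset_index()
        .sort_values(["gch", "REV", "gene"], ascending=[False, True, True])
        .set_index("gene")
    )
    return GCHRanking(region=region, scores=ordered, gmr=str(ordered.index[0]))


def region_hierarchy(
    table, region: str, block_size: int | None = None
) -> GCHRanking:
    """End-to-end GCH ranking of one region from an expression table."""
    from .expression import _log2_gene_matrix, region_stats

    stats = region_stats(table, region)
    logs = _log2_gene_matrix(table, region)
    r2 = mean_square_correlation(logs.to_numpy(), block_size=block_size)
    scores = gch_table(stats.loc[logs.index], pd.Series(r2, index=logs.index))
    return rank_hierarchy(scores, region=region)


def cross_region_report(
    rankings: dict[str, GCHRanking], watchlist
) -> pd.DataFrame:
    """GCH of watchlist genes across regions; NaN marks not-quantified.

    A missing entry means the gene was not adequately quantified (or not
    scoreable) in that region — deliberately distinct from a zero score.
    """
    watchlist = list(watchlist)
    out = pd.DataFrame(index=watchlist, columns=list(rankings), dtype=float)
    for region, ranking in rankings.items():
        present = [g for g in watchlist if g in ranking.scores.index]
        out.loc[present, region] = ranking.scores.loc[present, "gch"].astype(float)
    out.index.name = "gene"
    return out
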