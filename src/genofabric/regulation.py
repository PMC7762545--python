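"""Regulation calls with a variability-derived fold-change cutoff.

A gene is called regulated between two regions only when its signed fold
change clears a gene-specific cutoff built from the REVs of both regions
*and* a two-tail Welch t-test on the log2 replicate-level values is
significant.  The cutoff

    CUT = 1 + (1/100) * sqrt(2 * (REV_A**2 + REV_B**2))

absorbs the combined biological variability and technical noise of the
gene in the two compared regions, so noisy genes need a larger fold change
to be called.  Genes expressed in exactly one of the two regions are
called turned_on/turned_off outside the ratio logic.  Pathway-level
regulation is scored with a hypergeometric over-representation tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegulationCall",
    "fold_change",
    "regulation_cutoff",
    "call_regulation",
    "region_pair_calls",
    "pathway_regulation_p",
    "tabulate_regulation",
]

ALPHA = 0.05

VERDICTS = ("up", "down", "not_regulated", "turned_on", "turned_off", "unquantified")


@dataclass(frozen=True)
class RegulationCall:
    gene: str
    region_a: str
    region_b: str
    x: float  # signed fold change, |x| >= 1 where defined, NaN for on/off
    cut: float
    p_value: float
    verdict: str


def fold_change(ave_a: float, ave_b: float) -> float:
    """Signed fold change A→B: +μB/μA if B higher, −μA/μB if lower, +1 if equal."""
    if ave_a <= 0 or ave_b <= 0:
        raise ValueError("fold_change requires positive AVEs; zeros are on/off calls")
    if ave_b > ave_a:
        return ave_b / ave_a
    if ave_b < ave_a:
        return -ave_a / ave_b
    return 1.0


def regulation_cutoff(rev_a: float, rev_b: float) -> float:
    """Gene-specific fold-change cutoff from the two regions' REVs (percent)."""
    if rev_a < 0 or rev_b < 0:
        raise ValueError("REVs must be >= 0")
    return 1.0 + np.sqrt(2.0 * (rev_a**2 + rev_b**2)) / 100.0


def _welch_log2(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Two-tail Welch t-test on log2 replicate-level expression values."""
    a = np.log2(values_a.ravel())
    b = np.log2(values_b.ravel())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def call_regulation(
    table,
    gene: str,
    region_a: str,
    region_b: str,
    stats_a: pd.DataFrame | None = None,
    stats_b: pd.DataFrame | None = None,
    alpha: float = ALPHA,
) -> RegulationCall:
    """Regulation verdict for one gene between two regions (A→B).

    Requires significance on both gates: |x| > CUT and Welch p < alpha.
    AVE = 0 on exactly one side yields turned_on (zero in A) or turned_off
    (zero in B).  ``stats_a``/``stats_b`` are optional precomputed
    region_stats frames; they are recomputed for the single gene otherwise.
    """
    from .expression import compute_ave, compute_rev  # local to avoid cycle

    try:
        prof_a = table.gene_profile(gene, region_a)
        prof_b = table.gene_profile(gene, region_b)
    except KeyError:
        return RegulationCall(gene, region_a, region_b, np.nan, np.nan, np.nan, "unquantified")

    def _stat(stats_df, prof, col):
        if stats_df is not None and gene in stats_df.index:
            return float(stats_df.loc[gene, col])
        return compute_ave(prof) if col == "AVE" else compute_rev(prof)

    ave_a = _stat(stats_a, prof_a, "AVE")
    ave_b = _stat(stats_b, prof_b, "AVE")

    if ave_a == 0 and ave_b == 0:
        return RegulationCall(gene, region_a, region_b, np.nan, np.nan, np.nan, "not_regulated")
    if ave_a == 0 or ave_b == 0:
        # require genuinely silent replicates on the zero side
        silent = prof_a if ave_a == 0 else prof_b
        if np.all(silent == 0):
            verdict = "turned_on" if ave_a == 0 else "turned_off"
            return RegulationCall(gene, region_a, region_b, np.nan, np.nan, np.nan, verdict)
        return RegulationCall(gene, region_a, region_b, np.nan, np.nan, np.nan, "unquantified")

    rev_a = _stat(stats_a, prof_a, "REV")
    rev_b = _stat(stats_b, prof_b, "REV")
    if not (np.isfinite(rev_a) and np.isfinite(rev_b)):
        return RegulationCall(gene, region_a, region_b, np.nan, np.nan, np.nan, "unquantified")

    x = fold_change(ave_a, ave_b)
    cut = regulation_cutoff(rev_a, rev_b)
    if np.any(prof_a <= 0) or np.any(prof_b <= 0):
        p = np.nan
        verdict = "not_regulated"
    else:
        p = _welch_log2(prof_a, prof_b)
        if abs(x) > cut and p < alpha:
            verdict = "up" if x > 0 else "down"
        else:
            verdict = "not_regulated"
    return RegulationCall(gene, region_a, region_b, x, cut, p, verdict)


def region_pair_calls(
    table,
    region_a: str,
    region_b: str,
    genes=None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Regulation calls A→B for every gene (or a subset), as a DataFrame."""
    from .expression import region_stats

    stats_a = region_stats(table, region_a)
    stats_b = region_stats(table, region_b)
    genes = table.genes if genes is None else [g for g in genes if g in set(table.genes)]
    rows = []
    for gene in genes:
        call = call_regulation(table, gene, region_a, region_b, stats_a, stats_b, alpha)
        rows.append(
            {
                "gene": call.gene,
                "x": call.x,
                "CUT": call.cut,
                "p": call.p_value,
                "verdict": call.verdict,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def pathway_regulation_p(
    n_universe: int,
    n_regulated_universe: int,
    n_pathway: int,
    n_regulated_pathway: int,
) -> float:
    """Hypergeometric over-representation tail P(X >= observed).

    Drawing ``n_pathway`` genes from a universe of ``n_universe`` of which
    ``n_regulated_universe`` are regulated, the p-value is the upper tail
    (including the observed count) of the number regulated in the pathway.
    """
    if not 0 <= n_regulated_pathway <= n_pathway <= n_universe:
        raise ValueError("inconsistent counts: need 0 <= k <= pathway <= universe")
    if not n_regulated_pathway <= n_regulated_universe <= n_universe:
        raise ValueError("inconsistent counts: regulated exceeds universe")
    return float(
        stats.hypergeom.sf(
            n_regulated_pathway - 1, n_universe, n_regulated_universe, n_pathway
        )
    )


@dataclass(frozen=True)
class RegulationSummary:
    n_quantified: int
    n_up: int
    n_down: int
    n_turned_on: int
    n_turned_off: int
    n_not_regulated: int

    @property
    def ratio(self) -> str:
        """Up/down ratio in the field's "11:5" rendering."""
        return f"{self.n_up}:{self.n_down}"


def tabulate_regulation(calls: pd.DataFrame, genes) -> RegulationSummary:
    """Verdict counts restricted to a pathway's quantified genes."""
    subset = calls.loc[[g for g in genes if g in calls.index]]
    quantified = subset[subset["verdict"] != "unquantified"]
    counts = quantified["verdict"].value_counts()
    return RegulationSummary(
        n_quantified=len(quantified),
        n_up=int(counts.get("up", 0)),
        n_down=int(counts.get("down", 0)),
        n_turned_on=int(counts.get("turned_on", 0)),
        n_turned_off=int(counts.get("turned_off", 0)),
        n_not_regulated=int(counts.get("not_regulated", 0)),
    )
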