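"""Per-gene expression characteristics: level, variability, coordination.

Each quantified gene in each region carries three independent measures:

* **AVE** — average expression level: the mean over redundant spots of the
  per-spot replicate mean.
* **REV** — relative expression variability, in percent: the pooled
  per-spot coefficient of variation, multiplied by the mid-interval
  chi-square correction ½(r/χ²(r; 0.975) + r/χ²(r; 0.025)) with
  r = n_replicates·R − 1 degrees of freedom (R = spot redundancy).  The
  correction penalizes genes probed by few spots and tends to 1 as data
  accumulate.
* **COR** — Pearson correlation of two genes' log2 expression across
  biological replicates, with two-tail t significance at n_obs − 2 degrees
  of freedom.  Significant positive correlation is *synergism* (S),
  significant negative is *antagonism* (A), near-zero is *independence*
  (I), anything else is left blank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoordinationEntry",
    "compute_ave",
    "chi2_correction",
    "compute_rev",
    "region_stats",
    "correlation_pvalue",
    "compute_correlation",
    "correlation_matrix",
    "anchor_correlations",
    "critical_rho",
    "classify_coordination",
    "rev_summary",
]

ALPHA = 0.05
INDEPENDENCE_ALPHA = 0.95


def compute_ave(values: np.ndarray) -> float:
    """Average expression level of one gene in one region.

    ``values`` has shape (R spots, n replicates); AVE is the mean over
    spots of each spot's replicate mean, so every spot gets equal weight
    regardless of redundancy.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("values must be a non-empty (spots x replicates) matrix")
    return float(values.mean(axis=1).mean())


def chi2_correction(r_dof: int) -> float:
    """Mid-interval chi-square correction for a variance estimated on r dof.

    Returns ½(r/χ²(r; 0.975) + r/χ²(r; 0.025)); always > 1, monotonically
    decreasing toward 1 as r grows.
    """
    if r_dof < 1:
        raise ValueError("r_dof must be >= 1")
    lo = stats.chi2.ppf(0.025, r_dof)
    hi = stats.chi2.ppf(0.975, r_dof)
    return float(0.5 * (r_dof / hi + r_dof / lo))


def compute_rev(values: np.ndarray) -> float:
    """Relative expression variability (percent) of one gene in one region.

    REV = chi2_correction(n·R − 1) × sqrt((1/R) Σ_k (s_k/μ_k)²) × 100,
    pooling the per-spot coefficients of variation.  Undefined (NaN) when
    any spot mean is zero; exactly 0 when every spot has zero variance.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("values must be a non-empty (spots x replicates) matrix")
    mu = values.mean(axis=1)
    if np.any(mu == 0):
        return float("nan")
    s = values.std(axis=1, ddof=1)
    pooled_cv = np.sqrt(np.mean((s / mu) ** 2))
    r = values.size - 1
    return float(chi2_correction(r) * pooled_cv * 100.0)


def region_stats(table, region: str) -> pd.DataFrame:
    """Per-gene AVE/REV/redundancy table for one region.

    Columns: AVE, REV (NaN where undefined), R (spot redundancy), r_dof,
    expressed (AVE > 0).  ``table`` is an io_qc.ExpressionTable.
    """
    rows = {}
    cols = table.columns(region)
    for gene, sub in table.data.groupby("gene", sort=True):
        values = sub[cols].to_numpy(dtype=float)
        ave = compute_ave(values)
        rev = compute_rev(values) if ave > 0 else float("nan")
        rows[gene] = {
            "AVE": ave,
            "REV": rev,
            "R": values.shape[0],
            "r_dof": values.size - 1,
            "expressed": ave > 0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out


# -- coordination ----------------------------------------------------------


@dataclass(frozen=True)
class CoordinationEntry:
    gene_a: str
    gene_b: str
    region: str
    rho: float
    p_value: float
    dof: int
    klass: str  # "S", "A", "I" or "" (blank)


def correlation_pvalue(rho: float, dof: int) -> float:
    """Two-tail t-test p-value for a Pearson correlation at ``dof`` dof."""
    if not np.isfinite(rho):
        return float("nan")
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) == 1.0:
        return 0.0
    t = abs(rho) * np.sqrt(dof / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(t, dof))


def critical_rho(dof: int, alpha: float = ALPHA) -> float:
    """Smallest |ρ| significant at the two-tail ``alpha`` level."""
    t = stats.t.isf(alpha / 2.0, dof)
    return float(t / np.sqrt(dof + t**2))


def classify_coordination(
    rho: float,
    p_value: float,
    alpha: float = ALPHA,
    independence_alpha: float = INDEPENDENCE_ALPHA,
) -> str:
    """S/A/I/blank coordination class for one gene pair.

    S (synergism): ρ > 0 significant at ``alpha``; A (antagonism): ρ < 0
    significant; I (independence): |ρ| inside the near-zero band where the
    two-tail p-value is at least ``independence_alpha``; blank otherwise
    (including undefined ρ).
    """
    if not np.isfinite(rho) or not np.isfinite(p_value):
        return ""
    if p_value < alpha:
        return "S" if rho > 0 else "A"
    if p_value >= independence_alpha:
        return "I"
    return ""


def _paired_log2(table, gene_a: str, gene_b: str, region: str, pairing: str):
    prof_a = table.gene_profile(gene_a, region)
    prof_b = table.gene_profile(gene_b, region)
    if pairing == "spot":
        if prof_a.shape != prof_b.shape:
            raise ValueError(
                "spot-level pairing requires equal redundancy; "
                f"got {prof_a.shape[0]} and {prof_b.shape[0]} spots"
            )
        x, y = prof_a.ravel(), prof_b.ravel()
    elif pairing == "replicate_means":
        x, y = prof_a.mean(axis=0), prof_b.mean(axis=0)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    if np.any(x <= 0) or np.any(y <= 0):
        return None
    return np.log2(x), np.log2(y)


def compute_correlation(
    table,
    gene_a: str,
    gene_b: str,
    region: str,
    pairing: str = "replicate_means",
    alpha: float = ALPHA,
    independence_alpha: float = INDEPENDENCE_ALPHA,
) -> CoordinationEntry:
    """Coordination of two genes in one region.

    With the default ``replicate_means`` pairing the per-replicate spot
    means are correlated (n_rep observations, dof = n_rep − 2, the
    conservative choice for unequal redundancy); ``pairing="spot"`` pairs
    spot-level values when both genes have the same redundancy
    (dof = n_rep·R − 2).  Genes with a zero or negative value in any paired
    observation carry on/off information and yield an undefined ρ (blank).
    """
    pair = _paired_log2(table, gene_a, gene_b, region, pairing)
    if pair is None:
        return CoordinationEntry(gene_a, gene_b, region, float("nan"), float("nan"), 0, "")
    x, y = pair
    dof = len(x) - 2
    if dof < 1 or np.std(x) == 0 or np.std(y) == 0:
        return CoordinationEntry(gene_a, gene_b, region, float("nan"), float("nan"), dof, "")
    rho = float(np.corrcoef(x, y)[0, 1])
    p = correlation_pvalue(rho, dof)
    klass = classify_coordination(rho, p, alpha, independence_alpha)
    return CoordinationEntry(gene_a, gene_b, region, rho, p, dof, klass)


def _log2_gene_matrix(table, region: str, genes=None) -> pd.DataFrame:
    """Genes × replicates log2 matrix of spot means; zero-carrying genes NaN."""
    means = table.replicate_gene_means(region)
    if genes is not None:
        means = means.loc[[g for g in genes if g in means.index]]
    arr = means.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan)
    logs[np.isnan(logs).any(axis=1)] = np.nan
    return pd.DataFrame(logs, index=means.index, columns=means.columns)


def correlation_matrix(
    table, region: str, genes=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pairwise ρ and p matrices on log2 replicate-mean expression.

    Genes with any zero replicate value (or zero variance) get NaN rows and
    columns.  The degrees of freedom are n_replicates − 2 for every pair.
    """
    logs = _log2_gene_matrix(table, region, genes)
    arr = logs.to_numpy()
    valid = ~np.isnan(arr).any(axis=1)
    spread = np.zeros(len(arr))
    spread[valid] = arr[valid].std(axis=1)
    valid &= spread > 0
    rho = np.full((len(logs), len(logs)), np.nan)
    if valid.sum() >= 2:
        sub = np.corrcoef(arr[valid])
        idx = np.where(valid)[0]
        rho[np.ix_(idx, idx)] = sub
    np.fill_diagonal(rho, np.nan)
    dof = table.n_replicates - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.clip(rho**2, 0.0, 1.0 - 1e-15)
        t = np.abs(rho) * np.sqrt(dof / (1.0 - r2))
    p = 2.0 * stats.t.sf(t, dof)
    p[np.abs(rho) >= 1.0] = 0.0
    names = logs.index
    return (
        pd.DataFrame(rho, index=names, columns=names),
        pd.DataFrame(p, index=names, columns=names),
    )


def anchor_correlations(
    table, region: str, anchor: str, genes=None
) -> pd.DataFrame:
    """ρ, p and class of every gene against one anchor gene (e.g. VHL)."""
    rho_m, p_m = correlation_matrix(table, region, genes)
    if anchor not in rho_m.index:
        raise KeyError(f"anchor gene {anchor!r} not quantified in {region}")
    out = pd.DataFrame({"rho": rho_m[anchor], "p": p_m[anchor]})
    out["class"] = [
        classify_coordination(r, p) for r, p in zip(out["rho"], out["p"])
    ]
    return out.drop(index=anchor)


# -- region-level REV summaries -------------------------------------------


def rev_summary(
    rev_by_region: dict[str, np.ndarray] | pd.DataFrame,
    reference: str,
) -> pd.DataFrame:
    """Median REV per region, percent reduction vs reference and a p-value.

    The reduction is (median_ref − median_region)/median_ref × 100; the
    p-value comes from a two-sample z-test on the REV values (normality of
    REV assumed), two-tailed.  NaN REVs are ignored.
    """
    if isinstance(rev_by_region, pd.DataFrame):
        rev_by_region = {c: rev_by_region[c].to_numpy() for c in rev_by_region}
    ref = np.asarray(rev_by_region[reference], dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size < 2:
        raise ValueError("need at least 2 REV values in the reference region")
    med_ref = float(np.median(ref))
    rows = {}
    for region, values in rev_by_region.items():
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        med = float(np.median(v))
        reduction = (med_ref - med) / med_ref * 100.0
        if region == reference:
            p = 1.0
        else:
            se = np.sqrt(ref.var(ddof=1) / ref.size + v.var(ddof=1) / v.size)
            if se > 0:
                z = (ref.mean() - v.mean()) / se
                p = float(2.0 * stats.norm.sf(abs(z)))
            else:
                p = 1.0 if np.isclose(ref.mean(), v.mean()) else 0.0
        rows[region] = {
            "median_rev": med,
            "reduction_vs_reference": reduction,
            "p_value": p,
            "n": v.size,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "region"
    return out
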