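"""Transcriptomic separation between profiled regions.

A pathway's state in a region, relative to a reference region, is reduced
to three orthogonal percentage coordinates: the mean relative change of
the genes' average expression (AVE-diff), of their expression variability
(REV-diff), and of their correlation with an anchor gene (COR-diff).  The
transcriptomic distance between two regions is the Euclidean norm of the
difference of their coordinate triples, so the reference region sits at
the origin and distances are in percent units.  A complementary, purely
expression-level view places each replicate in the subspace spanned by a
few selected genes and measures the distance between region centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FabricCoordinates",
    "fabric_coordinates",
    "pathway_coordinates",
    "transcriptomic_distance",
    "subspace_centroid_distance",
]


@dataclass(frozen=True)
class FabricCoordinates:
    region: str
    pathway: str
    ave_diff: float  # percent
    rev_diff: float  # percent
    cor_diff: float  # percent
    reference_gene: str
    n_genes: int = 0
    excluded: tuple[str, ...] = field(default_factory=tuple)

    def as_array(self) -> np.ndarray:
        return np.array([self.ave_diff, self.rev_diff, self.cor_diff], dtype=float)


def _mean_ratio_percent(numer, denom, names) -> tuple[float, list[str]]:
    """Mean of (numer/denom − 1) × 100 over genes with usable denominators."""
    numer = np.asarray(numer, dtype=float)
    denom = np.asarray(denom, dtype=float)
    usable = np.isfinite(numer) & np.isfinite(denom) & (denom != 0)
    excluded = [n for n, ok in zip(names, usable) if not ok]
    if not usable.any():
        raise ValueError("no gene with a usable reference value")
    return float(np.mean(numer[usable] / denom[usable] - 1.0) * 100.0), excluded


def fabric_coordinates(
    stats_ref,
    stats_alt,
    cor_ref,
    cor_alt,
    genes,
    region: str,
    reference_gene: str,
    pathway: str = "",
    cor_mode: str = "ratio_mean",
    cor_class_ref=None,
    cor_class_alt=None,
) -> FabricCoordinates:
    """3D difference coordinates of ``region`` vs the reference region.

    ``stats_ref``/``stats_alt`` are region_stats frames (AVE, REV columns);
    ``cor_ref``/``cor_alt`` map gene → correlation with the anchor gene in
    each region.  The AVE and REV coordinates are the mean over the pathway
    genes of (value(region)/value(reference) − 1), in percent.  Genes with
    a zero or undefined reference value are excluded and reported.

    The COR axis supports two conventions.  ``ratio_mean`` applies the same
    mean-of-ratios form to the anchor correlations; with few replicates it
    is unstable whenever a reference correlation sits near zero.
    ``partner_count`` instead reports the percent change in the *number* of
    pathway genes significantly coordinated with the anchor (requires
    ``cor_class_ref``/``cor_class_alt`` mapping gene → S/A/I/blank class),
    which is how region-level coordination remodeling is usually quoted.
    """
    genes = [g for g in genes if g in stats_ref.index and g in stats_alt.index]
    if reference_gene in genes:
        genes = [g for g in genes if g != reference_gene]
    if not genes:
        raise ValueError("no pathway gene quantified in both regions")
    ave_diff, excl_a = _mean_ratio_percent(
        stats_alt.loc[genes, "AVE"], stats_ref.loc[genes, "AVE"], genes
    )
    rev_diff, excl_r = _mean_ratio_percent(
        stats_alt.loc[genes, "REV"], stats_ref.loc[genes, "REV"], genes
    )
    if cor_mode == "ratio_mean":
        cor_alt_v = np.array([cor_alt.get(g, np.nan) for g in genes])
        cor_ref_v = np.array([cor_ref.get(g, np.nan) for g in genes])
        cor_diff, excl_c = _mean_ratio_percent(cor_alt_v, cor_ref_v, genes)
    elif cor_mode == "partner_count":
        if cor_class_ref is None or cor_class_alt is None:
            raise ValueError("partner_count mode needs coordination classes")
        n_ref = sum(1 for g in genes if cor_class_ref.get(g) in ("S", "A"))
        n_alt = sum(1 for g in genes if cor_class_alt.get(g) in ("S", "A"))
        if n_ref == 0:
            raise ValueError("no significant anchor partner in the reference")
        cor_diff, excl_c = (n_alt / n_ref - 1.0) * 100.0, []
    else:
        raise ValueError(f"unknown cor_mode {cor_mode!r}")
    excluded = tuple(sorted(set(excl_a) | set(excl_r) | set(excl_c)))
    return FabricCoordinates(
        region=region,
        pathway=pathway,
        ave_diff=ave_diff,
        rev_diff=rev_diff,
        cor_diff=cor_diff,
        reference_gene=reference_gene,
        n_genes=len(genes),
        excluded=excluded,
    )


def pathway_coordinates(
    table,
    pathway_genes,
    anchor: str,
    region: str,
    reference: str,
    pathway: str = "",
    cor_mode: str = "ratio_mean",
) -> FabricCoordinates:
    """Convenience wrapper computing stats and anchor correlations itself."""
    from .expression import anchor_correlations, region_stats

    stats_ref = region_stats(table, reference)
    stats_alt = region_stats(table, region)
    ref_cor = anchor_correlations(table, reference, anchor)
    alt_cor = anchor_correlations(table, region, anchor)
    return fabric_coordinates(
        stats_ref, stats_alt,
        ref_cor["rho"].to_dict(), alt_cor["rho"].to_dict(),
        pathway_genes, region, anchor, pathway,
        cor_mode=cor_mode,
        cor_class_ref=ref_cor["class"].to_dict(),
        cor_class_alt=alt_cor["class"].to_dict(),
    )


def transcriptomic_distance(c1, c2=None) -> float:
    """Euclidean distance between two coordinate triples, in percent.

    ``c1``/``c2`` may be FabricCoordinates or plain 3-sequences; ``c2``
    defaults to the origin (the reference region).  The coordinates are
    already percentages, so no further scaling is applied.
    """
    a = c1.as_array() if isinstance(c1, FabricCoordinates) else np.asarray(c1, float)
    if c2 is None:
        b = np.zeros(3)
    else:
        b = c2.as_array() if isinstance(c2, FabricCoordinates) else np.asarray(c2, float)
    if isinstance(c1, FabricCoordinates) and isinstance(c2, FabricCoordinates):
        if c1.pathway != c2.pathway or c1.reference_gene != c2.reference_gene:
            raise ValueError("coordinates must share pathway and anchor gene")
    return float(np.linalg.norm(a - b))


def subspace_centroid_distance(
    table, genes, region_a: str, region_b: str, log2: bool = True
) -> float:
    """Distance between region centroids in a selected-gene expression subspace.

    Each replicate is a point whose coordinates are the per-gene expression
    values (mean over redundant spots), on the log2 scale by default; the
    returned value is the Euclidean distance between the replicate
    centroids of the two regions, in expression units.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("need at least one gene")
    points = []
    for region in (region_a, region_b):
        means = table.replicate_gene_means(region)
        missing = [g for g in genes if g not in means.index]
        if missing:
            raise KeyError(f"genes not quantified in {region}: {missing}")
        arr = means.loc[genes].to_numpy(dtype=float)  # genes x replicates
        if log2:
            if np.any(arr <= 0):
                raise ValueError("log2 scale requires positive expression values")
            arr = np.log2(arr)
        points.append(arr.mean(axis=1))  # centroid over replicates
    return float(np.linalg.norm(points[0] - points[1]))
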