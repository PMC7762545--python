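"""Synthetic spot-redundant, multi-region, replicated expression data.

The generator emulates a two-color microarray design: each of ~10^3–10^4
unigenes is probed by 1–20 redundant spots, each region is profiled in a
small number of biological replicates (4 by default), and expression is
lognormal with a per-gene coefficient of variation.  Coordination is
planted through latent factors: genes in a correlation block share one
standard-normal factor per region and replicate, and two members with
loadings a and b have population log-scale correlation a·b.  Ground truth
(base levels, CVs, loadings, planted fold changes, the planted master
gene) is carried alongside the table so every downstream stage can be
checked against what was planted.

All randomness flows from the explicit seed in the configuration; the
same configuration always produces byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_qc import ExpressionTable, column_name, read_expression_table

__all__ = [
    "CorrelationBlock",
    "PlantedGMR",
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "truncated_geometric",
    "simulate_dataset",
    "write_fixture",
    "read_fixture",
]

MAX_REDUNDANCY = 20


def truncated_geometric(p: float = 0.5, max_spots: int = MAX_REDUNDANCY) -> dict[int, float]:
    """Spots-per-gene law: geometric(p) truncated to [1, max_spots]."""
    ks = np.arange(1, max_spots + 1)
    w = p * (1 - p) ** (ks - 1)
    w /= w.sum()
    return {int(k): float(v) for k, v in zip(ks, w)}


@dataclass(frozen=True)
class CorrelationBlock:
    """Genes sharing one latent factor; loadings in [−1, 1] (scalar or per gene)."""

    genes: tuple[int, ...]
    loading: float | tuple[float, ...] = 0.7

    def loadings(self) -> np.ndarray:
        lam = np.asarray(self.loading, dtype=float)
        if lam.ndim == 0:
            lam = np.full(len(self.genes), float(lam))
        if lam.shape != (len(self.genes),):
            raise ValueError("loading must be scalar or one value per block gene")
        if np.any(np.abs(lam) > 1):
            raise ValueError("loadings must lie in [-1, 1]")
        return lam


@dataclass(frozen=True)
class PlantedGMR:
    """A planted master gene: high shared-factor loading, reduced CV.

    The gene is attached to the *first* correlation block's latent factor
    with its own loading, and its coefficient of variation is multiplied
    by ``cv_multiplier`` (< 1), mirroring the two factors of the GCH score
    (strong coordination, strong expression control).  ``redundancy`` pins
    the master gene's spot count (master genes on this platform tend to be
    redundantly probed; a single-spot gene cannot display a low REV because
    the small-sample chi-square correction dominates it); None leaves it to
    the redundancy law.
    """

    index: int
    loading: float = 0.95
    cv_multiplier: float = 0.3
    redundancy: int | None = 8

    def __post_init__(self) -> None:
        if not 0 < abs(self.loading) <= 1:
            raise ValueError("loading must be in (0, 1]")
        if not 0 < self.cv_multiplier < 1:
            raise ValueError("cv_multiplier must be in (0, 1)")
        if self.redundancy is not None and not 1 <= self.redundancy <= MAX_REDUNDANCY:
            raise ValueError(f"redundancy must be in [1, {MAX_REDUNDANCY}]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of one synthetic experiment.

    Defaults mirror the profiled-kidney design: 4 regions × 4 biological
    replicates, spot redundancy 1–20 averaging ≈3 spots per gene,
    lognormal expression on a normalized scale, per-gene CV in a range
    that yields median REVs of a few tens of percent, and a small planted
    fraction of QC failures to exercise the spot filter.
    """

    n_genes: int
    regions: tuple[str, ...] = ("NOR", "PTA", "PTB", "CWM")
    n_replicates: int = 4
    redundancy_law: Mapping[int, float] | None = None  # default truncated_geometric()
    base_expression_law: tuple[float, float] = (4.0, 1.5)  # mean, sigma of log2 level
    cv_law: tuple[float, float] = (0.02, 0.10)  # uniform CV range (fractions)
    correlation_blocks: tuple[CorrelationBlock, ...] = ()
    planted_gmr: PlantedGMR | None = None
    planted_regulation: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    background_level: float = 50.0
    qc_fail_fraction: float = 0.0
    corrupt_fraction: float = 0.0
    spot_effect_sd: float = 0.05  # ln-scale per-spot offset, fixed across replicates
    technical_noise: float = 0.0  # extra ln-scale independent spot x replicate noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not self.regions:
            raise ValueError("need at least one region")
        if self.base_expression_law[1] < 0:
            raise ValueError("sigma of the base expression law must be >= 0")
        lo, hi = self.cv_law
        if not (0 < lo <= hi < 1):
            raise ValueError("cv_law support must lie in (0, 1)")
        if self.redundancy_law is not None:
            ks = list(self.redundancy_law)
            if min(ks) < 1 or max(ks) > MAX_REDUNDANCY:
                raise ValueError(f"redundancy support must be in [1, {MAX_REDUNDANCY}]")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        seen: set[int] = set()
        for block in self.correlation_blocks:
            block.loadings()  # validates
            if seen & set(block.genes):
                raise ValueError("correlation blocks must be disjoint")
            seen |= set(block.genes)
            if block.genes and max(block.genes) >= self.n_genes:
                raise ValueError("block gene index out of range")
        if self.planted_gmr is not None:
            if self.planted_gmr.index >= self.n_genes:
                raise ValueError("planted GMR index out of range")
            if not self.correlation_blocks:
                raise ValueError("a planted GMR requires at least one correlation block")
        for idx, folds in self.planted_regulation.items():
            if idx >= self.n_genes:
                raise ValueError("planted regulation index out of range")
            for region in folds:
                if region not in self.regions:
                    raise ValueError(f"planted regulation in unknown region {region!r}")


@dataclass(frozen=True)
class SimulationTruth:
    """Planted per-gene ground truth for one simulated dataset."""

    genes: tuple[str, ...]
    base_level: np.ndarray  # linear-scale expression mean per gene
    cv: np.ndarray
    loading: np.ndarray
    block: np.ndarray  # factor id, -1 = none
    redundancy: np.ndarray
    region_multiplier: pd.DataFrame  # genes x regions, 0 = silenced
    gmr_gene: str | None


@dataclass(frozen=True)
class SimulatedDataset:
    table: ExpressionTable
    truth: SimulationTruth
    config: SimulationConfig


def _fold_to_multiplier(fold: float) -> float:
    """Signed fold-change convention → multiplicative factor (0 = silenced)."""
    if fold == 0:
        return 0.0
    if abs(fold) < 1:
        raise ValueError("planted fold changes must have |fold| >= 1 (or be 0)")
    return fold if fold > 0 else 1.0 / (-fold)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one spot-level multi-region dataset with known truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_rep = config.n_replicates
    regions = config.regions

    law = config.redundancy_law or truncated_geometric(0.3)
    ks = np.array(sorted(law), dtype=int)
    probs = np.array([law[int(k)] for k in ks], dtype=float)
    probs /= probs.sum()
    redundancy = rng.choice(ks, size=n, p=probs) if n else np.zeros(0, int)

    m_log2, s_log2 = config.base_expression_law
    base = 2.0 ** rng.normal(m_log2, s_log2, size=n)
    lo, hi = config.cv_law
    cv = rng.uniform(lo, hi, size=n)

    loading = np.zeros(n)
    block_id = np.full(n, -1, dtype=int)
    for b, block in enumerate(config.correlation_blocks):
        idx = np.array(block.genes, dtype=int)
        loading[idx] = block.loadings()
        block_id[idx] = b
    gmr_gene = None
    if config.planted_gmr is not None:
        g = config.planted_gmr.index
        cv[g] *= config.planted_gmr.cv_multiplier
        loading[g] = config.planted_gmr.loading
        block_id[g] = 0
        if config.planted_gmr.redundancy is not None:
            redundancy[g] = config.planted_gmr.redundancy
        gmr_gene = f"G{g:05d}"

    multiplier = pd.DataFrame(
        1.0, index=[f"G{i:05d}" for i in range(n)], columns=list(regions)
    )
    for idx, folds in config.planted_regulation.items():
        for region, fold in folds.items():
            multiplier.iloc[idx, multiplier.columns.get_loc(region)] = (
                _fold_to_multiplier(fold)
            )

    sigma = np.sqrt(np.log1p(cv**2))  # lognormal sigma giving the planted CV
    spot_gene = np.repeat(np.arange(n), redundancy)
    n_spots = len(spot_gene)
    spot_within = np.concatenate([np.arange(r) for r in redundancy]) if n else np.zeros(0, int)
    spot_offset = rng.normal(0.0, config.spot_effect_sd, size=n_spots)
    spot_base = base[spot_gene] * np.exp(spot_offset - config.spot_effect_sd**2 / 2)

    n_factors = max(len(config.correlation_blocks), 1)
    lam = loading
    resid = np.sqrt(1.0 - lam**2)

    columns: dict[str, np.ndarray | list | int] = {
        "spot_id": [f"G{g:05d}_S{k + 1}" for g, k in zip(spot_gene, spot_within)],
        "gene": [f"G{i:05d}" for i in spot_gene],
        "corrupted": np.zeros(n_spots, dtype=int),
    }

    tech = config.technical_noise
    for region in regions:
        z = rng.normal(size=(n_factors, n_rep))
        # residual noise is drawn per spot AND replicate: redundant probes are
        # semi-independent measurements, which is what gives the pooled-CV
        # estimator its n_rep*R - 1 degrees of freedom
        eta = rng.normal(size=(n_spots, n_rep))
        shared = np.where(block_id[:, None] >= 0, z[np.maximum(block_id, 0)], 0.0)
        sig_s = sigma[spot_gene]
        eps = sig_s[:, None] * (
            lam[spot_gene, None] * shared[spot_gene]
            + resid[spot_gene, None] * eta
        )
        noise_factor = np.exp(eps - sig_s[:, None] ** 2 / 2)  # unit mean
        mult = multiplier[region].to_numpy()
        expr = (
            spot_base[:, None]
            * mult[spot_gene, None]
            * noise_factor
            * np.exp(rng.normal(0.0, tech, size=(n_spots, n_rep)) - tech**2 / 2)
        )
        bg = config.background_level * np.exp(rng.normal(0.0, 0.05, size=(n_spots, n_rep)))
        fg = 2.0 * bg + expr
        for j in range(n_rep):
            columns[column_name(region, j + 1, "fg")] = fg[:, j]
            columns[column_name(region, j + 1, "bg")] = bg[:, j]
            columns[column_name(region, j + 1, "expr")] = expr[:, j]
    data = pd.DataFrame(columns)

    if n_spots and config.qc_fail_fraction > 0:
        n_fail = int(round(config.qc_fail_fraction * n_spots))
        fail = rng.choice(n_spots, size=n_fail, replace=False)
        for s in fail:
            region = regions[rng.integers(len(regions))]
            j = int(rng.integers(n_rep)) + 1
            bg_val = data.loc[s, column_name(region, j, "bg")]
            data.loc[s, column_name(region, j, "fg")] = 1.5 * bg_val
    if n_spots and config.corrupt_fraction > 0:
        n_bad = int(round(config.corrupt_fraction * n_spots))
        bad = rng.choice(n_spots, size=n_bad, replace=False)
        data.loc[bad, "corrupted"] = 1

    table = ExpressionTable(data=data, regions=tuple(regions), n_replicates=n_rep)
    truth = SimulationTruth(
        genes=tuple(f"G{i:05d}" for i in range(n)),
        base_level=base,
        cv=cv,
        loading=loading,
        block=block_id,
        redundancy=redundancy,
        region_multiplier=multiplier,
        gmr_gene=gmr_gene,
    )
    return SimulatedDataset(table=table, truth=truth, config=config)


# -- fixture I/O -----------------------------------------------------------


def write_fixture(dataset: SimulatedDataset, directory: str | Path) -> tuple[Path, Path]:
    """Write the table as TSV plus a truth sidecar; round-trips via io_qc.

    Returns the (table_path, truth_path) pair.  The truth sidecar is plain
    JSON with one record per gene plus the planted-structure summary.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table_path = directory / "expression.tsv"
    truth_path = directory / "truth.json"
    dataset.table.data.to_csv(table_path, sep="\t", index=False)

    t = dataset.truth
    records = {
        gene: {
            "base_level": float(t.base_level[i]),
            "cv": float(t.cv[i]),
            "loading": float(t.loading[i]),
            "block": int(t.block[i]),
            "redundancy": int(t.redundancy[i]),
            "region_multiplier": {
                r: float(t.region_multiplier.iloc[i][r])
                for r in t.region_multiplier.columns
            },
        }
        for i, gene in enumerate(t.genes)
    }
    payload = {
        "gmr_gene": t.gmr_gene,
        "regions": list(dataset.config.regions),
        "n_replicates": dataset.config.n_replicates,
        "seed": dataset.config.seed,
        "genes": records,
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return table_path, truth_path


def read_fixture(directory: str | Path) -> tuple[ExpressionTable, dict]:
    """Read back a fixture written by write_fixture."""
    directory = Path(directory)
    table = read_expression_table(directory / "expression.tsv")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return table, truth
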