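"""End-to-end orchestration: QC → stats → regulation → geometry →
landscape → hierarchy → prediction, from a single YAML config.

Every stage writes a plain-text, diff-able output into the run directory
and the run manifest records the config hash and per-stage row counts, so
re-running with identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import expression, geometry, hierarchy, io_qc, prediction, regulation, relevance

__all__ = ["RunConfig", "run_pipeline", "info_count"]

log = logging.getLogger("genofabric")

STAGES = (
    "qc",
    "stats",
    "regulation",
    "geometry",
    "landscape",
    "hierarchy",
    "prediction",
)


@dataclass(frozen=True)
class RunConfig:
    expression_table: Path
    gene_sets: Path
    reference_region: str
    anchor_gene: str
    output_dir: Path
    alpha: float = 0.05
    independence_alpha: float = 0.95
    top_n: int = 25
    direction: str = "overexpress"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.top_n < 0:
            raise ValueError("top_n must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.get("input", {})
        thresholds = raw.get("thresholds", {})
        return cls(
            expression_table=Path(inputs["expression"]),
            gene_sets=Path(inputs["gene_sets"]),
            reference_region=raw["reference_region"],
            anchor_gene=raw["anchor_gene"],
            output_dir=Path(raw["output_dir"]),
            alpha=float(thresholds.get("alpha", 0.05)),
            independence_alpha=float(thresholds.get("independence_alpha", 0.95)),
            top_n=int(thresholds.get("top_n", 25)),
            direction=raw.get("direction", "overexpress"),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
        )


def _config_hash(config: RunConfig) -> str:
    # the output location does not influence the analysis, so reruns into a
    # different directory hash identically
    payload = json.dumps(
        {
            k: str(v)
            for k, v in vars(config).items()
            if k not in ("output_dir", "log_level")
        },
        sort_keys=True,
    ).encode()
    return hashlib.sha256(payload).hexdigest()


def _validate(config: RunConfig) -> tuple[io_qc.ExpressionTable, io_qc.GeneSetCollection]:
    """Fail before any stage output is written."""
    for path in (config.expression_table, config.gene_sets):
        if not Path(path).exists():
            raise FileNotFoundError(path)
    table = io_qc.read_expression_table(config.expression_table)
    gene_sets = io_qc.read_gene_sets(config.gene_sets)
    if config.reference_region not in table.regions:
        raise ValueError(
            f"reference region {config.reference_region!r} not in table regions "
            f"{table.regions}"
        )
    if config.anchor_gene.upper() not in {g.upper() for g in table.genes}:
        raise ValueError(f"anchor gene {config.anchor_gene!r} not in gene universe")
    return table, gene_sets


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    table, gene_sets = _validate(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "stages": {},
    }

    def record(stage: str, path: Path, rows: int) -> None:
        manifest["stages"][stage] = {"output": path.name, "rows": rows}
        log.info("stage %-10s -> %s (%d rows)", stage, path.name, rows)

    # qc
    filtered, discard = io_qc.spot_qc_filter(table)
    filtered, eliminated = io_qc.eliminate_unquantified_genes(filtered)
    io_qc.write_expression_table(filtered, out / "filtered.tsv")
    discard.to_csv(out / "discarded_spots.tsv", sep="\t", index=False)
    eliminated.to_csv(out / "eliminated_genes.tsv", sep="\t", index=False)
    record("qc", out / "filtered.tsv", filtered.n_spots)

    # stats
    stats = {r: expression.region_stats(filtered, r) for r in filtered.regions}
    stats_long = pd.concat(stats, names=["region"]).reset_index()
    stats_long.to_csv(out / "gene_stats.tsv", sep="\t", index=False)
    record("stats", out / "gene_stats.tsv", len(stats_long))

    ref = config.reference_region
    alt_regions = [r for r in filtered.regions if r != ref]

    # regulation (per region pair vs reference, plus pathway scores)
    reg_frames = []
    pathway_rows = []
    universe = set(filtered.genes)
    for region in alt_regions:
        calls = regulation.region_pair_calls(filtered, ref, region, alpha=config.alpha)
        calls = calls.assign(region=region)
        reg_frames.append(calls.reset_index())
        regulated_universe = calls["verdict"].isin(
            ["up", "down", "turned_on", "turned_off"]
        )
        for name in gene_sets:
            members = gene_sets.restrict(name, universe)
            if not members:
                continue
            summary = regulation.tabulate_regulation(calls, members)
            n_reg = (
                summary.n_up + summary.n_down
                + summary.n_turned_on + summary.n_turned_off
            )
            p = regulation.pathway_regulation_p(
                len(calls), int(regulated_universe.sum()),
                summary.n_quantified, n_reg,
            )
            pathway_rows.append(
                {
                    "region": region,
                    "pathway": name,
                    "quantified": summary.n_quantified,
                    "regulated": n_reg,
                    "ratio": summary.ratio,
                    "p": p,
                }
            )
    reg_long = pd.concat(reg_frames, ignore_index=True)
    reg_long.to_csv(out / "regulation.tsv", sep="\t", index=False)
    pd.DataFrame(pathway_rows).to_csv(out / "pathway_regulation.tsv", sep="\t", index=False)
    record("regulation", out / "regulation.tsv", len(reg_long))

    # geometry: coordinates + pairwise distances per pathway
    anchor = config.anchor_gene.upper()
    coord_rows = []
    dist_rows = []
    for name in gene_sets:
        members = gene_sets.restrict(name, universe)
        if not members:
            continue
        coords = {}
        for region in alt_regions:
            try:
                c = geometry.pathway_coordinates(
                    filtered, members, anchor, region, ref, pathway=name
                )
            except (ValueError, KeyError) as err:
                log.warning("geometry %s/%s skipped: %s", name, region, err)
                continue
            coords[region] = c
            coord_rows.append(
                {
                    "pathway": name, "region": region,
                    "ave_diff": c.ave_diff, "rev_diff": c.rev_diff,
                    "cor_diff": c.cor_diff, "n_genes": c.n_genes,
                }
            )
            dist_rows.append(
                {
                    "pathway": name, "region_a": ref, "region_b": region,
                    "td": geometry.transcriptomic_distance(c),
                }
            )
        pairs = list(coords)
        for i, ra in enumerate(pairs):
            for rb in pairs[i + 1:]:
                dist_rows.append(
                    {
                        "pathway": name, "region_a": ra, "region_b": rb,
                        "td": geometry.transcriptomic_distance(coords[ra], coords[rb]),
                    }
                )
    pd.DataFrame(coord_rows).to_csv(out / "fabric_coordinates.tsv", sep="\t", index=False)
    pd.DataFrame(dist_rows).to_csv(out / "distances.tsv", sep="\t", index=False)
    record("geometry", out / "distances.tsv", len(dist_rows))

    # landscapes
    land_rows = []
    for region in filtered.regions:
        stats_r = stats[region]
        rho, _ = expression.correlation_matrix(filtered, region)
        for name in gene_sets:
            members = gene_sets.restrict(name, universe)
            if len(members) < 2:
                continue
            scores = relevance.pwr_table(stats_r, rho, members)
            top, _parts = relevance.landscape(scores, config.top_n)
            top = top.assign(region=region, pathway=name)
            land_rows.append(top)
    land = pd.concat(land_rows, ignore_index=True) if land_rows else pd.DataFrame()
    land.to_csv(out / "landscapes.tsv", sep="\t", index=False)
    record("landscape", out / "landscapes.tsv", len(land))

    # hierarchy
    rankings = {}
    rank_frames = []
    gmr_lines = []
    for region in filtered.regions:
        ranking = hierarchy.region_hierarchy(filtered, region)
        rankings[region] = ranking
        df = ranking.scores.reset_index().assign(region=region)
        df.insert(0, "rank", range(1, len(df) + 1))
        rank_frames.append(df)
        gmr_lines.append(
            {
                "region": region,
                "gmr": ranking.gmr,
                "gch": float(ranking.scores.iloc[0]["gch"]),
            }
        )
    ranks = pd.concat(rank_frames, ignore_index=True)
    ranks.to_csv(out / "gch_ranking.tsv", sep="\t", index=False)
    with open(out / "gmr.jsonl", "w") as fh:
        for line in gmr_lines:
            fh.write(json.dumps(line, sort_keys=True) + "\n")
    record("hierarchy", out / "gch_ranking.tsv", len(ranks))

    # prediction: manipulate each non-reference region's GMR
    pred_frames = []
    for region in alt_regions:
        target = rankings[region].gmr
        plan = prediction.ManipulationPlan(target, config.direction, region)
        for name in gene_sets:
            members = gene_sets.restrict(name, universe)
            cor = prediction.coordination_with_target(filtered, region, target, members)
            if len(cor) == 0:
                continue
            effects = prediction.predict_effects(plan, cor)
            effects = effects.reset_index(names="partner").assign(
                region=region, target=target, pathway=name
            )
            pred_frames.append(effects)
    pred = pd.concat(pred_frames, ignore_index=True) if pred_frames else pd.DataFrame()
    pred.to_csv(out / "predictions.tsv", sep="\t", index=False)
    record("prediction", out / "predictions.tsv", len(pred))

    manifest["n_genes"] = len(universe)
    manifest["regions"] = list(filtered.regions)
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def info_count(n_genes: int) -> tuple[int, int, int, float]:
    """Transcriptomic information counts for an N-gene region.

    Returns (n_ave, n_rev, n_cor, expansion): N expression levels, N
    variabilities, N(N−1)/2 pairwise correlations, and the expansion
    factor (2N + N(N−1)/2)/N over an expression-level-only analysis,
    rounded to one decimal.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    n_cor = n_genes * (n_genes - 1) // 2
    expansion = round((2 * n_genes + n_cor) / n_genes, 1)
    return n_genes, n_genes, n_cor, expansion
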