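"""Expression-table and gene-set I/O plus spot/gene quality control.

The input dialect is a single tab-separated table with one row per
microarray spot.  Mandatory columns are ``spot_id`` and ``gene``; an
optional ``corrupted`` column carries 0/1 flags.  Measurements are encoded
in triplet columns named ``<REGION>.R<j>.<field>`` with ``field`` one of
``fg`` (foreground fluorescence), ``bg`` (background fluorescence) and
``expr`` (normalized expression), e.g. ``PTA.R1.expr``.  All regions must
declare the same number of replicates and complete fg/bg/expr triplets.

Quality control follows the two-color microarray convention: a spot is
discarded when it is flagged corrupted or its foreground fluorescence is
less than twice the background in *any* replicate of *any* region; a gene
is eliminated from every region unless at least one of its spots survives
with a finite expression value in every region/replicate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionTable",
    "GeneSetCollection",
    "column_name",
    "read_expression_table",
    "write_expression_table",
    "spot_qc_filter",
    "eliminate_unquantified_genes",
    "read_gene_sets",
]

_TRIPLET_RE = re.compile(r"^(?P<region>.+)\.R(?P<rep>\d+)\.(?P<field>fg|bg|expr)$")
_FIELDS = ("fg", "bg", "expr")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


def column_name(region: str, replicate: int, field: str) -> str:
    """Header name of one measurement column, e.g. ``PTA.R1.expr``."""
    return f"{region}.R{replicate}.{field}"


@dataclass(frozen=True)
class ExpressionTable:
    """Spot-level expression table for one multi-region experiment.

    Parameters
    ----------
    data:
        Wide DataFrame with ``spot_id``, ``gene``, ``corrupted`` and one
        ``<region>.R<j>.<field>`` column per region, replicate and field.
    regions:
        Ordered region labels.
    n_replicates:
        Number of biological replicates per region (same for all regions).
    """

    data: pd.DataFrame
    regions: tuple[str, ...]
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for col in ("spot_id", "gene"):
            if col not in self.data.columns:
                raise FormatError(f"missing mandatory column {col!r}")
        key = self.data[["spot_id", "gene"]]
        if key.duplicated().any():
            raise FormatError("(spot_id, gene) pairs must be unique")

    # -- accessors ---------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def n_spots(self) -> int:
        return len(self.data)

    def columns(self, region: str, field: str = "expr") -> list[str]:
        return [column_name(region, j, field) for j in range(1, self.n_replicates + 1)]

    def expression(self, region: str) -> pd.DataFrame:
        """Spot × replicate expression matrix for one region."""
        if region not in self.regions:
            raise KeyError(f"unknown region {region!r}")
        out = self.data[self.columns(region)].copy()
        out.index = pd.MultiIndex.from_frame(self.data[["gene", "spot_id"]])
        return out

    def gene_profile(self, gene: str, region: str) -> np.ndarray:
        """Replicate values of every spot probing ``gene``: shape (R_i, n_rep)."""
        rows = self.data["gene"] == gene
        if not rows.any():
            raise KeyError(f"gene {gene!r} not in table")
        return self.data.loc[rows, self.columns(region)].to_numpy(dtype=float)

    def replicate_gene_means(self, region: str) -> pd.DataFrame:
        """Per-gene, per-replicate mean over redundant spots (genes × n_rep)."""
        expr = self.data[self.columns(region)].copy()
        expr["gene"] = self.data["gene"].values
        return expr.groupby("gene").mean()

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionTable":
        keep = self.data["gene"].isin(set(genes))
        return replace(self, data=self.data.loc[keep].reset_index(drop=True))


# -- reading and writing ---------------------------------------------------


def _parse_header(columns: Iterable[str]) -> tuple[tuple[str, ...], int]:
    seen: dict[str, dict[int, set[str]]] = {}
    order: list[str] = []
    for col in columns:
        m = _TRIPLET_RE.match(col)
        if m is None:
            continue
        region, rep = m["region"], int(m["rep"])
        if region not in seen:
            seen[region] = {}
            order.append(region)
        seen[region].setdefault(rep, set()).add(m["field"])
    if not order:
        raise FormatError("no <REGION>.R<j>.<field> measurement columns found")
    counts = set()
    for region in order:
        reps = seen[region]
        if sorted(reps) != list(range(1, len(reps) + 1)):
            raise FormatError(f"region {region!r}: replicate numbering must be R1..Rn")
        for rep, fields in reps.items():
            if fields != set(_FIELDS):
                raise FormatError(
                    f"region {region!r} replicate {rep}: incomplete fg/bg/expr triplet"
                )
        counts.add(len(reps))
    if len(counts) != 1:
        raise FormatError(f"unequal replicate counts per region: {sorted(counts)}")
    return tuple(order), counts.pop()


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Parse a TSV expression table, validating the dialect.

    Malformed numeric cells are rejected with their (1-based, header
    excluded) row numbers in the error message.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("spot_id", "gene"):
        if col not in raw.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    regions, n_rep = _parse_header(raw.columns)

    data = raw[["spot_id", "gene"]].copy()
    if "corrupted" in raw.columns:
        data["corrupted"] = (
            pd.to_numeric(raw["corrupted"], errors="coerce").fillna(0).astype(int)
        )
    else:
        data["corrupted"] = 0

    bad_rows: set[int] = set()
    meas_cols = [
        column_name(r, j, f)
        for r in regions
        for j in range(1, n_rep + 1)
        for f in _FIELDS
    ]
    for col in meas_cols:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        malformed = numeric.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        bad_rows.update((malformed[malformed].index + 1).tolist())
        data[col] = numeric.astype(float)
    if bad_rows:
        raise FormatError(
            f"{path.name}: non-numeric measurement values in rows "
            f"{sorted(bad_rows)[:20]}"
        )
    return ExpressionTable(data=data, regions=regions, n_replicates=n_rep)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# -- quality control -------------------------------------------------------


def spot_qc_filter(table: ExpressionTable) -> tuple[ExpressionTable, pd.DataFrame]:
    """Discard corrupted spots and spots with fg < 2×bg in any replicate.

    The boundary fg == 2×bg is retained (the rule is strict "less than").
    Spots with missing fluorescence in any replicate cannot be verified and
    are discarded as well.  Returns the filtered table and a discard report
    with one row per removed spot (columns: spot_id, gene, reason).
    """
    df = table.data
    corrupted = df["corrupted"].astype(bool).to_numpy()
    fg_cols = [c for r in table.regions for c in table.columns(r, "fg")]
    bg_cols = [c for r in table.regions for c in table.columns(r, "bg")]
    fg = df[fg_cols].to_numpy(dtype=float)
    bg = df[bg_cols].to_numpy(dtype=float)
    unverifiable = np.isnan(fg).any(axis=1) | np.isnan(bg).any(axis=1)
    dim = np.where(unverifiable, False, (fg < 2.0 * bg).any(axis=1))

    reason = np.select(
        [corrupted, unverifiable, dim],
        ["corrupted", "missing_fluorescence", "foreground_lt_2x_background"],
        default="",
    )
    drop = reason != ""
    report = pd.DataFrame(
        {
            "spot_id": df.loc[drop, "spot_id"].values,
            "gene": df.loc[drop, "gene"].values,
            "reason": reason[drop],
        }
    )
    filtered = replace(table, data=df.loc[~drop].reset_index(drop=True))
    return filtered, report


def eliminate_unquantified_genes(
    table: ExpressionTable,
) -> tuple[ExpressionTable, pd.DataFrame]:
    """Drop genes lacking a fully quantified surviving spot everywhere.

    A spot counts as quantified only when its expression value is finite in
    every replicate of every region; a gene is retained only if at least
    one of its spots is quantified (so the retained gene universe is the
    intersection across all region/replicate samples).  Returns the reduced
    table and a report of eliminated genes.
    """
    df = table.data
    expr_cols = [c for r in table.regions for c in table.columns(r, "expr")]
    complete = np.isfinite(df[expr_cols].to_numpy(dtype=float)).all(axis=1)
    quantified = df.loc[complete, "gene"].unique()
    keep = df["gene"].isin(quantified) & complete
    eliminated = sorted(set(df["gene"]) - set(quantified))
    report = pd.DataFrame({"gene": eliminated, "reason": "not_quantified_everywhere"})
    reduced = replace(table, data=df.loc[keep].reset_index(drop=True))
    return reduced, report


# -- gene sets -------------------------------------------------------------


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (pathways), symbols uppercase-normalized."""

    sets: Mapping[str, tuple[str, ...]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise FormatError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, name: str, universe: Iterable[str]) -> list[str]:
        """Members of a set quantified in ``universe`` (order preserved)."""
        allowed = {g.upper() for g in universe}
        return [g for g in self.sets[name] if g in allowed]


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated gene symbols.

    Blank lines are skipped; a duplicate set name is an error; unknown
    symbols are kept (they are intersected with the quantified universe at
    use time).
    """
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line needs name, description "
                    "and at least one gene"
                )
            name = parts[0].strip()
            if name in sets:
                raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            genes = tuple(
                dict.fromkeys(g.strip().upper() for g in parts[2:] if g.strip())
            )
            if not genes:
                raise FormatError(f"{path.name}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=descriptions)
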