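"""Coordination-based prediction of gene-manipulation effects.

If a target gene's expression is experimentally altered, its significantly
coordinated partners are predicted to follow: overexpressing the target
upregulates synergistic (S) partners and downregulates antagonistic (A)
ones; silencing does the opposite; partners that are independent (I) or
not significantly coordinated (blank) are predicted not regulated (NR).
Predictions are sign-only — no effect-size model is implied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ManipulationPlan",
    "predict_effects",
    "partner_fraction_report",
    "contrast_regions",
    "coordination_with_target",
]

DIRECTIONS = ("overexpress", "silence")

_EFFECT = {
    ("overexpress", "S"): "UR",
    ("overexpress", "A"): "DR",
    ("silence", "S"): "DR",
    ("silence", "A"): "UR",
}


@dataclass(frozen=True)
class ManipulationPlan:
    target: str
    direction: str  # "overexpress" or "silence"
    region: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


def coordination_with_target(table, region: str, target: str, scope=None) -> pd.DataFrame:
    """ρ/p/class of every scope gene against the target in one region."""
    from .expression import anchor_correlations

    cor = anchor_correlations(table, region, target)
    if scope is not None:
        scope = [g for g in scope if g in cor.index and g != target]
        cor = cor.loc[scope]
    return cor


def predict_effects(plan: ManipulationPlan, coordination: pd.DataFrame) -> pd.DataFrame:
    """Predicted regulation (UR/DR/NR) of each partner under the plan.

    ``coordination`` maps partner genes to ``rho`` and ``class`` columns
    (as produced by coordination_with_target).  The basis columns are kept
    so a blank class remains distinguishable from an explicit I.
    """
    out = coordination.copy()
    out["predicted"] = [
        _EFFECT.get((plan.direction, klass), "NR") for klass in out["class"]
    ]
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def partner_fraction_report(coordination: pd.DataFrame) -> dict[str, float]:
    """Counts and integer percentages of S/A partners in a scope.

    Percentages round half away from zero (so 33/88 → 38%, 14/25 → 56%).
    """
    n = len(coordination)
    n_s = int((coordination["class"] == "S").sum())
    n_a = int((coordination["class"] == "A").sum())
    return {
        "n_scope": n,
        "n_synergistic": n_s,
        "n_antagonistic": n_a,
        "pct_synergistic": _round_half_away(100.0 * n_s / n) if n else 0,
        "pct_antagonistic": _round_half_away(100.0 * n_a / n) if n else 0,
    }


def contrast_regions(
    coordination_a: pd.DataFrame,
    coordination_b: pd.DataFrame,
    region_a: str = "A",
    region_b: str = "B",
) -> pd.DataFrame:
    """Partners whose coordination class flips S↔A between two regions.

    A partner that is blank or I in either region is not a flip (there is
    insufficient evidence of a sign change).  Both correlation values are
    reported for the flipped partners.
    """
    shared = coordination_a.index.intersection(coordination_b.index)
    rows = []
    for gene in shared:
        ka = coordination_a.loc[gene, "class"]
        kb = coordination_b.loc[gene, "class"]
        if {ka, kb} == {"S", "A"}:
            rows.append(
                {
                    "gene": gene,
                    f"class_{region_a}": ka,
                    f"rho_{region_a}": float(coordination_a.loc[gene, "rho"]),
                    f"class_{region_b}": kb,
                    f"rho_{region_b}": float(coordination_b.loc[gene, "rho"]),
                }
            )
    cols = [
        "gene",
        f"class_{region_a}", f"rho_{region_a}",
        f"class_{region_b}", f"rho_{region_b}",
    ]
    return pd.DataFrame(rows, columns=cols).set_index("gene") if rows else (
        pd.DataFrame(columns=cols[1:], index=pd.Index([], name="gene"))
    )
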