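import numpy as np
import pandas as pd
import pytest

from genofabric.io_qc import ExpressionTable, column_name


def build_table(
    region_expr: dict[str, np.ndarray],
    genes: list[str],
    spot_ids: list[str] | None = None,
    bg_level: float = 10.0,
    corrupted: list[int] | None = None,
) -> ExpressionTable:
    """Hand-build an ExpressionTable from per-region (spots x reps) arrays.

    Foreground is set to 3x background so every spot passes QC unless the
    test overrides fluorescence afterwards.
    """
    regions = tuple(region_expr)
    first = np.asarray(next(iter(region_expr.values())), dtype=float)
    n_spots, n_rep = first.shape
    if spot_ids is None:
        spot_ids = [f"{g}_S{i}" for i, g in enumerate(genes)]
    data = pd.DataFrame(
        {
            "spot_id": spot_ids,
            "gene": genes,
            "corrupted": corrupted if corrupted is not None else 0,
        }
    )
    for region, arr in region_expr.items():
        arr = np.asarray(arr, dtype=float)
        assert arr.shape == (n_spots, n_rep)
        for j in range(n_rep):
            data[column_name(region, j + 1, "fg")] = 3.0 * bg_level
            data[column_name(region, j + 1, "bg")] = bg_level
            data[column_name(region, j + 1, "expr")] = arr[:, j]
    return ExpressionTable(data=data, regions=regions, n_replicates=n_rep)


@pytest.fixture
def table_builder():
    return build_table


@pytest.fixture
def two_region_table():
    """4 genes x 4 replicates in two regions with known structure.

    GA doubles in region B; GB is flat; GC is proportional to GA within
    each region (perfect coordination); GD is silent in region A only.
    """
    rng = np.random.default_rng(7)
    base = np.array([10.0, 11.0, 9.0, 10.5])
    expr_a = np.vstack([base, np.full(4, 5.0), 2 * base, np.zeros(4)])
    expr_b = np.vstack([2 * base, np.full(4, 5.0), 4 * base, np.full(4, 0.49)])
    return build_table(
        {"A": expr_a, "B": expr_b}, genes=["GA", "GB", "GC", "GD"]
    )


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "chemokine\tsignaling\tGA\tGB\tGC\n"
        "\n"
        "cycle\tcell cycle\tGC\tGD\tGX\n"
    )
    return path
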