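import dataclasses

import numpy as np
import pandas as pd
import pytest

from genofabric.io_qc import spot_qc_filter
from genofabric.simulate import (
    CorrelationBlock,
    PlantedGMR,
    SimulationConfig,
    read_fixture,
    simulate_dataset,
    truncated_geometric,
    write_fixture,
)


def small_config(**kw):
    defaults = dict(n_genes=20, regions=("A", "B"), n_replicates=4, seed=3)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(base_expression_law=(4.0, -0.5)),
            dict(cv_law=(0.0, 0.1)),
            dict(cv_law=(0.5, 1.2)),
            dict(n_replicates=1),
            dict(redundancy_law={0: 1.0}),
            dict(redundancy_law={25: 1.0}),
            dict(correlation_blocks=(CorrelationBlock((1, 2), 1.5),)),
            dict(correlation_blocks=(CorrelationBlock((1, 50), 0.5),)),
            dict(
                correlation_blocks=(
                    CorrelationBlock((1, 2), 0.5),
                    CorrelationBlock((2, 3), 0.5),
                )
            ),
            dict(planted_gmr=PlantedGMR(5)),  # no block to attach to
            dict(planted_regulation={50: {"B": 2.0}}),
            dict(planted_regulation={1: {"Z": 2.0}}),
            dict(background_level=-1.0),
        ],
    )
    def test_degenerate_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)


class TestSimulateDataset:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = small_config(qc_fail_fraction=0.05, corrupt_fraction=0.05)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture(simulate_dataset(cfg), d1)
        write_fixture(simulate_dataset(cfg), d2)
        assert (d1 / "expression.tsv").read_bytes() == (d2 / "expression.tsv").read_bytes()
        assert (d1 / "truth.json").read_bytes() == (d2 / "truth.json").read_bytes()

    def test_different_seed_differs(self):
        t1 = simulate_dataset(small_config(seed=1)).table
        t2 = simulate_dataset(small_config(seed=2)).table
        assert not t1.data.equals(t2.data)

    def test_block_correlation_matches_loading_product(self):
        # population check: single-spot genes, 1000 replicates, loadings 0.95
        cfg = SimulationConfig(
            n_genes=6,
            regions=("T",),
            n_replicates=1000,
            redundancy_law={1: 1.0},
            correlation_blocks=(CorrelationBlock(tuple(range(6)), 0.95),),
            seed=11,
        )
        table = simulate_dataset(cfg).table
        logs = np.log2(table.replicate_gene_means("T").to_numpy())
        rho = np.corrcoef(logs)
        off = rho[np.triu_indices(6, 1)]
        assert np.all(np.abs(off - 0.95**2) < 0.05)

    def test_planted_fold_change_recovered(self):
        cfg = small_config(
            cv_law=(0.001, 0.0011), planted_regulation={0: {"B": 2.0}, 1: {"B": -3.0}}
        )
        ds = simulate_dataset(cfg)
        means = {r: ds.table.replicate_gene_means(r).mean(axis=1) for r in ("A", "B")}
        assert means["B"]["G00000"] / means["A"]["G00000"] == pytest.approx(2.0, rel=0.01)
        assert means["B"]["G00001"] / means["A"]["G00001"] == pytest.approx(1 / 3, rel=0.01)

    def test_planted_off_gene_is_all_zero(self):
        ds = simulate_dataset(small_config(planted_regulation={2: {"A": 0.0}}))
        assert np.all(ds.table.gene_profile("G00002", "A") == 0)
        assert np.all(ds.table.gene_profile("G00002", "B") > 0)

    def test_sample_cv_converges_to_planted_cv(self):
        cfg = SimulationConfig(
            n_genes=5, regions=("T",), n_replicates=4000,
            redundancy_law={1: 1.0}, cv_law=(0.2, 0.4), seed=5,
        )
        ds = simulate_dataset(cfg)
        expr = ds.table.replicate_gene_means("T").to_numpy()
        cv_hat = expr.std(axis=1, ddof=1) / expr.mean(axis=1)
        assert np.allclose(cv_hat, ds.truth.cv, rtol=0.06)

    def test_redundancy_histogram_matches_law(self):
        law = {1: 0.5, 4: 0.3, 20: 0.2}
        cfg = SimulationConfig(
            n_genes=3000, regions=("T",), redundancy_law=law, seed=9
        )
        ds = simulate_dataset(cfg)
        counts = pd.Series(ds.truth.redundancy).value_counts()
        for k, p in law.items():
            expect = 3000 * p
            assert abs(counts[k] - expect) < 4 * np.sqrt(3000 * p * (1 - p))

    def test_planted_qc_failures_are_caught(self):
        cfg = small_config(n_genes=200, qc_fail_fraction=0.1)
        ds = simulate_dataset(cfg)
        _, report = spot_qc_filter(ds.table)
        n_fail = round(0.1 * ds.table.n_spots)
        assert len(report) == n_fail
        assert set(report["reason"]) == {"foreground_lt_2x_background"}

    def test_truncated_geometric_normalized(self):
        law = truncated_geometric(0.3)
        assert min(law) == 1 and max(law) == 20
        assert sum(law.values()) == pytest.approx(1.0)


class TestFixtureRoundTrip:
    def test_round_trip_equals_in_memory(self, tmp_path):
        ds = simulate_dataset(small_config(qc_fail_fraction=0.05))
        write_fixture(ds, tmp_path)
        table, truth = read_fixture(tmp_path)
        pd.testing.assert_frame_equal(table.data, ds.table.data)
        assert truth["gmr_gene"] is None
        assert len(truth["genes"]) == 20

    def test_empty_dataset_header_only(self, tmp_path):
        ds = simulate_dataset(small_config(n_genes=0))
        write_fixture(ds, tmp_path)
        text = (tmp_path / "expression.tsv").read_text()
        assert len(text.strip().splitlines()) == 1  # header only
        table, _ = read_fixture(tmp_path)
        assert table.n_spots == 0

    def test_spot_row_count_follows_redundancy(self, tmp_path):
        cfg = SimulationConfig(
            n_genes=10, regions=("A", "B"), redundancy_law={2: 1.0}, seed=0
        )
        ds = simulate_dataset(cfg)
        write_fixture(ds, tmp_path)
        table, _ = read_fixture(tmp_path)
        # wide dialect: 20 spot rows covering both regions' replicate columns
        assert table.n_spots == 20
        assert table.expression("A").shape == (20, 4)
        assert table.expression("B").shape == (20, 4)

    def test_truth_covers_planted_genes(self, tmp_path):
        cfg = small_config(
            correlation_blocks=(CorrelationBlock((0, 1, 2), 0.8),),
            planted_gmr=PlantedGMR(5, 0.9, 0.5),
            planted_regulation={7: {"B": 2.0}},
        )
        ds = simulate_dataset(cfg)
        write_fixture(ds, tmp_path)
        _, truth = read_fixture(tmp_path)
        assert truth["gmr_gene"] == "G00005"
        assert truth["genes"]["G00005"]["loading"] == pytest.approx(0.9)
        assert truth["genes"]["G00007"]["region_multiplier"]["B"] == pytest.approx(2.0)
        assert truth["genes"]["G00001"]["block"] == 0
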