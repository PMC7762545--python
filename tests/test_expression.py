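import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as ss

from genofabric.expression import (
    chi2_correction,
    classify_coordination,
    compute_ave,
    compute_correlation,
    compute_rev,
    correlation_matrix,
    correlation_pvalue,
    critical_rho,
    region_stats,
    rev_summary,
)
from genofabric.simulate import SimulationConfig, simulate_dataset


def spread_pattern():
    """4 replicate deviations with mean 0 and sample SD exactly 1."""
    p = np.array([-1.0, -1.0, 1.0, 1.0])
    return p / p.std(ddof=1)


class TestAve:
    def test_single_spot_mean(self):
        assert compute_ave(np.array([[2.0, 2.0, 2.0, 2.0]])) == 2.0

    def test_spots_weighted_equally(self):
        values = np.array([[1.0, 1.0, 1.0, 1.0], [3.0, 3.0, 3.0, 3.0]])
        assert compute_ave(values) == 2.0

    def test_all_zero_marks_not_expressed(self, table_builder):
        table = table_builder({"A": np.zeros((1, 4))}, genes=["G1"])
        stats = region_stats(table, "A")
        assert stats.loc["G1", "AVE"] == 0.0
        assert not stats.loc["G1", "expressed"]
        assert np.isnan(stats.loc["G1", "REV"])


class TestChi2Correction:
    def test_four_replicates_single_spot(self):
        # oracle: independent CDF inversion gives chi2(3; .025)=0.2158,
        # chi2(3; .975)=9.3484 -> 0.5*(3/9.3484 + 3/0.2158) = 7.111
        oracle = 0.5 * (3 / 9.3484 + 3 / 0.2158)
        assert chi2_correction(3) == pytest.approx(oracle, abs=2e-3)
        assert chi2_correction(3) == pytest.approx(7.11, abs=0.01)

    def test_large_dof_limit(self):
        assert abs(chi2_correction(10_000) - 1.0) < 0.02

    def test_monotone_decreasing_toward_one(self):
        assert chi2_correction(3) > chi2_correction(7) > chi2_correction(39) > 1.0

    def test_invalid_dof(self):
        with pytest.raises(ValueError):
            chi2_correction(0)


class TestRev:
    def test_zero_variance_gives_zero(self):
        assert compute_rev(np.full((3, 4), 5.0)) == 0.0

    def test_single_spot_known_cv(self):
        values = (1.0 + 0.10 * spread_pattern())[None, :]
        assert compute_rev(values) == pytest.approx(chi2_correction(3) * 10.0, rel=1e-9)
        assert compute_rev(values) == pytest.approx(71.1, abs=0.1)

    def test_pooling_two_identical_spots_uses_r7(self):
        one = 1.0 + 0.10 * spread_pattern()
        values = np.vstack([one, 2.0 * one])  # both spots have s/mu = 0.10
        assert compute_rev(values) == pytest.approx(chi2_correction(7) * 10.0, rel=1e-9)

    def test_zero_spot_mean_undefined(self):
        assert np.isnan(compute_rev(np.array([[0.0, 0.0, 0.0, 0.0], [1, 1, 1, 1]])))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(c=st.floats(min_value=1e-3, max_value=1e6))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        values = rng.lognormal(2.0, 0.3, size=(3, 4))
        assert compute_rev(c * values) == pytest.approx(compute_rev(values), rel=1e-9)


class TestCoordination:
    def test_proportional_vectors_synergistic(self, table_builder):
        base = np.array([10.0, 11.0, 9.0, 10.5])
        table = table_builder(
            {"A": np.vstack([base, 3 * base])}, genes=["G1", "G2"]
        )
        entry = compute_correlation(table, "G1", "G2", "A")
        assert entry.rho == pytest.approx(1.0)
        assert entry.p_value < 0.05
        assert entry.klass == "S"
        assert entry.dof == 2

    def test_significance_threshold_at_dof2(self):
        # the critical |rho| quoted for 4 replicas is 0.95
        assert critical_rho(2, 0.05) == pytest.approx(0.95, abs=1e-6)

    def test_moderate_rho_not_significant(self):
        # t = rho*sqrt(dof/(1-rho^2)) at dof=2: p = 0.5 -> blank
        p = correlation_pvalue(0.5, 2)
        assert p == pytest.approx(0.5, abs=1e-9)
        assert classify_coordination(0.5, p) == ""

    @pytest.mark.parametrize(
        "rho,expected",
        [(0.99, "S"), (-0.96, "A"), (0.5, ""), (0.03, "I")],
    )
    def test_classification_at_dof2(self, rho, expected):
        assert classify_coordination(rho, correlation_pvalue(rho, 2)) == expected

    def test_constant_vector_blank(self, table_builder):
        table = table_builder(
            {"A": np.vstack([np.full(4, 5.0), [1.0, 2.0, 3.0, 4.0]])},
            genes=["G1", "G2"],
        )
        entry = compute_correlation(table, "G1", "G2", "A")
        assert np.isnan(entry.rho) and entry.klass == ""

    def test_zero_expression_excluded_from_cor(self, two_region_table):
        entry = compute_correlation(two_region_table, "GA", "GD", "A")
        assert np.isnan(entry.rho)  # GD is silent in A: on/off, not COR

    def test_spot_pairing_requires_equal_redundancy(self, table_builder):
        table = table_builder(
            {"A": np.ones((3, 4)) + np.arange(12).reshape(3, 4)},
            genes=["G1", "G1", "G2"], spot_ids=["s1", "s2", "s3"],
        )
        with pytest.raises(ValueError, match="equal redundancy"):
            compute_correlation(table, "G1", "G2", "A", pairing="spot")

    def test_matrix_symmetric_diagonal_excluded(self, two_region_table):
        rho, p = correlation_matrix(two_region_table, "B")
        arr = rho.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(arr)))
        # GA vs GC are proportional -> rho 1 in the off-diagonal
        assert rho.loc["GA", "GC"] == pytest.approx(1.0)


class TestIndependenceOfCharacteristics:
    def test_ave_rev_cor_vary_independently(self, table_builder):
        base = np.array([10.0, 11.0, 9.0, 10.5])
        partner = np.array([5.0, 5.6, 4.4, 5.2])
        t0 = table_builder({"A": np.vstack([base, partner])}, genes=["G1", "G2"])
        # scaling G1 changes AVE only
        t1 = table_builder({"A": np.vstack([3 * base, partner])}, genes=["G1", "G2"])
        # widening G1's spread around the same mean changes REV (and here
        # leaves the perfect pairing with its own pattern intact)
        widened = base.mean() + 3 * (base - base.mean())
        t2 = table_builder({"A": np.vstack([widened, partner])}, genes=["G1", "G2"])
        s0, s1, s2 = (region_stats(t, "A") for t in (t0, t1, t2))
        assert s1.loc["G1", "AVE"] == pytest.approx(3 * s0.loc["G1", "AVE"])
        assert s1.loc["G1", "REV"] == pytest.approx(s0.loc["G1", "REV"])
        assert s2.loc["G1", "AVE"] == pytest.approx(s0.loc["G1", "AVE"])
        assert s2.loc["G1", "REV"] == pytest.approx(3 * s0.loc["G1", "REV"], rel=1e-6)
        r0 = compute_correlation(t0, "G1", "G2", "A").rho
        r1 = compute_correlation(t1, "G1", "G2", "A").rho
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_planted_cv_ranks_recovered(self):
        # estimator-consistency check at a replicate count where the pooled
        # CV is identifiable; the 4-replicate design is noisier (see docs)
        rs = []
        for seed in range(3):
            cfg = SimulationConfig(
                n_genes=500, regions=("T",), n_replicates=12,
                cv_law=(0.05, 0.5), seed=seed,
            )
            ds = simulate_dataset(cfg)
            stats = region_stats(ds.table, "T")
            corr = np.array([chi2_correction(int(r)) for r in stats["r_dof"]])
            cv_hat = stats["REV"].to_numpy() / corr / 100.0
            rs.append(ss.spearmanr(cv_hat, ds.truth.cv).statistic)
        assert np.mean(rs) >= 0.9


class TestRevSummary:
    def test_reduction_from_known_medians(self):
        revs = {
            "NOR": np.array([41.0, 41.5, 42.0]),
            "PTA": np.array([36.6, 37.12, 37.6]),
        }
        out = rev_summary(revs, "NOR")
        assert out.loc["NOR", "median_rev"] == 41.5
        assert out.loc["PTA", "reduction_vs_reference"] == pytest.approx(10.55, abs=0.01)

    def test_identical_distributions_null(self):
        rng = np.random.default_rng(1)
        v = rng.normal(40, 5, size=60)
        out = rev_summary({"R1": v, "R2": v.copy()}, "R1")
        assert out.loc["R2", "reduction_vs_reference"] == pytest.approx(0.0)
        assert out.loc["R2", "p_value"] > 0.5

    def test_ztest_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(42)
        ref = rng.normal(40.0, 5.0, size=50)
        alt = rng.normal(38.8, 5.0, size=50)
        p_z = rev_summary({"ref": ref, "alt": alt}, "ref").loc["alt", "p_value"]
        # permutation oracle: two-tail p of the mean difference, 1e5 draws
        pooled = np.concatenate([ref, alt])
        observed = abs(ref.mean() - alt.mean())
        perm_rng = np.random.default_rng(123)
        count = 0
        n_perm = 100_000
        for _ in range(n_perm):
            perm = perm_rng.permutation(pooled)
            count += abs(perm[:50].mean() - perm[50:].mean()) >= observed
        p_perm = count / n_perm
        assert p_z == pytest.approx(p_perm, abs=0.01)

    def test_needs_reference_values(self):
        with pytest.raises(ValueError):
            rev_summary({"R": np.array([1.0])}, "R")
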