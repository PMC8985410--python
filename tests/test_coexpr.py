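"""Coexpression network: correlation, soft threshold, TOM oracle, clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from convergene import coexpr, synthdata


def study_from_matrix(values: np.ndarray, phenotype=None) -> synthdata.ExpressionStudy:
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    if phenotype is None:
        phenotype = [0] * (values.shape[1] // 2) + [1] * (
            values.shape[1] - values.shape[1] // 2
        )
    return synthdata.ExpressionStudy(
        values=pd.DataFrame(values, index=genes, columns=samples),
        phenotype=pd.Series(phenotype, index=samples),
    )


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook covariance-formula Pearson correlation."""
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Naive O(n^3) topological overlap."""
    n = a.shape[0]
    k = a.sum(axis=0) - np.diag(a)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestCorrelationMatrix:
    def test_duplicated_gene_correlates_one(self, rng):
        row = rng.standard_normal(20)
        study = study_from_matrix(np.vstack([row, row, rng.standard_normal(20)]))
        r = coexpr.correlation_matrix(study)
        assert r.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_gene_correlates_minus_one(self, rng):
        row = rng.standard_normal(20)
        study = study_from_matrix(np.vstack([row, -row]))
        r = coexpr.correlation_matrix(study)
        assert r.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        values = rng.standard_normal((10, 15))
        study = study_from_matrix(values)
        r = coexpr.correlation_matrix(study).to_numpy()
        for i in range(10):
            for j in range(i + 1, 10):
                assert r[i, j] == pytest.approx(
                    pearson_oracle(values[i], values[j]), abs=1e-12
                )

    def test_zero_variance_gene_warned_and_zeroed(self, rng):
        values = np.vstack([np.full(12, 5.0), rng.standard_normal((2, 12))])
        study = study_from_matrix(values)
        with pytest.warns(UserWarning, match="zero-variance"):
            r = coexpr.correlation_matrix(study)
        assert (r.iloc[0, 1:] == 0).all()
        assert r.iloc[0, 0] == 1.0


class TestAdjacency:
    def test_power_one_is_absolute_correlation(self, rng):
        r = rng.uniform(-1, 1, size=(6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        np.testing.assert_allclose(coexpr.adjacency(r, 1), np.abs(r))

    def test_half_to_the_sixth(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert coexpr.adjacency(r, 6)[0, 1] == pytest.approx(0.015625)

    def test_entries_non_increasing_in_power(self, rng):
        r = rng.uniform(-0.99, 0.99, size=(8, 8))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        prev = coexpr.adjacency(r, 1)
        for beta in range(2, 21):
            cur = coexpr.adjacency(r, beta)
            off = ~np.eye(8, dtype=bool)
            assert (cur[off] <= prev[off] + 1e-15).all()
            prev = cur

    def test_non_integer_power_rejected(self):
        with pytest.raises(ValueError):
            coexpr.adjacency(np.eye(3), 0)


class TestSoftThreshold:
    def test_scans_powers_one_to_twenty(self, planted_study):
        r = coexpr.correlation_matrix(planted_study)
        scan = coexpr.pick_soft_threshold(r)
        assert scan.powers == list(range(1, 21))

    def test_modular_network_reaches_fit_target(self):
        config = synthdata.SimulationConfig(deg_fraction=0.0, seed=0)
        study = synthdata.simulate_expression(config)
        scan = coexpr.pick_soft_threshold(coexpr.correlation_matrix(study))
        assert scan.target_reached
        assert max(scan.fit_r2) > 0.80

    def test_fallback_returns_argmax_with_warning(self, rng):
        # pure noise at tiny n rarely reaches the fit target at any power
        values = rng.standard_normal((40, 6))
        r = coexpr.correlation_matrix(study_from_matrix(values))
        with pytest.warns(UserWarning, match="argmax"):
            scan = coexpr.pick_soft_threshold(r, r2_target=0.999)
        assert not scan.target_reached
        assert scan.chosen_power == scan.powers[int(np.argmax(scan.fit_r2))]


class TestTOM:
    def test_two_gene_network_collapses_to_adjacency(self):
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        t = coexpr.tom(a)
        assert t[0, 1] == pytest.approx(0.3)

    def test_complete_network_is_all_ones(self):
        a = np.ones((5, 5))
        np.testing.assert_allclose(coexpr.tom(a), 1.0)

    @pytest.mark.parametrize("n", [5, 10, 17, 25])
    def test_matches_brute_force_oracle(self, n, rng):
        r = rng.uniform(0, 1, size=(n, n))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(coexpr.tom(a), tom_oracle(a), atol=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(5):
            r = rng.uniform(0, 1, size=(12, 12))
            a = (r + r.T) / 2
            np.fill_diagonal(a, 1.0)
            t = coexpr.tom(a)
            assert t.min() >= 0.0 and t.max() <= 1.0


class TestClusterModules:
    def test_two_separated_blocks_recovered_exactly(self):
        t = np.full((40, 40), 0.05)
        t[:20, :20] = 0.9
        t[20:, 20:] = 0.9
        np.fill_diagonal(t, 1.0)
        part = coexpr.cluster_modules(t, min_module_size=10)
        truth = [1] * 20 + [2] * 20
        assert adjusted_rand_score(truth, part.assignment) == 1.0
        assert len(part.labels) == 2

    def test_identical_genes_form_single_module(self):
        t = np.ones((35, 35))
        part = coexpr.cluster_modules(t, min_module_size=30)
        assert len(part.labels) == 1
        assert (part.assignment == 1).all()

    def test_oversized_minimum_unassigns_everything(self):
        t = np.full((20, 20), 0.05)
        t[:10, :10] = 0.9
        t[10:, 10:] = 0.9
        np.fill_diagonal(t, 1.0)
        part = coexpr.cluster_modules(t, min_module_size=15)
        assert (part.assignment == 0).all()

    def test_partition_invariant_under_gene_permutation(self, rng):
        t = np.full((30, 30), 0.1)
        t[:15, :15] = 0.8
        t[15:, 15:] = 0.8
        np.fill_diagonal(t, 1.0)
        base = coexpr.cluster_modules(t, min_module_size=5).assignment.to_numpy()
        perm = rng.permutation(30)
        permuted = coexpr.cluster_modules(
            t[np.ix_(perm, perm)], min_module_size=5
        ).assignment.to_numpy()
        assert adjusted_rand_score(base[perm], permuted) == 1.0

    def test_planted_modules_recovered_at_generator_defaults(self):
        """Membership ARI > 0.8 at rho = 0.7 with 60 samples per group."""
        config = synthdata.SimulationConfig(deg_fraction=0.0, seed=1)
        study = synthdata.simulate_expression(config)
        corr = coexpr.correlation_matrix(study)
        scan = coexpr.pick_soft_threshold(corr)
        t = coexpr.tom(coexpr.adjacency(corr.to_numpy(), scan.chosen_power))
        part = coexpr.cluster_modules(
            pd.DataFrame(t, index=corr.index, columns=corr.index)
        )
        planted = study.truth["module"]
        assert adjusted_rand_score(planted, part.assignment) > 0.8


class TestEigengenes:
    def test_single_gene_module_is_its_z_score(self, rng):
        values = rng.standard_normal((3, 16))
        study = study_from_matrix(values)
        assignment = pd.Series([1, 0, 0], index=study.values.index)
        eig = coexpr.module_eigengene(study, assignment, 1)
        z = (values[0] - values[0].mean()) / values[0].std(ddof=1)
        np.testing.assert_allclose(eig.to_numpy(), z, atol=1e-10)

    def test_identical_members_correlate_one_with_eigengene(self, rng):
        row = rng.standard_normal(14)
        study = study_from_matrix(np.vstack([row] * 4))
        assignment = pd.Series([1] * 4, index=study.values.index)
        eig = coexpr.module_eigengene(study, assignment, 1)
        assert np.corrcoef(eig, row)[0, 1] == pytest.approx(1.0)

    def test_explains_more_variance_than_random_directions(self, rng):
        values = rng.standard_normal((20, 30))
        study = study_from_matrix(values)
        assignment = pd.Series([1] * 20, index=study.values.index)
        eig = coexpr.module_eigengene(study, assignment, 1).to_numpy()
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, ddof=1, keepdims=True
        )
        eig_var = ((z @ eig) ** 2).sum() / (eig @ eig)
        for _ in range(100):
            u = rng.standard_normal(30)
            assert ((z @ u) ** 2).sum() / (u @ u) <= eig_var + 1e-9

    def test_empty_module_rejected(self, rng):
        study = study_from_matrix(rng.standard_normal((3, 10)))
        assignment = pd.Series([1, 1, 1], index=study.values.index)
        with pytest.raises(ValueError, match="empty"):
            coexpr.module_eigengene(study, assignment, 2)


class TestModuleTrait:
    def test_eigengene_equal_to_phenotype_gives_r_one(self):
        pheno = pd.Series([0, 0, 0, 1, 1, 1], index=[f"s{i}" for i in range(6)])
        eig = (pheno - pheno.mean()) / pheno.std(ddof=1)
        table = coexpr.module_trait_correlation(eig.to_frame("ME1"), pheno)
        assert table.loc["ME1", "correlation"] == pytest.approx(1.0)
        assert table.loc["ME1", "p_value"] == pytest.approx(0.0, abs=1e-12)

    def test_p_value_matches_t_transform_oracle(self, rng):
        n = 10
        eig = pd.DataFrame({"ME1": rng.standard_normal(n)})
        pheno = pd.Series(rng.integers(0, 2, size=n))
        pheno.iloc[0], pheno.iloc[1] = 0, 1  # both classes present
        table = coexpr.module_trait_correlation(eig, pheno)
        r = np.corrcoef(eig["ME1"], pheno)[0, 1]
        from scipy import stats

        t_stat = r * np.sqrt((n - 2) / (1 - r**2))
        expected = 2 * stats.t.sf(abs(t_stat), df=n - 2)
        assert table.loc["ME1", "p_value"] == pytest.approx(expected, abs=1e-10)

    def test_constant_phenotype_rejected(self, rng):
        eig = pd.DataFrame({"ME1": rng.standard_normal(8)})
        with pytest.raises(ValueError, match="constant"):
            coexpr.module_trait_correlation(eig, pd.Series(np.ones(8)))


class TestSelectADModule:
    def test_single_significant_positive_module_selected(self):
        table = pd.DataFrame(
            {"correlation": [0.6], "p_value": [0.001]}, index=["ME1"]
        )
        assert coexpr.select_ad_module(table) == "ME1"

    def test_all_negative_correlations_give_none(self):
        table = pd.DataFrame(
            {"correlation": [-0.5, -0.7], "p_value": [0.001, 0.001]},
            index=["ME1", "ME2"],
        )
        assert coexpr.select_ad_module(table) is None

    def test_tie_broken_by_smaller_label(self):
        table = pd.DataFrame(
            {"correlation": [0.5, 0.5], "p_value": [0.01, 0.01]},
            index=["ME2", "ME1"],
        )
        assert coexpr.select_ad_module(table) == "ME1"

    def test_insignificant_modules_excluded(self):
        table = pd.DataFrame(
            {"correlation": [0.9, 0.3], "p_value": [0.2, 0.01]},
            index=["ME1", "ME2"],
        )
        assert coexpr.select_ad_module(table) == "ME2"
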