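"""Network construction: bicor, adjacency, scale-free fit, TOM, modules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexnet.network import (
    adjacency,
    bicor,
    correlation_matrix,
    detect_modules,
    intramodular_connectivity,
    pick_soft_threshold,
    scale_free_fit,
    tom_similarity,
)
from coexnet.simulate import SyntheticConfig, generate_dataset
from tests.conftest import random_expr


def bicor_reference(x, y):
    """Direct transcription of the biweight midcorrelation formula."""
    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w
    a, b = weights(np.asarray(x, float)), weights(np.asarray(y, float))
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(30)
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 25))
            assert bicor(x, y) == pytest.approx(bicor_reference(x, y), abs=1e-12)

    def test_close_to_pearson_on_clean_gaussian_data(self, rng):
        cov = [[1.0, 0.7], [0.7, 1.0]]
        x, y = rng.multivariate_normal([0, 0], cov, size=1000).T
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(bicor(x, y) - pearson) < 0.05

    def test_downweights_a_gross_outlier(self, rng):
        x = rng.standard_normal(50)
        y = x + 0.05 * rng.standard_normal(50)
        y_bad = y.copy()
        y_bad[0] = 1000.0
        assert bicor(x, y_bad) > np.corrcoef(x, y_bad)[0, 1] + 0.2

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 5.0])  # MAD 0, not constant
        y = np.array([0.1, 0.2, 0.4, 0.3, 5.0])
        with pytest.warns(UserWarning, match="zero MAD"):
            r = bicor(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            bicor(np.ones(3), np.ones(3))


class TestCorrelationMatrix:
    def test_matches_scalar_bicor_pairwise(self, rng):
        expr = random_expr(rng, 20, 10)
        cor = correlation_matrix(expr)
        values = expr.to_numpy()
        for i in range(0, 20, 3):
            for j in range(i + 1, 20, 4):
                assert cor.iloc[i, j] == pytest.approx(bicor(values[i], values[j]), abs=1e-12)

    def test_symmetric_with_unit_diagonal(self, rng):
        cor = correlation_matrix(random_expr(rng, 15, 8)).to_numpy()
        assert np.allclose(cor, cor.T)
        assert np.allclose(np.diag(cor), 1.0)

    def test_identical_genes_have_correlation_one(self, rng):
        expr = random_expr(rng, 1, 10)
        expr = pd.concat([expr, expr.rename(index={"g0": "g1"})])
        assert correlation_matrix(expr).iloc[0, 1] == pytest.approx(1.0)


class TestAdjacency:
    def test_power_of_absolute_correlation(self, rng):
        cor = correlation_matrix(random_expr(rng, 5, 8))
        adj = adjacency(cor, 2.0)
        assert adj.iloc[0, 1] == pytest.approx(abs(cor.iloc[0, 1]) ** 2)
        assert adj.iloc[0, 0] == 0.0  # diagonal convention for connectivity

    def test_specific_value(self):
        cor = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        assert adjacency(cor, 2.0).iloc[0, 1] == pytest.approx(0.25)
        assert adjacency(cor, 7.0).loc["a", "b"] == pytest.approx(0.5**7)

    def test_beta_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            adjacency(correlation_matrix(random_expr(rng, 4, 6)), 0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(1.0, 20.0))
    def test_monotone_in_absolute_correlation(self, r1, r2, beta):
        lo, hi = sorted([r1, r2])
        assert lo**beta <= hi**beta


class TestScaleFreeFit:
    def test_exact_power_law_fits_perfectly(self):
        # frequencies proportional to 1/k over geometric bin centres
        k = np.concatenate([np.full(int(round(1000 / c)), float(c)) for c in (1, 2, 4, 8, 16, 32)])
        r2, slope = scale_free_fit(k, n_bins=40)
        assert r2 >= 0.99
        assert slope < 0

    def test_independent_least_squares_oracle(self):
        k = np.concatenate([np.full(200, 1.0), np.full(100, 2.0), np.full(50, 3.0)])
        r2, slope = scale_free_fit(k, n_bins=3)
        x = np.log10([1.0, 2.0, 3.0])
        y = np.log10(np.array([200, 100, 50]) / 350)
        slope_ref, intercept = np.polyfit(x, y, 1)
        pred = slope_ref * x + intercept
        r2_ref = 1 - ((y - pred) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 == pytest.approx(r2_ref, abs=1e-12)
        assert slope == pytest.approx(slope_ref, abs=1e-12)

    def test_constant_connectivity_gives_zero(self):
        with pytest.warns(UserWarning):
            assert scale_free_fit(np.full(100, 3.0)) == (0.0, 0.0)

    def test_positive_slope_zeroes_the_index(self):
        k = np.concatenate([np.full(10, 1.0), np.full(100, 2.0), np.full(1000, 3.0)])
        r2, slope = scale_free_fit(k, n_bins=3)
        assert r2 == 0.0
        assert slope > 0


class TestPickSoftThreshold:
    def test_singleton_grid_returns_that_beta(self, small_dataset):
        expr, _, _ = small_dataset
        assert pick_soft_threshold(expr, beta_grid=(10,)).beta == 10

    def test_default_synthetic_data_reaches_target(self, small_dataset):
        expr, _, _ = small_dataset
        result = pick_soft_threshold(expr)
        assert result.reached_target
        assert result.fit_index >= 0.8

    def test_pure_noise_flags_unreached_target(self):
        flagged = 0
        for seed in range(10):
            expr = random_expr(np.random.default_rng(seed), 200, 12)
            with pytest.warns(UserWarning):
                result = pick_soft_threshold(expr, beta_grid=tuple(range(1, 7)), target_r2=0.95)
            flagged += not result.reached_target
        assert flagged >= 9

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            pick_soft_threshold(random_expr(rng, 20, 8))


def tom_reference(a):
    """O(n^3) direct evaluation of unsigned topological overlap."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTom:
    def test_fully_connected_triangle(self):
        a = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        tom = tom_similarity(a)
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_empty_graph(self):
        a = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        tom = tom_similarity(a).to_numpy()
        assert np.allclose(tom, np.eye(4))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            raw = rng.uniform(0, 1, size=(6, 6))
            a = (raw + raw.T) / 2
            np.fill_diagonal(a, 0.0)
            frame = pd.DataFrame(a, index=[f"g{i}" for i in range(6)], columns=[f"g{i}" for i in range(6)])
            assert np.allclose(tom_similarity(frame).to_numpy(), tom_reference(a), atol=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        raw = rng.uniform(0, 1, size=(10, 10))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 0.0)
        frame = pd.DataFrame(a, index=[f"g{i}" for i in range(10)], columns=[f"g{i}" for i in range(10)])
        tom = tom_similarity(frame).to_numpy()
        assert tom.min() >= 0.0 and tom.max() <= 1.0


def _block_tom(rng, sizes, n_noise):
    """TOM of a noiseless block-diagonal design plus independent noise genes."""
    genes = []
    profiles = []
    for b, size in enumerate(sizes):
        u = rng.standard_normal(40)
        for i in range(size):
            genes.append(f"b{b}_g{i}")
            profiles.append(u * rng.uniform(0.5, 1.5))
    for i in range(n_noise):
        genes.append(f"noise_{i}")
        profiles.append(rng.standard_normal(40))
    expr = pd.DataFrame(profiles, index=genes)
    return tom_similarity(adjacency(correlation_matrix(expr, method="pearson"), 6.0)), expr


class TestDetectModules:
    def test_recovers_noiseless_planted_blocks_exactly(self, rng):
        tom, expr = _block_tom(rng, [60, 60, 60], 50)
        assignment = detect_modules(tom, min_module_size=50)
        blocks = pd.Series([g.split("_")[0] for g in expr.index], index=expr.index)
        for label in assignment[assignment != "grey"].unique():
            members = blocks[assignment == label]
            assert members.nunique() == 1
            assert len(members) == 60
        assert assignment[assignment != "grey"].nunique() == 3
        assert (assignment[blocks == "noise"] == "grey").all()

    def test_block_below_min_size_goes_grey(self, rng):
        tom, expr = _block_tom(rng, [60, 30], 40)
        assignment = detect_modules(tom, min_module_size=50)
        blocks = pd.Series([g.split("_")[0] for g in expr.index], index=expr.index)
        assert (assignment[blocks == "b1"] == "grey").all()
        assert (assignment[blocks == "b0"] != "grey").all()

    def test_gene_order_does_not_change_partition(self, rng):
        tom, _ = _block_tom(rng, [55, 55], 30)
        direct = detect_modules(tom, min_module_size=50)
        perm = rng.permutation(len(tom))
        shuffled_tom = tom.iloc[perm, perm]
        shuffled = detect_modules(shuffled_tom, min_module_size=50)
        joined = pd.DataFrame({"a": direct, "b": shuffled.reindex(direct.index)})
        # identical partition: label pairs are in bijection
        assert joined.groupby("a")["b"].nunique().max() == 1
        assert joined.groupby("b")["a"].nunique().max() == 1

    def test_min_size_above_gene_count_gives_all_grey(self, rng):
        tom, _ = _block_tom(rng, [10], 0)
        with pytest.warns(UserWarning):
            assignment = detect_modules(tom, min_module_size=100)
        assert (assignment == "grey").all()

    def test_labels_are_colors_by_decreasing_size(self, rng):
        tom, _ = _block_tom(rng, [80, 55], 30)
        assignment = detect_modules(tom, min_module_size=50)
        sizes = assignment[assignment != "grey"].value_counts()
        assert list(sizes.index[:2]) == ["turquoise", "blue"]
        assert sizes["turquoise"] >= sizes["blue"]


class TestPlantedRecovery:
    def test_planted_modules_recovered_across_seeds(self):
        from sklearn.metrics import adjusted_rand_score

        passes = 0
        for seed in range(20):
            cfg = SyntheticConfig(module_sizes=(120, 90, 70), n_background=320, seed=seed)
            expr, _, truth = generate_dataset(cfg)
            tom = tom_similarity(adjacency(correlation_matrix(expr), 10.0))
            assignment = detect_modules(tom, min_module_size=50)
            non_grey = assignment[assignment != "grey"]
            if len(non_grey) == 0:
                continue
            planted = pd.Series(truth.module_of_gene).loc[non_grey.index]
            if adjusted_rand_score(planted, non_grey) >= 0.8:
                passes += 1
        assert passes >= 18


class TestIntramodularConnectivity:
    def test_three_gene_module_row_sums(self):
        genes = ["g1", "g2", "g3"]
        a = pd.DataFrame(
            [[0.0, 0.5, 0.2], [0.5, 0.0, 0.1], [0.2, 0.1, 0.0]], index=genes, columns=genes
        )
        assignment = pd.Series("turquoise", index=genes)
        stats = intramodular_connectivity(a, assignment)
        assert np.allclose(stats["kWithin"], [0.7, 0.6, 0.3])
        assert np.allclose(stats["kTotal"], stats["kWithin"])

    def test_singleton_module_has_zero_kwithin(self):
        genes = ["g1", "g2"]
        a = pd.DataFrame([[0.0, 0.9], [0.9, 0.0]], index=genes, columns=genes)
        stats = intramodular_connectivity(a, pd.Series(["blue", "red"], index=genes))
        assert np.allclose(stats["kWithin"], 0.0)
        assert np.allclose(stats["kTotal"], 0.9)

    def test_matches_brute_force_double_loop(self, rng):
        n = 8
        raw = rng.uniform(0, 1, (n, n))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 0.0)
        genes = [f"g{i}" for i in range(n)]
        frame = pd.DataFrame(a, index=genes, columns=genes)
        assignment = pd.Series(rng.choice(["m1", "m2"], n), index=genes)
        stats = intramodular_connectivity(frame, assignment)
        for i in range(n):
            k_within = sum(
                a[i, j] for j in range(n) if j != i and assignment.iloc[j] == assignment.iloc[i]
            )
            assert stats["kWithin"].iloc[i] == pytest.approx(k_within, abs=1e-12)
            assert stats["kTotal"].iloc[i] == pytest.approx(a[i].sum(), abs=1e-12)

    def test_ktotal_decomposes_into_within_plus_out(self, rng):
        expr = random_expr(rng, 30, 10)
        a = adjacency(correlation_matrix(expr), 6.0)
        assignment = pd.Series(
            np.repeat(["m1", "m2", "grey"], 10), index=expr.index
        )
        stats = intramodular_connectivity(a, assignment)
        out_of_module = stats["kTotal"] - stats["kWithin"]
        assert (out_of_module >= -1e-12).all()
        # recompute out-of-module directly for one gene
        g = expr.index[0]
        others = [h for h in expr.index if assignment[h] != assignment[g]]
        assert out_of_module[g] == pytest.approx(a.loc[g, others].sum(), abs=1e-12)

    def test_incomplete_assignment_rejected(self, rng):
        expr = random_expr(rng, 6, 8)
        a = adjacency(correlation_matrix(expr), 2.0)
        with pytest.raises(ValueError):
            intramodular_connectivity(a, pd.Series("m", index=expr.index[:-1]))
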