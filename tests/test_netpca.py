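import numpy as np
import pytest

from metnetpca.data_network import DataMatrix, build_data_network, uv_scale
from metnetpca.netpca import (
    block_influence,
    fit_netpca,
    select_markers,
    variable_explained_variance,
)
from metnetpca.synthetic import generate_cohort, paper_design

from conftest import random_data_network


def single_matrix_network(rng, n=20, p=10):
    m = DataMatrix(
        rng.normal(size=(n, p)),
        [f"o{i}" for i in range(n)],
        [f"v{i}" for i in range(p)],
        "g", "b",
    )
    return build_data_network([m])


def rank1_network(rng, groups=("gA", "gB"), blocks=("b1", "b2"), n=6, p=4):
    """Noiseless network X(g,b) = t(g) p(b)^T."""
    t = {g: rng.normal(size=n) for g in groups}
    p_vecs = {b: rng.normal(size=p) for b in blocks}
    mats = []
    for g in groups:
        for b in blocks:
            mats.append(
                DataMatrix(
                    np.outer(t[g], p_vecs[b]),
                    [f"{g}_o{i}" for i in range(n)],
                    [f"{b}_v{i}" for i in range(p)],
                    g, b,
                )
            )
    return build_data_network(mats), t, p_vecs


class TestFit:
    def test_single_matrix_equals_leading_svd_triplets(self):
        rng = np.random.default_rng(0)
        net = single_matrix_network(rng)
        model = fit_netpca(net, n_components=3, tol=1e-14, max_iter=2000)
        X = net.matrices[0].values
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        for a in range(3):
            p_hat = model.loadings["b"][:, a]
            t_hat = model.scores["g"][:, a]
            sign = np.sign(p_hat @ Vt[a])
            np.testing.assert_allclose(p_hat, sign * Vt[a], atol=1e-7)
            np.testing.assert_allclose(t_hat, sign * s[a] * U[:, a], atol=1e-6)

    def test_single_matrix_reconstruction_error_matches_truncated_svd(self):
        # reconstruction-error equivalence with the rank-3 SVD to 1e-8 relative
        rng = np.random.default_rng(1)
        net = single_matrix_network(rng)
        model = fit_netpca(net, n_components=3, tol=1e-14, max_iter=2000)
        X = net.matrices[0].values
        _, s, _ = np.linalg.svd(X, full_matrices=False)
        svd_residual = np.sum(s[3:] ** 2)
        fitted = sum(
            float(model.scores["g"][:, a] @ model.scores["g"][:, a])
            for a in range(3)
        )
        netpca_residual = np.sum(X**2) - fitted
        assert netpca_residual == pytest.approx(svd_residual, rel=1e-8)

    def test_noiseless_rank1_network_recovered_exactly(self):
        rng = np.random.default_rng(2)
        net, t_true, p_true = rank1_network(rng)
        model = fit_netpca(net, n_components=1)
        assert model.component_variance[0] == pytest.approx(100.0, abs=1e-8)
        # loadings proportional to the planted vectors (global sign/scale free)
        p_hat = np.concatenate([model.loadings[b][:, 0] for b in ("b1", "b2")])
        p_plant = np.concatenate([p_true[b] for b in ("b1", "b2")])
        cos = abs(p_hat @ p_plant) / np.linalg.norm(p_plant)
        assert cos == pytest.approx(1.0, rel=1e-8)

    def test_variance_bookkeeping_decomposes_total_ss(self, cohort):
        model, scaled = cohort["model"], cohort["scaled"]
        total = scaled.total_sum_of_squares()
        fitted = sum(
            sum(float(model.scores[g][:, a] @ model.scores[g][:, a]) for g in model.scores)
            for a in range(model.n_components)
        )
        residual = 0.0
        for m in scaled.matrices:
            approx = sum(
                np.outer(model.scores[m.row_class][:, a], model.loadings[m.col_class][:, a])
                for a in range(model.n_components)
            )
            residual += np.sum((m.values - approx) ** 2)
        assert fitted + residual == pytest.approx(total, rel=1e-8)

    def test_score_orthogonality(self, cohort):
        # deflation makes successive components orthogonal: exactly per
        # score vector for a single matrix, and for the concatenation over
        # all observation sets on a network fit (the per-group sub-vectors
        # of a weakly structured group need not be orthogonal)
        rng = np.random.default_rng(3)
        net = single_matrix_network(rng)
        m1 = fit_netpca(net, 3, tol=1e-14, max_iter=2000)
        t = m1.scores["g"]
        for a in range(3):
            for b in range(a + 1, 3):
                cos = t[:, a] @ t[:, b] / np.linalg.norm(t[:, a]) / np.linalg.norm(t[:, b])
                assert abs(cos) < 1e-8
        model, scaled = cohort["model"], cohort["scaled"]
        t1 = np.concatenate([model.scores[g][:, 0] for g in scaled.row_classes])
        t2 = np.concatenate([model.scores[g][:, 1] for g in scaled.row_classes])
        cos = t1 @ t2 / np.linalg.norm(t1) / np.linalg.norm(t2)
        assert abs(cos) < 1e-4

    def test_concatenated_loading_unit_norm(self, cohort):
        model = cohort["model"]
        for a in range(model.n_components):
            norm = np.sqrt(sum(float(model.loadings[b][:, a] @ model.loadings[b][:, a]) for b in model.loadings))
            assert norm == pytest.approx(1.0, rel=1e-10)

    def test_seed_determinism_bitwise(self):
        net, _ = generate_cohort(paper_design(seed=5))
        scaled, _ = uv_scale(net)
        m1 = fit_netpca(scaled, 2, seed=9, init="random")
        m2 = fit_netpca(scaled, 2, seed=9, init="random")
        for g in m1.scores:
            assert (m1.scores[g] == m2.scores[g]).all()
        assert (m1.component_variance == m2.component_variance).all()

    def test_label_permutation_changes_no_numeric_value(self):
        rng = np.random.default_rng(4)
        net = random_data_network(rng)
        renamed = build_data_network(
            [
                DataMatrix(m.values, m.obs_ids, m.var_ids, "X" + m.row_class, "Y" + m.col_class)
                for m in net.matrices
            ]
        )
        m1 = fit_netpca(net, 2, tol=1e-12)
        m2 = fit_netpca(renamed, 2, tol=1e-12)
        for g in m1.scores:
            np.testing.assert_array_equal(m1.scores[g], m2.scores["X" + g])
        np.testing.assert_array_equal(m1.component_variance, m2.component_variance)

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(5)
        net = single_matrix_network(rng, n=4, p=10)
        with pytest.raises(ValueError, match="n_components"):
            fit_netpca(net, 5)


class TestBlockInfluence:
    def test_single_matrix_influence_is_100(self):
        rng = np.random.default_rng(6)
        net = single_matrix_network(rng)
        model = fit_netpca(net, 2)
        infl = block_influence(model, net)
        for a in (1, 2):
            assert infl.influence("g", "b", a) == pytest.approx(100.0)

    def test_two_identical_matrices_split_influence_evenly(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(5, 4))
        var = [f"v{i}" for i in range(4)]
        a = DataMatrix(vals, [f"a{i}" for i in range(5)], var, "gA", "b")
        b = DataMatrix(vals.copy(), [f"b{i}" for i in range(5)], var, "gB", "b")
        net = build_data_network([a, b])
        model = fit_netpca(net, 1)
        infl = block_influence(model, net)
        assert infl.influence("gA", "b", 1) == pytest.approx(50.0, rel=1e-6)
        assert infl.influence("gB", "b", 1) == pytest.approx(50.0, rel=1e-6)

    def test_influences_sum_to_100_per_component(self, cohort):
        infl = block_influence(cohort["model"], cohort["scaled"])
        sums = infl.table.sum(axis=0)
        np.testing.assert_allclose(sums.to_numpy(), 100.0, atol=1e-6)

    def test_component_out_of_range(self, cohort):
        infl = block_influence(cohort["model"], cohort["scaled"])
        with pytest.raises(IndexError):
            infl.influence("preHD", "RPLC+", 3)

    def test_planted_prehd_shift_dominates_component1(self, cohort):
        by_group = block_influence(cohort["model"], cohort["scaled"]).by_row_class(1)
        assert by_group.index[0] in {"preHD", "preKG"}
        assert by_group["preHD"] > by_group["CTRL"]


class TestVariableVariance:
    def test_noiseless_rank1_variables_fully_explained(self):
        rng = np.random.default_rng(8)
        net, _, p_true = rank1_network(rng)
        model = fit_netpca(net, 1)
        table = variable_explained_variance(model, net)
        for b in ("b1", "b2"):
            for i, v in enumerate(net.var_ids(b)):
                if abs(p_true[b][i]) > 1e-12:
                    assert table.percent.loc[v, "comp1"] == pytest.approx(100.0, abs=1e-6)

    def test_zero_loading_variable_explains_zero(self):
        rng = np.random.default_rng(9)
        t = rng.normal(size=6)
        p = np.array([1.0, -2.0, 0.0])
        m = DataMatrix(np.outer(t, p), [f"o{i}" for i in range(6)], ["v0", "v1", "vnull"], "g", "b")
        net = build_data_network([m])
        model = fit_netpca(net, 1)
        table = variable_explained_variance(model, net)
        assert table.percent.loc["vnull", "comp1"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_noise_variable_below_marker_threshold(self):
        # a planted null variable in an otherwise structured network stays
        # below the 20% marker threshold on the leading component
        design = paper_design(seed=42)
        net, truth = generate_cohort(design)
        rng = np.random.default_rng(1234)
        null_block = []
        for m in net.matrices:
            vals = m.values.copy()
            if m.col_class == "RPLC+":
                vals = np.column_stack([vals, rng.normal(size=len(m.obs_ids))])
                var_ids = m.var_ids + ["pure_noise"]
            else:
                var_ids = m.var_ids
            null_block.append(DataMatrix(vals, m.obs_ids, var_ids, m.row_class, m.col_class))
        net2 = build_data_network(null_block)
        scaled, _ = uv_scale(net2)
        model = fit_netpca(scaled, 2)
        table = variable_explained_variance(model, scaled)
        assert table.percent.loc["pure_noise", "comp1"] < 20.0

    def test_cumulative_within_bounds(self, cohort):
        table = variable_explained_variance(cohort["model"], cohort["scaled"])
        assert (table.percent.to_numpy() >= -1e-9).all()
        assert (table.cumulative.to_numpy() <= 100 + 1e-6).all()


class TestSelectMarkers:
    @pytest.fixture
    def table(self, cohort):
        return variable_explained_variance(cohort["model"], cohort["scaled"])

    def test_threshold_is_inclusive_and_sorted(self, table):
        markers = select_markers(table, 1, 20.0)
        pct = table.percent["comp1"]
        assert set(markers) == set(pct[pct >= 20.0].index)
        vals = [pct[v] for v in markers]
        assert vals == sorted(vals, reverse=True)

    def test_all_below_threshold_gives_empty_list(self, table):
        assert select_markers(table, 1, 100.0) == []

    def test_tie_break_by_variable_id(self):
        import pandas as pd

        from metnetpca.netpca import VariableVarianceTable

        pct = pd.DataFrame({"comp1": [35.0, 35.0, 10.0]}, index=["v2", "v1", "v3"])
        t = VariableVarianceTable(pct, pct.cumsum(axis=1), pd.Series("b", index=pct.index))
        assert select_markers(t, 1) == ["v1", "v2"]

    def test_invalid_threshold_rejected(self, table):
        with pytest.raises(ValueError):
            select_markers(table, 1, 101.0)
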