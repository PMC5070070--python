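import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from bloodmark.network import (
    NetworkConfig,
    detect_modules,
    merge_close_modules,
    module_eigengenes,
    module_membership,
    scale_free_fit,
    signed_adjacency,
    topological_overlap,
)


def _df(a, prefix="g"):
    a = np.asarray(a, dtype=float)
    names = [f"{prefix}{i}" for i in range(a.shape[0])]
    return pd.DataFrame(a, index=names, columns=names)


def _expr(a):
    a = np.asarray(a, dtype=float)
    return pd.DataFrame(
        a,
        index=[f"g{i}" for i in range(a.shape[0])],
        columns=[f"s{j}" for j in range(a.shape[1])],
    )


def block_dissimilarity(sizes, within=0.0, between=1.0):
    n = sum(sizes)
    d = np.full((n, n), between)
    pos = 0
    for s in sizes:
        d[pos : pos + s, pos : pos + s] = within
        pos += s
    np.fill_diagonal(d, 0.0)
    return _df(d)


class TestSignedAdjacency:
    def test_correlation_endpoints(self):
        # perfectly correlated pair -> 1; anti-correlated -> ~0
        t = np.arange(6, dtype=float)
        expr = _expr([t, 2 * t + 1, -t])
        adj = signed_adjacency(expr)
        assert adj.iloc[0, 1] == pytest.approx(1.0)
        assert adj.iloc[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_closed_form(self):
        cfg = NetworkConfig(beta=9)
        # orthogonal, zero-correlation vectors
        expr = _expr([[1, -1, 1, -1], [1, 1, -1, -1]])
        adj = signed_adjacency(expr, cfg)
        assert adj.iloc[0, 1] == pytest.approx(0.5**9)

    def test_matches_bruteforce_formula(self, rng):
        expr = _expr(rng.standard_normal((4, 10)))
        cfg = NetworkConfig(beta=9)
        adj = signed_adjacency(expr, cfg).to_numpy()
        x = expr.to_numpy()
        for i in range(4):
            for j in range(4):
                r = np.corrcoef(x[i], x[j])[0, 1]
                expected = 1.0 if i == j else ((1 + r) / 2) ** 9
                assert adj[i, j] == pytest.approx(expected, abs=1e-12)

    def test_unsigned_option(self, rng):
        expr = _expr(rng.standard_normal((3, 8)))
        adj = signed_adjacency(expr, NetworkConfig(signed=False, beta=6))
        x = expr.to_numpy()
        r = abs(np.corrcoef(x[0], x[1])[0, 1])
        assert adj.iloc[0, 1] == pytest.approx(r**6)

    def test_zero_variance_gene_dropped_with_warning(self, rng):
        x = rng.standard_normal((4, 8))
        x[2] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            adj = signed_adjacency(_expr(x))
        assert adj.shape == (3, 3)

    def test_permutation_equivariance(self, toy_expression):
        adj = signed_adjacency(toy_expression)
        perm = list(toy_expression.index[::-1])
        adj_p = signed_adjacency(toy_expression.loc[perm])
        pd.testing.assert_frame_equal(adj.loc[perm, perm], adj_p)


class TestScaleFreeFit:
    def test_constant_connectivity_flagged(self):
        a = np.full((20, 20), 0.3)
        np.fill_diagonal(a, 1.0)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(scale_free_fit(_df(a)))

    def test_power_law_network_fits_well(self, rng):
        w = rng.pareto(2.0, size=300) + 0.1
        a = np.sqrt(np.outer(w, w))
        a /= a.max()
        np.fill_diagonal(a, 1.0)
        assert scale_free_fit(_df(a)) >= 0.8

    def test_gaussian_expression_fits_worse_than_power_law(self, rng):
        w = rng.pareto(2.0, size=300) + 0.1
        a = np.sqrt(np.outer(w, w))
        a /= a.max()
        np.fill_diagonal(a, 1.0)
        r2_pl = scale_free_fit(_df(a))
        expr = _expr(rng.standard_normal((300, 30)))
        r2_gauss = scale_free_fit(signed_adjacency(expr))
        assert r2_gauss < r2_pl


class TestTopologicalOverlap:
    def test_two_gene_closed_form(self):
        # no third gene: shared term 0, k_1 = k_2 = a_12, so
        # TOM_12 = a_12 / (a_12 + 1 - a_12) = a_12
        a = _df([[1.0, 0.5], [0.5, 1.0]])
        tom, diss = topological_overlap(a)
        assert tom.iloc[0, 1] == pytest.approx(0.5)
        assert diss.iloc[0, 1] == pytest.approx(0.5)

    def test_identical_fully_connected_rows(self):
        a = np.ones((3, 3))
        tom, _ = topological_overlap(_df(a))
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_triple_loop_oracle(self, rng):
        x = rng.uniform(0, 1, size=(5, 5))
        a = (x + x.T) / 2
        np.fill_diagonal(a, 1.0)
        tom, _ = topological_overlap(_df(a))
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert tom.iloc[i, j] == 1.0
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(5) if u not in (i, j))
                k_i = sum(a[i, u] for u in range(5) if u != i)
                k_j = sum(a[j, u] for u in range(5) if u != j)
                expected = (shared + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert tom.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_asymmetric_input_rejected(self):
        a = _df([[1.0, 0.2], [0.8, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)

    def test_gene_relabeling_equivariance(self, toy_expression):
        adj = signed_adjacency(toy_expression)
        tom, _ = topological_overlap(adj)
        perm = list(adj.index[::-1])
        tom_p, _ = topological_overlap(adj.loc[perm, perm])
        pd.testing.assert_frame_equal(tom.loc[perm, perm], tom_p, atol=1e-12, rtol=0)


class TestDetectModules:
    def test_two_perfect_blocks(self):
        diss = block_dissimilarity([20, 20])
        part = detect_modules(diss, NetworkConfig(min_module_size=15))
        labels = part.to_numpy()
        assert (labels != 0).all()
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_blocks_below_min_size_go_grey(self):
        # documented behavior: without any acceptable module the genes stay grey
        diss = block_dissimilarity([20, 20])
        part = detect_modules(diss, NetworkConfig(min_module_size=25))
        assert (part.to_numpy() == 0).all()

    def test_fewer_genes_than_min_size_all_grey(self):
        diss = block_dissimilarity([5])
        with pytest.warns(UserWarning):
            part = detect_modules(diss, NetworkConfig(min_module_size=15))
        assert (part.to_numpy() == 0).all()

    def test_recovers_planted_modules(self, default_cohort, default_expression):
        _, _, truth = default_cohort
        adj = signed_adjacency(default_expression.values)
        _, diss = topological_overlap(adj)
        part = merge_close_modules(
            default_expression.values, detect_modules(diss)
        )
        gm = truth.gene_modules.reindex(part.index).to_numpy()
        mask = gm >= 0
        ari = adjusted_rand_score(gm[mask], part.to_numpy()[mask])
        assert ari >= 0.7

    def test_deterministic(self, default_expression):
        values = default_expression.values.iloc[:400]
        adj = signed_adjacency(values)
        _, diss = topological_overlap(adj)
        p1 = detect_modules(diss)
        p2 = detect_modules(diss)
        pd.testing.assert_series_equal(p1, p2)


class TestMergeCloseModules:
    def _partition(self, values, groups):
        return pd.Series(groups, index=values.index, name="module")

    def _two_module_expr(self, rng, cor_factor):
        """40 genes in 2 modules driven by factors with a set correlation."""
        n = 12
        f1 = rng.standard_normal(n)
        f2 = cor_factor * f1 + np.sqrt(max(0.0, 1 - cor_factor**2)) * rng.standard_normal(n)
        rows = [f1 + 0.05 * rng.standard_normal(n) for _ in range(20)]
        rows += [f2 + 0.05 * rng.standard_normal(n) for _ in range(20)]
        return _expr(rows)

    def test_identical_eigengenes_merged(self, rng):
        values = self._two_module_expr(rng, 1.0)
        part = self._partition(values, [1] * 20 + [2] * 20)
        merged = merge_close_modules(values, part)
        assert merged.nunique() == 1

    def test_uncorrelated_eigengenes_not_merged(self, rng):
        values = self._two_module_expr(rng, 0.0)
        part = self._partition(values, [1] * 20 + [2] * 20)
        merged = merge_close_modules(values, part)
        assert merged.nunique() == 2

    def test_correlation_085_merged(self, rng):
        values = self._two_module_expr(rng, 0.9)
        # with tight loadings the ME correlation tracks the factor correlation
        eg = module_eigengenes(values, self._partition(values, [1] * 20 + [2] * 20))
        r = np.corrcoef(eg.values.iloc[0], eg.values.iloc[1])[0, 1]
        assert 1 - r < 0.2  # dissimilarity below the cut height
        merged = merge_close_modules(values, self._partition(values, [1] * 20 + [2] * 20))
        assert merged.nunique() == 1

    def test_no_close_pair_after_merging(self, default_cohort, default_expression):
        _, _, _ = default_cohort
        values = default_expression.values
        adj = signed_adjacency(values)
        _, diss = topological_overlap(adj)
        cfg = NetworkConfig()
        part = merge_close_modules(values, detect_modules(diss, cfg), cfg)
        eg = module_eigengenes(values, part)
        r = np.corrcoef(eg.values.to_numpy())
        off = r[np.triu_indices(len(eg.values), k=1)]
        assert (off <= 1 - cfg.merge_cut_height + 1e-12).all()


class TestEigengenes:
    def test_identical_gene_module_rank_one(self, rng):
        base = rng.standard_normal(10)
        values = _expr([base] * 10)
        part = pd.Series([1] * 10, index=values.index)
        eg = module_eigengenes(values, part)
        assert eg.var_explained.iloc[0] == pytest.approx(1.0)
        r = np.corrcoef(eg.values.iloc[0], values.iloc[0])[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_matches_pca_oracle(self, rng):
        values = _expr(rng.standard_normal((15, 10)))
        part = pd.Series([1] * 15, index=values.index)
        eg = module_eigengenes(values, part)
        # independent oracle: eigendecomposition of the subject covariance of
        # the standardized module matrix
        x = values.to_numpy()
        xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1)[:, None]
        cov = xs.T @ xs
        w, v = np.linalg.eigh(cov)
        pc1 = v[:, -1]
        me = eg.values.iloc[0].to_numpy()
        delta = min(np.abs(me - pc1).max(), np.abs(me + pc1).max())
        assert delta < 1e-8

    def test_unit_norm_and_majority_positive_orientation(self, default_expression, default_cohort):
        _, _, truth = default_cohort
        part = truth.gene_modules.reindex(default_expression.values.index).copy()
        part = (part + 1).astype(int)  # truth modules -> labels 1..8, background 0
        eg = module_eigengenes(default_expression.values, part)
        norms = np.linalg.norm(eg.values.to_numpy(), axis=1)
        assert np.allclose(norms, 1.0)
        kme, _ = module_membership(default_expression.values, eg, part)
        for m in eg.values.index:
            label = int(str(m).lstrip("M"))
            members = part.index[part == label]
            col = kme.loc[members, m]
            assert (col > 0).sum() >= (col < 0).sum()

    def test_subject_permutation_equivariance(self, rng):
        values = _expr(rng.standard_normal((12, 8)))
        part = pd.Series([1] * 12, index=values.index)
        eg = module_eigengenes(values, part)
        perm = list(values.columns[::-1])
        eg_p = module_eigengenes(values[perm], part)
        pd.testing.assert_frame_equal(eg.values[perm], eg_p.values, atol=1e-10, rtol=0)

    def test_constant_gene_module_rejected(self):
        values = _expr([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0]])
        part = pd.Series([1, 1], index=values.index)
        with pytest.raises(ValueError, match="module 1"):
            module_eigengenes(values, part)

    def test_eigengene_tracks_planted_factor(self, default_cohort, default_expression):
        _, _, truth = default_cohort
        part = (truth.gene_modules.reindex(default_expression.values.index) + 1).astype(int)
        eg = module_eigengenes(default_expression.values, part)
        for m in range(truth.module_factors.shape[0]):
            me = eg.values.loc[f"M{m+1}"].to_numpy()
            f = truth.module_factors.iloc[m].to_numpy()
            assert abs(np.corrcoef(me, f)[0, 1]) >= 0.9


class TestModuleMembership:
    def test_gene_equal_to_eigengene(self, rng):
        f = rng.standard_normal(10)
        values = _expr([f + 0.01 * rng.standard_normal(10) for _ in range(5)] + [f])
        part = pd.Series([1] * 6, index=values.index)
        eg = module_eigengenes(values, part)
        # overwrite the last gene to be exactly the eigengene
        values.iloc[5] = eg.values.iloc[0].to_numpy()
        kme, _ = module_membership(values, eg, part)
        assert abs(kme.iloc[5, 0]) == pytest.approx(1.0)

    def test_orthogonal_gene_zero_kme(self):
        values = _expr(
            [[1, -1, 1, -1], [1, -1, 1, -1.0], [1, 1, -1, -1]]
        )
        part = pd.Series([1, 1, 0], index=values.index)
        eg = module_eigengenes(values, part)
        kme, _ = module_membership(values, eg, part)
        assert abs(kme.iloc[2, 0]) < 1e-10

    def test_kme_threshold_filter(self, rng):
        f = rng.standard_normal(12)
        rows = [f + s * rng.standard_normal(12) for s in (0.1, 0.1, 0.2, 3.0, 5.0)]
        values = _expr(rows)
        part = pd.Series([1] * 5, index=values.index)
        eg = module_eigengenes(values, part)
        kme, _ = module_membership(values, eg, part)
        passing = set(kme.index[kme["M1"] > 0.50])
        brute = {g for g in values.index if np.corrcoef(values.loc[g], eg.values.iloc[0])[0, 1] > 0.50}
        assert passing == brute
        assert {"g0", "g1", "g2"} <= passing

    def test_hub_gene_has_max_kme(self, default_expression, default_cohort):
        _, _, truth = default_cohort
        part = (truth.gene_modules.reindex(default_expression.values.index) + 1).astype(int)
        eg = module_eigengenes(default_expression.values, part)
        kme, hubs = module_membership(default_expression.values, eg, part)
        for m, hub in hubs.items():
            label = int(m.lstrip("M"))
            members = part.index[part == label]
            assert kme.loc[hub, m] == kme.loc[members, m].max()
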