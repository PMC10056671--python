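"""Preprocessing chain: filters, HVG, normalization, log1p, PCA, graph."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imaae import (
    AnnotatedMatrix,
    build_cross_batch_graph,
    compute_pca,
    filter_cells_genes,
    log1p_transform,
    normalize_total,
    select_hvg,
)


def _matrix(values, batch=None, types=None, layer="raw_counts"):
    values = np.asarray(values)
    n, g = values.shape
    return AnnotatedMatrix(
        values,
        np.array([f"c{i}" for i in range(n)], dtype=object),
        np.array([f"g{j}" for j in range(g)], dtype=object),
        np.array(batch or ["b0"] * n, dtype=object),
        np.array(types or ["t0"] * n, dtype=object),
        layer,
    )


class TestFilter:
    def test_boundary_exactly_at_threshold_kept(self):
        """Cells expressing exactly the minimum are retained ('less than' excluded)."""
        rng = np.random.default_rng(0)
        g = 800
        counts = np.zeros((5, g), dtype=np.int64)
        for i, n_expr in enumerate([700, 600, 599, 0, 601]):
            idx = rng.choice(g, size=n_expr, replace=False)
            counts[i, idx] = 1
        # keep every gene afterwards by using min_cells_per_gene=1
        m = _matrix(counts)
        out = filter_cells_genes(m, min_genes_per_cell=600, min_cells_per_gene=1)
        assert list(out.cell_ids) == ["c0", "c1", "c4"]

    def test_identity_when_all_pass(self, tiny_matrix):
        out = filter_cells_genes(tiny_matrix, 1, 1)
        np.testing.assert_array_equal(out.values, tiny_matrix.values)

    def test_matches_double_pass_oracle(self):
        """Survivors equal an independently coded cells-then-genes filter."""
        rng = np.random.default_rng(42)
        counts = rng.poisson(0.4, size=(200, 100)).astype(np.int64)
        counts[rng.integers(0, 200, 40)] += rng.poisson(2.0, size=(40, 100))
        m = _matrix(counts)
        min_g, min_c = 20, 5
        out = filter_cells_genes(m, min_g, min_c)
        # oracle: explicit loops
        keep_cells = [i for i in range(200) if (counts[i] > 0).sum() >= min_g]
        sub = counts[keep_cells]
        keep_genes = [j for j in range(100) if (sub[:, j] > 0).sum() >= min_c]
        assert list(out.cell_ids) == [f"c{i}" for i in keep_cells]
        assert list(out.gene_ids) == [f"g{j}" for j in keep_genes]

    def test_all_cells_removed_is_error(self):
        m = _matrix(np.ones((3, 4), dtype=np.int64))
        with pytest.raises(ValueError, match="min_genes_per_cell"):
            filter_cells_genes(m, 100, 1)

    def test_filter_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.poisson(1.0, size=(50, 60)).astype(np.int64))
        kept = [
            set(filter_cells_genes(m, thr, 1).cell_ids)
            for thr in (5, 10, 20)
        ]
        assert kept[2] <= kept[1] <= kept[0]


class TestHVG:
    def test_all_genes_kept_when_n_equals_total(self, tiny_matrix):
        out = select_hvg(tiny_matrix, tiny_matrix.n_genes)
        assert list(out.gene_ids) == list(tiny_matrix.gene_ids)

    def test_planted_high_variance_genes_recovered(self):
        """Genes with a planted bimodal program dominate the dispersion ranking."""
        rng = np.random.default_rng(1)
        n, g, planted = 300, 500, 20
        # background rates spread over a range so every mean bin is dominated
        # by well-behaved Poisson genes; planted genes are bimodal (on/off)
        # with roughly the background mean but far higher dispersion
        base = rng.gamma(4.0, 1.5, size=g)
        counts = rng.poisson(base, size=(n, g))
        on = rng.uniform(size=(n, planted)) < 0.5
        counts[:, :planted] = rng.poisson(
            np.where(on, 2.0 * base[:planted], 0.05 * base[:planted])
        )
        m = _matrix(counts.astype(np.int64))
        out = select_hvg(m, planted)
        hits = sum(1 for gid in out.gene_ids if int(gid[1:]) < planted)
        assert hits >= 18

    def test_too_many_requested_is_error(self, tiny_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            select_hvg(tiny_matrix, 10)


class TestNormalizeLog:
    def test_proportional_scaling(self):
        m = _matrix(np.array([[1, 1, 2]]))
        out = normalize_total(m, 20000)
        np.testing.assert_allclose(out.values, [[5000, 5000, 10000]])
        assert out.layer_tag == "normalized"

    def test_row_sums_hit_target(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.poisson(3.0, size=(40, 30)) + 1)
        out = normalize_total(m, 20000)
        np.testing.assert_allclose(out.values.sum(axis=1), 20000, rtol=1e-9)

    def test_normalize_idempotent(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.poisson(3.0, size=(10, 8)) + 1)
        once = normalize_total(m, 20000)
        twice = normalize_total(once, 20000)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)

    def test_zero_count_cell_is_error(self):
        m = _matrix(np.array([[1, 2], [0, 0]]))
        with pytest.raises(ValueError, match="zero total"):
            normalize_total(m, 100)

    def test_log1p_closed_forms(self):
        m = _matrix(np.array([[0.0, np.e - 1.0]]), layer="normalized")
        out = log1p_transform(m)
        np.testing.assert_allclose(out.values, [[0.0, 1.0]], atol=1e-12)
        assert out.layer_tag == "lognormalized"

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    @settings(deadline=None, max_examples=50)
    def test_log1p_monotone(self, a, b):
        if a == b:
            return
        lo, hi = sorted([a, b])
        assert np.log1p(lo) < np.log1p(hi)


class TestPCA:
    def test_rank_one_data(self):
        u = np.outer(np.arange(1, 6, dtype=float), [1.0, 2.0, 3.0])
        m = _matrix(u, layer="lognormalized")
        res = compute_pca(m, 3)
        assert res.explained_variance[0] > 1e-6
        np.testing.assert_allclose(res.explained_variance[1:], 0, atol=1e-10)

    def test_line_direction(self):
        x = np.linspace(0, 5, 30)
        pts = np.stack([x, 2 * x], axis=1)
        res = compute_pca(_matrix(pts, layer="lognormalized"), 1)
        direction = res.components[0] / np.linalg.norm(res.components[0])
        expected = np.array([1.0, 2.0]) / np.sqrt(5.0)
        assert min(np.linalg.norm(direction - expected), np.linalg.norm(direction + expected)) < 1e-8

    def test_matches_svd_oracle(self):
        """Embedding equals the centred-SVD projection up to per-component sign."""
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 5, size=(100, 50))
        res = compute_pca(_matrix(X, layer="lognormalized"), 10)
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        oracle = Xc @ Vt[:10].T
        for k in range(10):
            diff = min(
                np.abs(res.embedding[:, k] - oracle[:, k]).max(),
                np.abs(res.embedding[:, k] + oracle[:, k]).max(),
            )
            assert diff < 1e-5
        # orthonormal components, non-increasing variance
        G = res.components @ res.components.T
        np.testing.assert_allclose(G, np.eye(10), atol=1e-6)
        assert np.all(np.diff(res.explained_variance) <= 1e-10)

    def test_too_many_components_is_error(self):
        m = _matrix(np.ones((3, 2)), layer="lognormalized")
        with pytest.raises(ValueError, match="exceeds"):
            compute_pca(m, 5)


class TestGraph:
    def _toy(self, rng, n_per=10):
        emb = np.concatenate([
            rng.normal(0, 1, size=(n_per, 2)),      # batch A type t
            rng.normal(0, 1, size=(n_per, 2)),      # batch B type t
        ])
        batch = np.array(["A"] * n_per + ["B"] * n_per, dtype=object)
        types = np.array(["t"] * 2 * n_per, dtype=object)
        return emb, batch, types

    def test_saturated_k_gives_complete_bipartite(self):
        rng = np.random.default_rng(0)
        emb, batch, types = self._toy(rng, n_per=4)
        with pytest.warns(UserWarning, match="capped"):
            g = build_cross_batch_graph(emb, batch, types, k=10)
        assert len(g.edges) == 16

    def test_single_batch_type_has_no_edges(self):
        emb = np.random.default_rng(1).normal(size=(6, 2))
        batch = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        types = np.array(["u", "u", "u", "v", "v", "v"], dtype=object)
        g = build_cross_batch_graph(emb, batch, types, k=2)
        assert g.edges == []

    def test_matches_brute_force_mutual_knn(self):
        rng = np.random.default_rng(3)
        emb, batch, types = self._toy(rng, n_per=10)
        k = 3
        g = build_cross_batch_graph(emb, batch, types, k=k)
        # oracle: exhaustive pairwise distances
        ia, ib = np.arange(10), np.arange(10, 20)
        d = np.linalg.norm(emb[ia][:, None] - emb[ib][None], axis=2)
        expected = set()
        nn_ab = {a: set(np.argsort(d[a], kind="stable")[:k]) for a in range(10)}
        nn_ba = {b: set(np.argsort(d[:, b], kind="stable")[:k]) for b in range(10)}
        for a in range(10):
            for b in range(10):
                if b in nn_ab[a] and a in nn_ba[b]:
                    expected.add((a, b + 10))
        assert set(g.edges) == expected

    def test_every_edge_crosses_batches_same_type(self, prepped_small):
        prep, graph = prepped_small
        for (i, j), (ba, bb, t) in zip(graph.edges, graph.metadata):
            assert prep.batch[i] != prep.batch[j]
            assert prep.cell_type[i] == prep.cell_type[j] == t
        assert len(set(graph.edges)) == len(graph.edges)
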