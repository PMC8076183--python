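"""The CA eigenproblem and its three equivalent readings.

Frozen expected values for the 2x3 worked example come from the dense
generalized eigensolver on the 2x2 row operator [[0.75, 0.25], [0.25, 0.75]]
(eigenvalues 1 and 0.5, second eigenvector proportional to (1, -1)) and from
hand enumeration of the four edges.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import caspectral as cs
from conftest import random_table


class TestSimilarityProjection:
    def test_row_projection_worked_example(self, toy_table):
        g = cs.project_similarity(toy_table, "row")
        np.testing.assert_allclose(g.dense(), [[1.5, 0.5], [0.5, 1.5]])

    def test_disjoint_rows_give_identity(self):
        g = cs.project_similarity(cs.load_incidence(np.eye(2)), "row")
        np.testing.assert_allclose(g.dense(), np.eye(2))

    def test_column_projection_row_sums_equal_degrees(self, toy_table):
        g = cs.project_similarity(toy_table, "column")
        np.testing.assert_allclose(g.dense().sum(axis=1), [1, 2, 1])

    def test_asymmetric_similarity_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            cs.SimilarityGraph("row", np.array([[1.0, 0.4], [0.0, 1.0]]), np.array([1.4, 1.0]), ("a", "b"))


class TestCASpectrum:
    def test_worked_example_eigenpairs(self, toy_table):
        s = cs.ca_spectrum(toy_table)
        np.testing.assert_allclose(s.eigenvalues, [1.0, 0.5], atol=1e-12)
        # v2 ∝ (1, -1), u2 ∝ (1, 0, -1), sign fixed to positive leading entry
        v2 = s.row_scores[:, 1]
        u2 = s.col_scores[:, 1]
        np.testing.assert_allclose(v2 / v2[0], [1.0, -1.0], atol=1e-12)
        np.testing.assert_allclose(u2 / u2[0], [1.0, 0.0, -1.0], atol=1e-12)

    def test_rank_one_table_has_zero_second_eigenvalue(self):
        s = cs.ca_spectrum(cs.load_incidence(np.ones((2, 2))))
        np.testing.assert_allclose(s.eigenvalues, [1.0, 0.0], atol=1e-12)

    def test_two_disconnected_blocks_have_double_unit_eigenvalue(self, two_component_table):
        s = cs.ca_spectrum(two_component_table)
        np.testing.assert_allclose(s.eigenvalues[:2], [1.0, 1.0], atol=1e-12)

    def test_trivial_axis_constant_and_nontrivial_centered(self):
        table = random_table(7)
        s = cs.ca_spectrum(table)
        assert np.ptp(s.row_scores[:, 0]) < 1e-8
        assert np.ptp(s.col_scores[:, 0]) < 1e-8
        # weighted centering: sum_i r_i v_ki = 0 for every nontrivial axis
        cen_r = s.row_weights @ s.row_scores[:, 1:]
        cen_c = s.col_weights @ s.col_scores[:, 1:]
        np.testing.assert_allclose(cen_r, 0, atol=1e-7)
        np.testing.assert_allclose(cen_c, 0, atol=1e-7)

    def test_eigenproblem_residual(self):
        table = random_table(11)
        s = cs.ca_spectrum(table)
        A = table.dense()
        op = (A / table.row_margins[:, None]) @ (A / table.col_margins[None, :]).T
        for k in range(len(s.eigenvalues)):
            v = s.row_scores[:, k]
            np.testing.assert_allclose(op @ v, s.eigenvalues[k] * v, atol=1e-8)

    def test_transition_formula_links_row_and_column_scores(self):
        table = random_table(13)
        s = cs.ca_spectrum(table)
        A = table.dense()
        for k in range(1, len(s.eigenvalues)):
            if s.eigenvalues[k] < 1e-6:
                continue
            u_from_v = (A.T @ s.row_scores[:, k]) / table.col_margins
            expected = np.sqrt(s.eigenvalues[k]) * s.col_scores[:, k]
            np.testing.assert_allclose(u_from_v, expected, atol=1e-8)

    def test_unit_norm_option(self, toy_table):
        s = cs.ca_spectrum(toy_table, normalization="unit-norm")
        np.testing.assert_allclose(np.linalg.norm(s.row_scores, axis=0), 1.0)
        np.testing.assert_allclose(np.linalg.norm(s.col_scores, axis=0), 1.0)

    def test_normalization_choice_does_not_change_rankings(self):
        table = random_table(5)
        a = cs.ca_spectrum(table, normalization="unit-variance")
        b = cs.ca_spectrum(table, normalization="unit-norm")
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)
        for k in range(1, 4):
            np.testing.assert_array_equal(
                np.argsort(a.row_scores[:, k]), np.argsort(b.row_scores[:, k])
            )

    def test_k_max_truncation_warns(self, toy_table):
        with pytest.warns(UserWarning, match="truncating"):
            s = cs.ca_spectrum(toy_table, k_max=5)
        assert len(s.eigenvalues) == 2

    def test_single_row_table_warns_trivial_only(self):
        with pytest.warns(UserWarning, match="trivial"):
            s = cs.ca_spectrum(cs.load_incidence(np.array([[1.0, 2.0, 1.0]])))
        assert len(s.eigenvalues) == 1

    def test_sparse_truncated_route_matches_dense(self):
        rng = np.random.default_rng(3)
        A = (rng.random((150, 200)) < 0.02).astype(float)
        table = cs.load_incidence(A, drop_empty=True)
        assert table.is_sparse
        trunc = cs.ca_spectrum(table, k_max=8)
        dense = cs.ca_spectrum(cs.load_incidence(table.dense(), drop_empty=False), k_max=8)
        np.testing.assert_allclose(trunc.eigenvalues, dense.eigenvalues, atol=1e-8)
        for k in range(8):
            np.testing.assert_allclose(
                trunc.row_scores[:, k], dense.row_scores[:, k], atol=1e-6
            )


class TestEdgeScores:
    def test_worked_example_edge_enumeration(self, toy_table):
        s = cs.ca_spectrum(toy_table)
        es = cs.edge_scores(toy_table, s, 2)
        v, u = s.row_scores[:, 1], s.col_scores[:, 1]
        # edges in row-major order: (0,0), (0,1), (1,1), (1,2)
        np.testing.assert_allclose(es.y_r, [v[0], v[0], v[1], v[1]])
        np.testing.assert_allclose(es.y_c, [u[0], u[1], u[1], u[2]])
        assert len(es.y_r) == toy_table.total

    def test_edge_scores_are_centered(self):
        table = random_table(17)
        s = cs.ca_spectrum(table)
        es = cs.edge_scores(table, s, 2)
        assert abs(es.y_r.mean()) < 1e-8
        assert abs(es.y_c.mean()) < 1e-8

    def test_weighted_cell_repeats_scores(self):
        table = cs.load_incidence(np.array([[3.0, 1.0], [1.0, 2.0]]))
        s = cs.ca_spectrum(table)
        es = cs.edge_scores(table, s, 2)
        assert len(es.y_r) == 7
        assert np.sum(es.y_r == s.row_scores[0, 1]) == 4  # row 0 has margin 4

    def test_trivial_axis_rejected(self, toy_table):
        s = cs.ca_spectrum(toy_table)
        with pytest.raises(ValueError, match="trivial"):
            cs.edge_scores(toy_table, s, 1)

    def test_correlation_squared_is_the_eigenvalue(self, toy_table):
        s = cs.ca_spectrum(toy_table)
        corr = cs.score_correlation(cs.edge_scores(toy_table, s, 2))
        assert corr**2 == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_scores_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cs.score_correlation(cs.EdgeScores(np.ones(4), np.arange(4.0), axis=2))


class TestLaplacianRoute:
    def test_worked_example_generalized_eigenvalues(self, toy_table):
        g = cs.project_similarity(toy_table, "row")
        vals, vecs = cs.laplacian_generalized_eigs(g)
        np.testing.assert_allclose(vals, [0.0, 0.5], atol=1e-10)
        assert np.ptp(vecs[:, 0]) < 1e-8  # constant eigenvector at 0

    def test_disconnected_blocks_give_two_zero_eigenvalues(self, two_component_table):
        g = cs.project_similarity(two_component_table, "row")
        vals, _ = cs.laplacian_generalized_eigs(g)
        assert np.sum(vals < 1e-10) == 2


class TestEmbedding:
    def test_coordinates_are_sqrt_lambda_scaled(self, toy_table):
        s = cs.ca_spectrum(toy_table)
        e = cs.embed(s, n_axes=1)
        np.testing.assert_allclose(
            e.coordinates[:, 0], np.sqrt(0.5) * s.row_scores[:, 1]
        )

    def test_single_nontrivial_axis_explains_everything(self, toy_table):
        e = cs.embed(cs.ca_spectrum(toy_table))
        np.testing.assert_allclose(e.variation_shares, [1.0], atol=1e-12)

    def test_column_side_shares(self, toy_table):
        # column side has nontrivial eigenvalues {0.5, 0}: shares {100%, 0%}
        s = cs.ca_spectrum(toy_table)
        e = cs.embed(s, side="column")
        np.testing.assert_allclose(e.variation_shares, [1.0], atol=1e-12)

    def test_shares_sum_to_at_most_one(self):
        table = random_table(23)
        s = cs.ca_spectrum(table)
        partial = cs.embed(s, n_axes=2)
        full = cs.embed(s)
        assert partial.variation_shares.sum() <= full.variation_shares.sum() <= 1 + 1e-9

    def test_zero_axes_rejected(self, toy_table):
        with pytest.raises(ValueError):
            cs.embed(cs.ca_spectrum(toy_table), n_axes=0)


class TestComponentsAndArch:
    def test_identity_table_has_two_components(self):
        s = cs.ca_spectrum(cs.load_incidence(np.eye(2)))
        assert cs.count_components(s) == 2

    def test_connected_band_is_one_component(self):
        table, _ = cs.gradient_band(30, 30, 0.5, 0.9, seed=4)
        assert cs.count_components(cs.ca_spectrum(table)) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_component_count_matches_bfs(self, seed):
        import networkx as nx

        table, spec = cs.blocks(3, (12, 15), 0.4, 0.0, seed=seed)
        spectral = cs.count_components(cs.ca_spectrum(table))
        g = nx.Graph()
        A = table.dense()
        for i, j in zip(*np.nonzero(A)):
            g.add_edge(("r", i), ("c", j))
        assert spectral == nx.number_connected_components(g) == 3

    def test_exact_quadratic_gives_r2_one(self, toy_table):
        x = np.linspace(-1, 1, 20)
        e = cs.Embedding(
            coordinates=np.column_stack([x, 1 + 2 * x - 3 * x**2]),
            variation_shares=np.array([0.6, 0.3]),
            eigenvalues=np.array([0.6, 0.3]),
            side="row",
            labels=tuple(str(i) for i in range(20)),
        )
        assert cs.arch_diagnostic(e, 1, 2) == pytest.approx(1.0)

    def test_independent_noise_gives_r2_near_zero(self):
        rng = np.random.default_rng(0)
        x = np.linspace(-1, 1, 400)
        e = cs.Embedding(
            coordinates=np.column_stack([x, rng.standard_normal(400)]),
            variation_shares=np.array([0.6, 0.3]),
            eigenvalues=np.array([0.6, 0.3]),
            side="row",
            labels=tuple(str(i) for i in range(400)),
        )
        assert cs.arch_diagnostic(e, 1, 2) < 0.1

    def test_constant_axis_rejected(self):
        e = cs.Embedding(
            coordinates=np.column_stack([np.ones(5), np.arange(5.0)]),
            variation_shares=np.array([0.5, 0.2]),
            eigenvalues=np.array([0.5, 0.2]),
            side="row",
            labels=tuple("abcde"),
        )
        with pytest.raises(ValueError, match="degenerate"):
            cs.arch_diagnostic(e, 1, 2)

    def test_band_fixture_shows_the_arch(self):
        table, _ = cs.gradient_band(60, 60, 0.2, 0.9, seed=2)
        e = cs.embed(cs.ca_spectrum(table))
        assert cs.arch_diagnostic(e, 1, 2) > 0.5


# ---------------------------------------------------------------------------
# property tests


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_spectrum_bounds_and_identities(seed):
    """All eigenvalues live in [0, 1]; both solver routes agree; corr² = λ."""
    table = random_table(seed, max_rows=25, max_cols=35)
    s = cs.ca_spectrum(table)
    assert np.all((s.eigenvalues >= 0) & (s.eigenvalues <= 1))
    assert s.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
    vals, _ = cs.laplacian_generalized_eigs(cs.project_similarity(table, "row"))
    k = min(len(vals), len(s.eigenvalues))
    np.testing.assert_allclose(np.sort(vals)[:k], 1 - s.eigenvalues[:k], atol=1e-8)
    corr = cs.score_correlation(cs.edge_scores(table, s, 2))
    assert corr**2 == pytest.approx(s.eigenvalues[1], abs=1e-8)


@settings(max_examples=15, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_permutation_equivariance(seed):
    """Permuting rows/columns permutes scores and preserves eigenvalues."""
    table = random_table(seed, max_rows=20, max_cols=25)
    rng = np.random.default_rng(seed + 1)
    pr = rng.permutation(table.n_rows)
    pc = rng.permutation(table.n_cols)
    permuted = cs.load_incidence(
        table.to_frame().iloc[pr, pc], drop_empty=False
    )
    a = cs.ca_spectrum(table)
    b = cs.ca_spectrum(permuted)
    np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-9)
    for k in range(1, min(4, len(a.eigenvalues))):
        if a.eigenvalues[k] < 1e-8 or 1 - a.eigenvalues[k] < 1e-8:
            continue  # degenerate subspaces need not match vector-wise
        ref = a.row_scores[pr, k]
        got = b.row_scores[:, k]
        sign = np.sign(ref @ got)
        np.testing.assert_allclose(got * sign, ref, atol=1e-6)
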