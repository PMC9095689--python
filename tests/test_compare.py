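"""Difference maps, weight extraction, and the per-PC statistical battery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from myoshape.compare import (
    compare_groups,
    extract_weights,
    holm_bonferroni,
    kruskal_wallis,
    levene,
    mean_difference_map,
    shapiro_wilk,
)
from myoshape.errors import DegenerateInputError, DimensionError, ParameterError
from myoshape.mesh import ShapeVector, SurfaceMesh
from myoshape.model import WeightTable, fit_pca, project


class TestDifferenceMap:
    def test_self_comparison_is_zero(self, template_small):
        dmap = mean_difference_map(template_small, template_small)
        assert np.allclose(dmap.per_vertex_mm, 0.0)
        assert dmap.hausdorff_mm == pytest.approx(0.0, abs=1e-12)

    def test_unit_translation(self, template_small):
        moved = SurfaceMesh(
            template_small.vertices + [0.0, 0.0, 1.0], template_small.faces
        )
        dmap = mean_difference_map(template_small, moved)
        assert np.allclose(dmap.per_vertex_mm, 1.0)
        assert dmap.hausdorff_mm <= 1.0 + 1e-12

    def test_hausdorff_bounded_by_point_set_oracle(self, tetrahedron):
        rng = np.random.default_rng(8)
        a = SurfaceMesh(rng.normal(size=(50, 3)) * 10, _fan_faces(50))
        b = SurfaceMesh(a.vertices + rng.normal(size=(50, 3)), a.faces)
        dmap = mean_difference_map(a, b)
        oracle = _point_set_hausdorff(a.vertices, b.vertices)
        assert dmap.hausdorff_mm <= oracle + 1e-9

    def test_hausdorff_equals_point_oracle_on_offset_grids(self):
        """Flat grids offset perpendicular: every closest surface point is a
        vertex, so the surface and point-set Hausdorff coincide."""
        g = _grid_mesh(5)
        moved = SurfaceMesh(g.vertices + [0.0, 0.0, 1.0], g.faces)
        dmap = mean_difference_map(g, moved)
        assert dmap.hausdorff_mm == pytest.approx(
            _point_set_hausdorff(g.vertices, moved.vertices), abs=1e-9
        )

    def test_symmetry_of_per_vertex_distances(self, template_small):
        moved = SurfaceMesh(
            template_small.vertices * 1.02, template_small.faces
        )
        ab = mean_difference_map(template_small, moved)
        ba = mean_difference_map(moved, template_small)
        assert np.allclose(ab.per_vertex_mm, ba.per_vertex_mm)
        assert ab.hausdorff_mm == pytest.approx(ba.hausdorff_mm)

    def test_topology_mismatch_rejected(self, template_small, tetrahedron):
        with pytest.raises(DimensionError):
            mean_difference_map(template_small, tetrahedron)


def _fan_faces(n):
    return np.array([[0, i, i + 1] for i in range(1, n - 1)])


def _grid_mesh(n):
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return SurfaceMesh(verts, np.array(faces))


def _point_set_hausdorff(a, b):
    """Exhaustive double-loop point-set Hausdorff distance."""
    def directed(p, q):
        worst = 0.0
        for x in p:
            best = np.inf
            for y in q:
                best = min(best, float(np.linalg.norm(x - y)))
            worst = max(worst, best)
        return worst

    return max(directed(a, b), directed(b, a))


class TestExtractWeights:
    @pytest.fixture
    def model_and_vectors(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(10, 30))
        vecs = [ShapeVector(x, 10) for x in X]
        return fit_pca(vecs, k=4), vecs

    def test_training_weights_reproduced(self, model_and_vectors):
        model, vecs = model_and_vectors
        table = extract_weights(model, vecs, ["A"] * 10)
        expected = np.stack([project(model, v) for v in vecs])
        assert np.array_equal(table.weights, expected)

    def test_mean_shape_gives_zero_row(self, model_and_vectors):
        model, _ = model_and_vectors
        table = extract_weights(model, [model.mean], ["A"])
        assert np.allclose(table.weights, 0.0, atol=1e-9)

    def test_weight_covariance_is_diagonal_with_model_variances(
        self, model_and_vectors
    ):
        model, vecs = model_and_vectors
        W = extract_weights(model, vecs, ["A"] * 10).weights
        cov = np.cov(W, rowvar=False)
        assert np.allclose(np.diag(cov), model.variances, rtol=1e-6)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-6 * model.variances[0]

    def test_label_mismatch_rejected(self, model_and_vectors):
        model, vecs = model_and_vectors
        with pytest.raises(DimensionError):
            extract_weights(model, vecs, ["A"])


class TestShapiroWilk:
    def test_matches_independent_reference(self):
        # reference W from an independent implementation (R's shapiro.test)
        W, p = shapiro_wilk(np.arange(1.0, 11.0))
        assert W == pytest.approx(0.970165, abs=1e-3)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            shapiro_wilk(np.ones(10))

    def test_statistic_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            W, _ = shapiro_wilk(rng.normal(size=20))
            assert 0.0 < W <= 1.0

    def test_sample_size_domain(self):
        with pytest.raises(ParameterError):
            shapiro_wilk([1.0, 2.0])


class TestLevene:
    def test_identical_groups(self):
        stat, p = levene([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        """Levene W computed from the definition (mean-centred absolute
        deviations, one-way F) for groups (1,2,3,4) and (10,20,30,40)."""
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 20.0, 30.0, 40.0])
        za, zb = np.abs(a - a.mean()), np.abs(b - b.mean())
        zbar = np.concatenate([za, zb]).mean()
        num = (len(a) * (za.mean() - zbar) ** 2 + len(b) * (zb.mean() - zbar) ** 2) * (
            len(a) + len(b) - 2
        )
        den = (((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()) * 1
        stat, _ = levene(a, b)
        assert stat == pytest.approx(num / den, rel=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        stat, _ = levene(rng.normal(size=10), rng.normal(size=12))
        assert stat >= 0

    def test_min_group_size(self):
        with pytest.raises(ParameterError):
            levene([1.0], [1.0, 2.0])


class TestHolmBonferroni:
    def test_single_p_unchanged(self):
        adj, rej = holm_bonferroni([0.03], alpha=0.05)
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_example(self):
        adj, _ = holm_bonferroni([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8)
    )
    def test_matches_step_down_oracle_and_dominates_raw(self, p_values):
        """Brute-force step-down rule: sort ascending, adjusted_i is the
        running max of (m - j + 1) * p_(j), capped at 1."""
        adj, _ = holm_bonferroni(p_values)
        m = len(p_values)
        order = np.argsort(p_values)
        expected = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_values[idx])
            expected[idx] = min(1.0, running)
        assert np.allclose(adj, expected)
        assert np.all(adj >= np.asarray(p_values) - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            holm_bonferroni([0.5, 1.5])


class TestKruskalWallis:
    def test_hand_example(self):
        H, _ = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert H == pytest.approx(3.857, abs=1e-3)

    def test_null_p_is_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(1000):
            pool = rng.normal(size=12)
            H, p = kruskal_wallis(pool[:6], pool[6:])
            ps.append(p)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.05)

    def test_nonnegative(self):
        rng = np.random.default_rng(4)
        H, _ = kruskal_wallis(rng.normal(size=8), rng.normal(size=9))
        assert H >= 0

    def test_insufficient_data(self):
        with pytest.raises(ParameterError):
            kruskal_wallis([1.0, 2.0], [3.0])


class TestCompareGroups:
    def _table(self, a, b, k=None):
        a, b = np.atleast_2d(a), np.atleast_2d(b)
        if a.shape[0] == 1:
            a, b = a.T, b.T
        W = np.vstack([a, b])
        ids = [f"s{i}" for i in range(len(W))]
        labels = ["A"] * len(a) + ["B"] * len(b)
        return WeightTable(ids, labels, W)

    def test_strong_shift_detected_with_t_test(self):
        rng = np.random.default_rng(5)
        table = self._table(rng.normal(3.0, 1, 19), rng.normal(0.0, 1, 17))
        (res,) = compare_groups(table)
        assert res.test_used == "t_test"
        assert res.significant

    def test_non_normal_group_routes_to_kruskal_wallis(self):
        rng = np.random.default_rng(6)
        skewed = np.exp(rng.normal(0, 1.5, 30))  # lognormal: fails Shapiro
        normal = rng.normal(1.0, 1.0, 30)
        table = self._table(skewed, normal)
        (res,) = compare_groups(table, outlier_rule="none")
        assert res.normality_p["A"] <= 0.05
        assert res.test_used == "kruskal_wallis"

    def test_branch_choice_reproducible_from_recorded_gates(self):
        rng = np.random.default_rng(7)
        table = self._table(
            rng.normal(size=(15, 4)), rng.normal(size=(14, 4)) * [1, 1, 4, 1]
        )
        for res in compare_groups(table):
            gate_ok = (
                not res.outliers_excluded
                and res.normality_p["A"] > 0.05
                and res.normality_p["B"] > 0.05
                and res.variance_equality_p > 0.05
            )
            assert res.test_used == ("t_test" if gate_ok else "kruskal_wallis")

    def test_zero_variance_pc_flagged_without_breaking_others(self):
        rng = np.random.default_rng(8)
        a = np.column_stack([np.zeros(10), rng.normal(size=10)])
        b = np.column_stack([np.zeros(9), rng.normal(size=9)])
        results = compare_groups(self._table(a, b))
        assert results[0].error is not None
        assert not results[0].significant
        assert results[1].error is None
        assert np.isfinite(results[1].p_adjusted)

    def test_adjusted_p_dominates_raw(self):
        rng = np.random.default_rng(9)
        results = compare_groups(
            self._table(rng.normal(size=(12, 5)), rng.normal(size=(11, 5)))
        )
        for res in results:
            assert res.p_adjusted >= res.p_raw - 1e-15

    def test_outliers_recorded_and_route_to_nonparametric(self):
        a = np.array([0.1, 0.2, -0.1, 0.0, 0.15, 50.0])  # one wild point
        b = np.array([0.05, -0.05, 0.1, 0.0, -0.1])
        (res,) = compare_groups(self._table(a, b))
        assert res.outliers_excluded == ["s5"]
        assert res.test_used == "kruskal_wallis"

    def test_label_cardinality_enforced(self):
        table = WeightTable(["a", "b", "c"], ["A", "A", "A"], np.zeros((3, 1)))
        with pytest.raises(ParameterError):
            compare_groups(table)
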