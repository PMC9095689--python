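"""PCA shape model: mean, modes, projection, normalization, persistence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import subspace_angles
from scipy.optimize import minimize_scalar

from myoshape.errors import DegenerateGeometryError, DimensionError, ParameterError
from myoshape.mesh import ShapeVector, SurfaceMesh, mesh_to_shape_vector
from myoshape.model import (
    build_model,
    compute_mean,
    cumulative_variance,
    fit_pca,
    load_model,
    project,
    reconstruct,
    save_model,
    size_normalize,
)
from myoshape.registration import rigid_align
from myoshape.synthetic import (
    MODE_NAMES,
    GeneratorConfig,
    generate_cohort,
    mode_displacement_field,
)


def _vectors(X, n_vertices):
    return [ShapeVector(x, n_vertices) for x in X]


class TestMean:
    def test_two_vector_mean(self):
        vecs = _vectors([np.zeros(12), np.full(12, 2.0)], 4)
        assert np.array_equal(compute_mean(vecs).values, np.ones(12))

    def test_mean_of_copies_is_the_copy(self):
        v = np.arange(12.0)
        assert np.array_equal(compute_mean(_vectors([v] * 5, 4)).values, v)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 12))
        expected = np.zeros(12)
        for row in X:  # brute-force per-coordinate accumulation
            expected += row
        expected /= 5
        assert np.allclose(compute_mean(_vectors(X, 4)).values, expected)

    def test_errors(self):
        with pytest.raises(ParameterError):
            compute_mean([])
        with pytest.raises(DimensionError):
            compute_mean([ShapeVector(np.zeros(12), 4), ShapeVector(np.zeros(6), 2)])


class TestFitPca:
    def test_two_symmetric_shapes(self):
        u = np.zeros(12)
        u[0] = 1.0
        base = np.arange(12.0)
        a = 3.0
        model = fit_pca(_vectors([base + a * u, base - a * u], 4), k=1)
        assert np.allclose(np.abs(model.modes[:, 0]), u)
        # divisor m-1 on two points at distance a from the mean
        assert model.variances[0] == pytest.approx(2 * a * a)

    def test_identical_shapes_have_zero_variance(self):
        model = fit_pca(_vectors([np.arange(12.0)] * 4, 4), k=2)
        assert np.allclose(model.variances, 0.0)

    def test_dual_equals_direct_eigendecomposition(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = int(rng.integers(3, 11))
            nv = int(rng.integers(5, 51))
            X = rng.normal(size=(m, 3 * nv))
            model = fit_pca(_vectors(X, nv), k=m - 1)
            D = X - X.mean(axis=0)
            direct = np.sort(np.linalg.eigvalsh(D.T @ D / (m - 1)))[::-1][: m - 1]
            assert np.allclose(model.variances, direct, rtol=1e-8, atol=1e-10)

    def test_modes_orthonormal_and_variances_descending(self):
        rng = np.random.default_rng(1)
        model = fit_pca(_vectors(rng.normal(size=(8, 30)), 10), k=7)
        assert np.allclose(model.modes.T @ model.modes, np.eye(7), atol=1e-9)
        assert np.all(np.diff(model.variances) <= 1e-12)

    def test_total_variance_equals_covariance_trace(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 24))
        model = fit_pca(_vectors(X, 8), k=5)
        D = X - X.mean(axis=0)
        assert model.total_variance == pytest.approx(
            np.trace(D.T @ D) / 5, rel=1e-6
        )

    def test_k_bounds(self):
        vecs = _vectors(np.random.default_rng(0).normal(size=(4, 12)), 4)
        with pytest.raises(ParameterError):
            fit_pca(vecs, k=4)

    def test_generator_subspace_recovered_noise_free(self):
        cfg = GeneratorConfig(
            n_subjects=30, mode_sds=(1.0, 0.8, 0.6, 0, 0), noise_sd=0.0,
            resolution=6, seed=11,
        )
        cohort = generate_cohort(cfg)
        model = fit_pca([mesh_to_shape_vector(m) for m in cohort.meshes], k=3)
        F = np.stack(
            [
                mode_displacement_field(cohort.template, m).reshape(-1)
                for m in MODE_NAMES[:3]
            ],
            axis=1,
        )
        assert np.degrees(subspace_angles(model.modes, F)).max() < 0.5


class TestProjectReconstruct:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(4)
        return fit_pca(_vectors(rng.normal(size=(8, 30)), 10), k=5)

    def test_mean_projects_to_zero(self, model):
        assert np.allclose(project(model, model.mean), 0.0, atol=1e-9)

    def test_mode_projects_to_its_weight(self, model):
        vec = ShapeVector(model.mean.values + 2.0 * model.modes[:, 0], 10)
        b = project(model, vec)
        assert b[0] == pytest.approx(2.0)
        assert np.allclose(b[1:], 0.0, atol=1e-9)

    def test_reconstruct_zero_weights_gives_mean(self, model):
        assert np.allclose(reconstruct(model, []).values, model.mean.values)

    def test_project_reconstruct_round_trip(self, model):
        b = np.array([1.0, -2.0, 0.5, 0, 0])
        assert np.allclose(project(model, reconstruct(model, b)), b, atol=1e-9)

    def test_training_shape_reproduced_at_full_rank(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 24))
        vecs = _vectors(X, 8)
        model = fit_pca(vecs, k=5)
        for v in vecs:
            rec = reconstruct(model, project(model, v))
            assert np.abs(rec.values - v.values).max() < 1e-8

    def test_dimension_errors(self, model):
        with pytest.raises(DimensionError):
            project(model, ShapeVector(np.zeros(6), 2))
        with pytest.raises(DimensionError):
            reconstruct(model, np.zeros(6))


class TestCumulativeVariance:
    def test_full_rank_reaches_one(self):
        rng = np.random.default_rng(6)
        model = fit_pca(_vectors(rng.normal(size=(5, 18)), 6), k=4)
        assert cumulative_variance(model, 4) == pytest.approx(1.0)

    def test_single_mode_data(self):
        u = np.zeros(12)
        u[3] = 1.0
        X = np.arange(12.0) + np.array([[1.0], [-1.0], [2.0], [0.5]]) * u
        model = fit_pca(_vectors(X, 4), k=2)
        assert cumulative_variance(model, 1) == pytest.approx(1.0, abs=1e-9)

    def test_nine_three_one_variance_ratio(self):
        """Three orthonormal modes with variances 9:3:1 -> PC1 explains
        about 9/13 of the total at m = 200."""
        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.normal(size=(30, 3)))
        coeffs = rng.normal(size=(200, 3)) * np.sqrt([9.0, 3.0, 1.0])
        X = coeffs @ q.T
        model = fit_pca(_vectors(X, 10), k=3)
        assert cumulative_variance(model, 1) == pytest.approx(9 / 13, rel=0.1)

    def test_j_out_of_range(self):
        rng = np.random.default_rng(8)
        model = fit_pca(_vectors(rng.normal(size=(4, 12)), 4), k=3)
        with pytest.raises(ParameterError):
            cumulative_variance(model, 0)
        with pytest.raises(ParameterError):
            cumulative_variance(model, 4)


class TestSizeNormalize:
    def test_double_size_recovers_reference(self):
        ref = ShapeVector(np.arange(1.0, 13.0), 4)
        double = ShapeVector(2.0 * ref.values, 4)
        normalized, scales = size_normalize([double], ref)
        assert scales[0] == pytest.approx(0.5)
        assert np.allclose(normalized[0].values, ref.values)

    def test_reference_normalizes_to_itself(self):
        ref = ShapeVector(np.arange(1.0, 13.0), 4)
        _, scales = size_normalize([ref], ref)
        assert scales[0] == pytest.approx(1.0)

    def test_closed_form_matches_numeric_minimizer(self):
        rng = np.random.default_rng(9)
        ref = ShapeVector(rng.normal(size=30), 10)
        v = ShapeVector(rng.normal(size=30) * 3, 10)
        _, scales = size_normalize([v], ref)
        res = minimize_scalar(
            lambda s: float(((s * v.values - ref.values) ** 2).sum()),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert scales[0] == pytest.approx(res.x, abs=1e-6)

    def test_zero_norm_rejected(self):
        ref = ShapeVector(np.ones(12), 4)
        with pytest.raises(DegenerateGeometryError):
            size_normalize([ShapeVector(np.zeros(12), 4)], ref)

    @given(st.floats(min_value=0.2, max_value=5.0))
    def test_pure_scaling_always_undone(self, factor):
        ref = ShapeVector(np.arange(1.0, 13.0), 4)
        scaled = ShapeVector(factor * ref.values, 4)
        normalized, _ = size_normalize([scaled], ref)
        assert np.allclose(normalized[0].values, ref.values, atol=1e-9)


class TestBuildModel:
    def test_identical_meshes_give_null_model(self, template_small):
        model, table, rms = build_model(
            [template_small.copy() for _ in range(5)],
            k=3,
            assume_corresponded=True,
        )
        assert np.allclose(model.variances, 0.0, atol=1e-12)
        assert np.allclose(table.weights, 0.0, atol=1e-6)
        assert np.allclose(rms, 0.0)

    def test_size_only_cohort_pc1_dominates(self):
        cfg = GeneratorConfig(
            n_subjects=15, mode_sds=(1, 0, 0, 0, 0), noise_sd=0.0,
            resolution=6, seed=3,
        )
        cohort = generate_cohort(cfg)
        model, _, _ = build_model(cohort.meshes, k=3, assume_corresponded=True)
        assert cumulative_variance(model, 1) > 0.99

    def test_normalization_removes_size_variance(self):
        cfg = GeneratorConfig(
            n_subjects=15, mode_sds=(1, 0, 0, 0, 0), noise_sd=0.5,
            resolution=6, seed=3,
        )
        cohort = generate_cohort(cfg)
        raw, _, _ = build_model(cohort.meshes, k=3, assume_corresponded=True)
        normed, _, _ = build_model(
            cohort.meshes, normalize=True, k=3, assume_corresponded=True
        )
        assert normed.total_variance < 0.05 * raw.total_variance

    def test_registration_route_on_identical_meshes(self, template_small):
        model, table, rms = build_model(
            [template_small.copy() for _ in range(3)], k=2
        )
        assert np.all(np.asarray(rms) < 1e-9)
        assert np.allclose(model.variances, 0.0, atol=1e-9)

    def test_too_few_meshes(self, template_small):
        with pytest.raises(ParameterError):
            build_model([template_small], k=1)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        model = fit_pca(_vectors(rng.normal(size=(6, 24)), 8), k=4)
        model.topology = np.array([[0, 1, 2], [1, 2, 3]])
        model.normalized = True
        path = str(tmp_path / "model.h5")
        save_model(model, path, provenance={"seed": 1})
        back = load_model(path)
        assert np.allclose(back.mean.values, model.mean.values)
        assert np.allclose(back.modes, model.modes)
        assert np.allclose(back.variances, model.variances)
        assert np.array_equal(back.topology, model.topology)
        assert back.normalized is True
        assert back.total_variance == pytest.approx(model.total_variance)
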