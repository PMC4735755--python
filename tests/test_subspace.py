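"""Eigenface PCA and Fisher discriminant construction."""
import numpy as np
import pandas as pd
import pytest

from facespace import (
    LabeledFaceSet,
    fit_lfd,
    fit_pca,
    pad_orthogonal,
    project_fisher,
    project_pca,
    vectorize_and_center,
)


def toy_faceset(images):
    images = np.asarray(images, dtype=float)
    n = images.shape[0]
    labels = pd.DataFrame(
        {
            "sample_id": [f"{i:06d}" for i in range(n)],
            "identity": [f"id{i}" for i in range(n)],
            "sex": ["female"] * n,
            "race": ["asian"] * n,
            "expression": ["neutral"] * n,
            "viewpoint": [0.0] * n,
        }
    )
    return LabeledFaceSet(images=images, labels=labels)


class TestVectorize:
    def test_row_major_order_hand_enumerated(self):
        img = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        fs = toy_faceset([img, np.zeros((3, 3))])
        x, mean = vectorize_and_center(fs)
        # row-major concatenation, then the two-image mean subtracted
        expected = np.arange(1.0, 10.0)
        assert np.array_equal(x[0] + mean, expected)
        assert np.array_equal(mean, expected / 2)

    def test_identical_images_center_to_zero(self):
        img = np.random.default_rng(0).random((4, 4))
        x, _ = vectorize_and_center(toy_faceset([img, img]))
        assert np.allclose(x, 0.0)

    def test_single_image_mean_is_image(self):
        img = np.random.default_rng(1).random((4, 4))
        x, mean = vectorize_and_center(toy_faceset([img]))
        assert np.allclose(x, 0.0)
        assert np.array_equal(mean, img.ravel())


class TestPCA:
    def test_rank_limit_enforced(self, small_invariant_set):
        with pytest.raises(ValueError, match="n_components"):
            fit_pca(small_invariant_set, small_invariant_set.n_samples)

    def test_copies_of_one_image_give_zero_eigenvalues(self):
        img = np.random.default_rng(2).random((5, 5))
        model = fit_pca(toy_faceset([img] * 6), 3)
        assert np.allclose(model.eigenvalues, 0.0, atol=1e-20)

    def test_low_rank_data_recovered_against_eigh_oracle(self):
        # data on a known 5-dim basis, no noise: eigenvalues 6..10 vanish
        rng = np.random.default_rng(3)
        basis = rng.standard_normal((5, 36))
        data = (rng.standard_normal((40, 5)) @ basis).reshape(40, 6, 6)
        fs = toy_faceset(data)
        model = fit_pca(fs, 10)
        assert np.all(model.eigenvalues[5:] < 1e-12 * model.eigenvalues[0])
        x, _ = vectorize_and_center(fs)
        oracle = np.linalg.eigh(np.cov(x.T))[0][::-1][:10]
        assert np.allclose(model.eigenvalues, oracle, atol=1e-9)

    def test_components_orthonormal_and_sorted(self, small_invariant_set):
        model = fit_pca(small_invariant_set, 12)
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(12), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_reconstruction_error_monotone_in_k(self, small_invariant_set):
        x, _ = vectorize_and_center(small_invariant_set)
        errors = []
        for k in (2, 5, 10, 20):
            model = fit_pca(small_invariant_set, k)
            proj = x @ model.components.T @ model.components
            errors.append(float(np.sum((x - proj) ** 2)))
        assert errors == sorted(errors, reverse=True)

    def test_projection_variance_equals_eigenvalues(self, small_invariant_set):
        model = fit_pca(small_invariant_set, 8)
        coords = project_pca(model, small_invariant_set)
        assert np.allclose(coords.var(axis=0, ddof=1), model.eigenvalues, rtol=1e-8)

    def test_mean_face_projects_to_origin(self, small_invariant_set):
        model = fit_pca(small_invariant_set, 5)
        fs = toy_faceset([model.mean_face.reshape(model.image_shape)])
        assert np.allclose(project_pca(model, fs), 0.0, atol=1e-10)

    def test_component_displacement_projects_to_unit_axis(self, small_invariant_set):
        model = fit_pca(small_invariant_set, 5)
        c = 0.37
        img = (model.mean_face + c * model.components[2]).reshape(model.image_shape)
        coords = project_pca(model, toy_faceset([img]))
        expected = np.zeros(5)
        expected[2] = c
        assert np.allclose(coords[0], expected, atol=1e-10)

    def test_resolution_mismatch_raises(self, small_invariant_set):
        model = fit_pca(small_invariant_set, 3)
        with pytest.raises(ValueError, match="resolution"):
            project_pca(model, toy_faceset([np.zeros((4, 4))]))


def two_gaussian_classes(rng, n=400, k=10, sep=2.0):
    cov_root = rng.standard_normal((k, k)) * 0.4 + np.eye(k)
    mu = rng.standard_normal(k)
    delta = rng.standard_normal(k)
    delta *= sep / np.linalg.norm(delta)
    xa = rng.standard_normal((n // 2, k)) @ cov_root + mu
    xb = rng.standard_normal((n // 2, k)) @ cov_root + mu + delta
    coords = np.vstack([xa, xb])
    labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    return coords, labels, cov_root


class TestLFD:
    def test_two_class_direction_matches_closed_form(self):
        rng = np.random.default_rng(4)
        coords, labels, _ = two_gaussian_classes(rng)
        model = fit_lfd(coords, labels)
        mu_a = coords[labels == "a"].mean(axis=0)
        mu_b = coords[labels == "b"].mean(axis=0)
        s_w = sum(
            (coords[labels == c] - coords[labels == c].mean(axis=0)).T
            @ (coords[labels == c] - coords[labels == c].mean(axis=0))
            for c in ("a", "b")
        )
        oracle = np.linalg.solve(s_w, mu_a - mu_b)
        cos = np.dot(model.directions[0], oracle) / (
            np.linalg.norm(model.directions[0]) * np.linalg.norm(oracle)
        )
        assert abs(cos) > 0.999

    @pytest.mark.parametrize("n_classes", [2, 3, 6])
    def test_dimension_cap(self, n_classes):
        rng = np.random.default_rng(5)
        coords = rng.standard_normal((20 * n_classes, 8))
        labels = np.repeat([f"c{i}" for i in range(n_classes)], 20)
        model = fit_lfd(coords, labels)
        assert model.n_discriminants == min(n_classes - 1, 8)

    def test_permuted_labels_kill_dominant_eigenvalue(self):
        rng = np.random.default_rng(6)
        coords, labels, _ = two_gaussian_classes(rng, sep=4.0)
        true_ev = fit_lfd(coords, labels).eigenvalues[0]
        null_evs = [
            fit_lfd(coords, rng.permutation(labels)).eigenvalues[0]
            for _ in range(20)
        ]
        assert true_ev > 3 * max(null_evs)

    def test_directions_sw_orthonormal(self):
        rng = np.random.default_rng(7)
        coords = rng.standard_normal((60, 6))
        labels = np.repeat(["a", "b", "c"], 20)
        model = fit_lfd(coords, labels)
        assert np.allclose(model.gram_sw(), np.eye(model.n_discriminants), atol=1e-8)

    def test_scale_equivariance_of_directions(self):
        rng = np.random.default_rng(8)
        coords, labels, _ = two_gaussian_classes(rng)
        d1 = fit_lfd(coords, labels).directions[0]
        d2 = fit_lfd(coords * 7.5, labels).directions[0]
        cos = np.dot(d1, d2) / (np.linalg.norm(d1) * np.linalg.norm(d2))
        assert abs(cos) > 1 - 1e-9

    def test_errors_on_degenerate_labelings(self):
        coords = np.random.default_rng(9).standard_normal((10, 4))
        with pytest.raises(ValueError, match="2 distinct"):
            fit_lfd(coords, np.array(["a"] * 10))
        labels = np.array(["a"] * 9 + ["b"])
        with pytest.raises(ValueError, match="< 2 samples"):
            fit_lfd(coords, labels)


class TestPadding:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(10)
        coords = rng.standard_normal((80, 8))
        labels = np.repeat(["a", "b"], 40)
        return fit_lfd(coords, labels), coords

    def test_target_equal_m_leaves_model_unchanged(self, fitted):
        model, _ = fitted
        padded = pad_orthogonal(model, model.n_discriminants, seed=0)
        assert padded.n_padded == 0
        assert np.array_equal(padded.directions, model.directions)

    def test_padded_gram_identity_in_sw_metric(self, fitted):
        model, _ = fitted
        padded = pad_orthogonal(model, 4, seed=1)
        assert padded.total_dim == 4
        assert np.allclose(padded.gram_sw(), np.eye(4), atol=1e-8)

    def test_padding_deterministic_and_seed_dependent(self, fitted):
        model, _ = fitted
        a = pad_orthogonal(model, 5, seed=2)
        b = pad_orthogonal(model, 5, seed=2)
        c = pad_orthogonal(model, 5, seed=3)
        assert np.array_equal(a.padding, b.padding)
        assert not np.array_equal(a.padding, c.padding)
        assert np.array_equal(a.directions, c.directions)

    def test_target_bounds_enforced(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError, match="exceeds"):
            pad_orthogonal(model, 9, seed=0)
        with pytest.raises(ValueError, match="smaller"):
            pad_orthogonal(model, 0, seed=0)


class TestProjectFisher:
    def test_zero_coords_project_to_zero(self):
        rng = np.random.default_rng(11)
        coords = rng.standard_normal((40, 5))
        labels = np.repeat(["a", "b"], 20)
        model = fit_lfd(coords, labels)
        pset = project_fisher(model, np.zeros((3, 5)))
        assert np.allclose(pset.coordinates, 0.0)

    def test_separated_classes_stay_separated(self):
        rng = np.random.default_rng(12)
        coords = np.vstack(
            [rng.standard_normal((30, 4)), rng.standard_normal((30, 4)) + 12.0]
        )
        labels = np.repeat(["a", "b"], 30)
        model = fit_lfd(coords, labels)
        pset = project_fisher(model, coords, eval_labels=labels)
        mu = [pset.coordinates[labels == c].mean(axis=0) for c in ("a", "b")]
        between = np.linalg.norm(mu[0] - mu[1])
        within = max(
            np.linalg.norm(pset.coordinates[labels == c] - mu[i], axis=1).max()
            for i, c in enumerate(("a", "b"))
        )
        assert between > within

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(13)
        coords = rng.standard_normal((40, 5))
        labels = np.repeat(["a", "b"], 20)
        model = fit_lfd(coords, labels)
        with pytest.raises(ValueError, match="dimension"):
            project_fisher(model, np.zeros((3, 4)))
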