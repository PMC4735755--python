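"""Synthetic face generator: balance, determinism, latent structure."""
import dataclasses

import numpy as np
import pytest

from facespace import (
    AttributeSpec,
    FaceRenderer,
    LatentFaceCode,
    latent_to_image,
    make_identity_bank,
    render_expression_dataset,
    render_invariant_dataset,
)
from facespace.faces import (
    E_DIM,
    LATENT_DIM,
    M_DIM,
    N_IDENTITY_DIMS,
    RACE_DIM,
    SEX_DIM,
    V_DIM,
)


class TestIdentityBank:
    def test_balanced_cells_120(self):
        bank = make_identity_bank(AttributeSpec(120), seed=0)
        counts = {}
        for s, r in zip(bank.sex, bank.race):
            counts[(s, r)] = counts.get((s, r), 0) + 1
        assert set(counts.values()) == {30}

    def test_single_race_half_female(self):
        bank = make_identity_bank(
            AttributeSpec(50, race_levels=("asian",)), seed=0
        )
        assert bank.sex.count("female") == 25
        assert bank.sex.count("male") == 25
        assert set(bank.race) == {"asian"}
        # race constant => no offset on the race appearance dim
        assert np.allclose(bank.morphologies[:, RACE_DIM], 0.0)

    def test_indivisible_raises_naming_cells(self):
        with pytest.raises(ValueError, match="cells"):
            make_identity_bank(AttributeSpec(10), seed=0)  # 10 % 4 != 0

    def test_deterministic_given_seed(self):
        spec = AttributeSpec(4)
        a = make_identity_bank(spec, seed=5)
        b = make_identity_bank(spec, seed=5)
        assert np.array_equal(a.morphologies, b.morphologies)
        assert a.sex == b.sex and a.race == b.race

    def test_offset_scaling(self):
        bank = make_identity_bank(AttributeSpec(4), seed=1, effect_size=2.0)
        assert set(np.round(bank.morphologies[:, SEX_DIM], 12)) == {-2.0, 2.0}


class TestRenderer:
    def test_basis_full_column_rank(self, renderer):
        assert np.linalg.matrix_rank(renderer.basis) == LATENT_DIM

    def test_zero_code_renders_base_face(self, renderer):
        img = latent_to_image(np.zeros(LATENT_DIM), renderer)
        base = np.round(np.clip(renderer.base_face, 0, 1) * 255) / 255
        assert np.array_equal(img.ravel(), base)

    def test_negated_code_symmetric_about_base(self, renderer):
        code = np.zeros(LATENT_DIM)
        code[:4] = 0.5  # small enough that nothing clips
        plus = latent_to_image(code, renderer)
        minus = latent_to_image(-code, renderer)
        base = renderer.base_face.reshape(renderer.image_shape)
        # quantization allows at most one grey level of slack per pixel
        assert np.max(np.abs((plus + minus) / 2 - base)) <= 1.5 / 255

    def test_intensities_clipped_for_extreme_codes(self, renderer):
        img = latent_to_image(np.full(LATENT_DIM, 50.0), renderer)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_dimension_mismatch_raises(self, renderer):
        with pytest.raises(ValueError, match="dimension"):
            latent_to_image(np.zeros(5), renderer)

    def test_latent_face_code_concat_layout(self):
        code = LatentFaceCode(
            morphology=np.arange(M_DIM, dtype=float),
            expression=np.arange(E_DIM, dtype=float),
            viewpoint=np.arange(V_DIM, dtype=float),
        )
        assert code.concat().shape == (LATENT_DIM,)


class TestInvariantDataset:
    def test_one_image_per_identity_per_viewpoint(self, small_invariant_set):
        assert small_invariant_set.n_samples == 12 * 5
        per = small_invariant_set.labels.groupby(["identity", "viewpoint"]).size()
        assert (per == 1).all()

    def test_expression_column_constant(self, small_invariant_set):
        assert set(small_invariant_set.labels["expression"]) == {"neutral"}

    def test_bit_identical_on_same_seed(self, renderer):
        spec = AttributeSpec(4)
        bank = make_identity_bank(spec, seed=3)
        a = render_invariant_dataset(bank, noise_sd=0.02, seed=9, renderer=renderer)
        b = render_invariant_dataset(bank, noise_sd=0.02, seed=9, renderer=renderer)
        assert np.array_equal(a.images, b.images)
        assert a.labels.equals(b.labels)

    def test_identical_latent_codes_render_identically(self, renderer):
        bank = make_identity_bank(AttributeSpec(4), seed=3)
        morph = bank.morphologies.copy()
        morph[1] = morph[0]  # two identities with identical codes
        twin = dataclasses.replace(bank, morphologies=morph)
        ds = render_invariant_dataset(twin, noise_sd=0.0, seed=0, renderer=renderer)
        lab = ds.labels
        for vp in bank.spec.viewpoints:
            i0 = lab.index[(lab.identity == "id0000") & (lab.viewpoint == vp)][0]
            i1 = lab.index[(lab.identity == "id0001") & (lab.viewpoint == vp)][0]
            assert np.array_equal(ds.images[i0], ds.images[i1])

    def test_viewpoint_is_only_source_of_within_identity_change(self):
        # with pixel noise and pose interaction off, images of one identity
        # differ across viewpoints purely via the deterministic V shift
        quiet = FaceRenderer(seed=7, viewpoint_morph=0.0, viewpoint_offset_morph=0.0)
        bank = make_identity_bank(AttributeSpec(4), seed=3)
        ds = render_invariant_dataset(bank, noise_sd=0.0, seed=0, renderer=quiet)
        lab = ds.labels
        rows = lab.index[lab.identity == "id0000"]
        imgs = ds.images[rows]
        assert not np.array_equal(imgs[0], imgs[1])  # -10 vs 0 degrees
        lat = ds.latents[rows]
        assert np.allclose(lat[:, :M_DIM], lat[0, :M_DIM])  # morphology fixed
        assert np.allclose(lat[:, M_DIM:M_DIM + E_DIM], 0.0)

    def test_empty_viewpoints_raise(self, renderer):
        bank = make_identity_bank(AttributeSpec(4), seed=3)
        with pytest.raises(ValueError, match="non-empty"):
            render_invariant_dataset(bank, viewpoints=(), renderer=renderer)


class TestExpressionDataset:
    def test_one_image_per_identity_per_expression(self, small_expression_set):
        assert small_expression_set.n_samples == 8 * 6
        per = small_expression_set.labels.groupby(["identity", "expression"]).size()
        assert (per == 1).all()
        assert set(small_expression_set.labels["viewpoint"]) == {0.0}

    def test_kappa_out_of_range_raises(self, renderer):
        bank = make_identity_bank(AttributeSpec(4, race_levels=("asian",)), seed=1)
        with pytest.raises(ValueError, match="kappa"):
            render_expression_dataset(bank, kappa=1.5, renderer=renderer)

    def test_empty_expressions_raise(self, renderer):
        bank = make_identity_bank(AttributeSpec(4, race_levels=("asian",)), seed=1)
        with pytest.raises(ValueError, match="non-empty"):
            render_expression_dataset(bank, expressions=(), renderer=renderer)

    def test_kappa_zero_expression_block_independent_of_identity(
        self, small_expression_set
    ):
        """Permutation-test oracle: at kappa=0 the latent expression block
        carries no identity information (identity-mean deviations sit
        inside the permutation null)."""
        lat = small_expression_set.latents[:, M_DIM:M_DIM + E_DIM]
        ident = small_expression_set.labels["identity"].to_numpy()

        def stat(labels):
            groups = [lat[labels == g].mean(axis=0) for g in np.unique(labels)]
            return float(np.sum((np.asarray(groups) - lat.mean(axis=0)) ** 2))

        observed = stat(ident)
        rng = np.random.default_rng(0)
        null = np.array([stat(rng.permutation(ident)) for _ in range(300)])
        assert (null >= observed).mean() > 0.05

    def test_kappa_one_deformation_direction_identity_specific(self, renderer):
        bank = make_identity_bank(AttributeSpec(4, race_levels=("asian",)), seed=1)
        ds = render_expression_dataset(bank, kappa=1.0, noise_sd=0.0, seed=2,
                                       renderer=renderer)
        lat = ds.latents[:, M_DIM:M_DIM + E_DIM]
        ident = ds.labels["identity"].to_numpy()
        mean_dirs = []
        for g in np.unique(ident):
            m = lat[ident == g].mean(axis=0)
            mean_dirs.append(m / np.linalg.norm(m))
        cos = abs(float(np.dot(mean_dirs[0], mean_dirs[1])))
        assert cos < 0.99

    def test_sex_linearly_separable_from_latents(self, small_expression_set):
        from sklearn.linear_model import LogisticRegression

        lat = small_expression_set.latents
        sex = small_expression_set.labels["sex"].to_numpy()
        clf = LogisticRegression(max_iter=1000).fit(lat, sex)
        assert clf.score(lat, sex) > 0.95
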