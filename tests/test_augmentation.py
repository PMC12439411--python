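"""GMM intensity augmentation and paired geometric transforms."""

import numpy as np
import pytest

from vetbrain.augmentation import (
    AugmentationSpec,
    GmmIntensityModel,
    augment_study,
    fit_gmm,
    geometric_augment,
    perturb_model,
    transform_intensities,
)
from vetbrain.errors import VetbrainError
from vetbrain.geometry import BrainMask, ImageVolume, resample_to_iso_cube
from vetbrain.phantom import truth_mask_on_grid


def volume_from_samples(x, shape):
    return ImageVolume(np.asarray(x, dtype=np.float64).reshape(shape), np.eye(4))


class TestFitGmm:
    def test_single_gaussian_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 2.0, 10**5)
        model = fit_gmm(volume_from_samples(x, (100, 100, 10)), K=1, seed=0)
        assert model.means[0] == pytest.approx(5.0, rel=0.02)
        assert model.stds[0] == pytest.approx(2.0, rel=0.02)

    def test_two_separated_components_recovered(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0.0, 0.5, 60_000), rng.normal(10.0, 0.5, 40_000)])
        rng.shuffle(x)
        model = fit_gmm(volume_from_samples(x, (100, 100, 10)), K=2, seed=0)
        assert model.means[0] == pytest.approx(0.0, abs=0.5 * 0.05)
        assert model.means[1] == pytest.approx(10.0, rel=0.05)
        assert model.stds == pytest.approx([0.5, 0.5], rel=0.05)
        assert model.weights == pytest.approx([0.6, 0.4], abs=0.05)

    def test_seeded_determinism(self, rng):
        vol = volume_from_samples(rng.normal(3, 1, 8000), (20, 20, 20))
        a = fit_gmm(vol, K=2, seed=7)
        b = fit_gmm(vol, K=2, seed=7)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.stds, b.stds)
        assert np.array_equal(a.weights, b.weights)

    def test_too_few_voxels_rejected(self):
        vol = volume_from_samples(np.arange(1, 25, dtype=float), (2, 3, 4))
        with pytest.raises(VetbrainError):
            fit_gmm(vol, K=3, seed=0)


class TestPerturbModel:
    def model(self, K=2):
        return GmmIntensityModel(np.full(K, 1.0 / K), np.linspace(0, 5, K), np.full(K, 0.5))

    def test_degenerate_range_shifts_exactly(self):
        spec = AugmentationSpec(mean_shift_range=(1.5, 1.5), std_shift_range=(0.05, 0.05))
        out = perturb_model(self.model(), spec, np.random.default_rng(0))
        assert np.allclose(np.abs(out.means - self.model().means), 1.5)
        assert np.allclose(np.abs(out.stds - self.model().stds), 0.05)

    def test_shift_magnitudes_within_range_over_many_draws(self):
        model = self.model(K=3)
        spec = AugmentationSpec()
        rng = np.random.default_rng(42)
        for _ in range(10_000):
            out = perturb_model(model, spec, rng)
            d = np.abs(out.means - model.means)
            assert np.all(d >= 0.01 - 1e-12) and np.all(d <= 3.0 + 1e-12)

    def test_std_floor(self):
        model = GmmIntensityModel([1.0], [0.0], [0.02])
        spec = AugmentationSpec(std_shift_range=(0.1, 0.1))
        rng = np.random.default_rng(3)
        for _ in range(50):
            assert perturb_model(model, spec, rng).stds[0] >= 0.01

    def test_weights_unchanged(self):
        model = self.model(K=3)
        out = perturb_model(model, AugmentationSpec(), np.random.default_rng(5))
        assert np.array_equal(out.weights, model.weights)


class TestTransformIntensities:
    def test_identity_perturbation_is_noop(self, rng):
        vol = volume_from_samples(rng.normal(2, 1, 8000) + 10, (20, 20, 20))
        model = fit_gmm(vol, K=2, seed=0)
        out = transform_intensities(vol, model, model)
        assert np.abs(out.voxels - vol.voxels).max() < 1e-9

    def test_k1_mean_shift_is_global_shift(self, rng):
        vol = volume_from_samples(rng.normal(2, 1, 8000) + 10, (20, 20, 20))
        model = fit_gmm(vol, K=1, seed=0)
        shifted = GmmIntensityModel(model.weights, model.means + 0.7, model.stds)
        out = transform_intensities(vol, model, shifted)
        assert np.allclose(out.voxels - vol.voxels, 0.7, atol=1e-9)

    def test_selective_component_shift_follows_responsibility(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.5, 4000), rng.normal(10, 0.5, 4000)])
        rng.shuffle(x)
        vol = volume_from_samples(x, (20, 20, 20))
        model = fit_gmm(vol, K=2, seed=0)
        delta = 2.0
        shifted = GmmIntensityModel(
            model.weights, model.means + np.array([0.0, delta]), model.stds
        )
        out = transform_intensities(vol, model, shifted)
        gamma2 = model.responsibilities(vol.voxels.ravel())[:, 1].reshape(vol.shape)
        moved = out.voxels - vol.voxels
        assert np.allclose(moved[gamma2 > 0.99], delta, atol=0.01 * delta)
        assert np.all(np.abs(moved[gamma2 < 0.01]) < 0.01 * delta)
        # oracle: direct formula evaluation
        expected = gamma2 * delta
        assert np.allclose(moved, expected, atol=1e-9)

    def test_k_mismatch_rejected(self, rng):
        vol = volume_from_samples(rng.normal(0, 1, 8000), (20, 20, 20))
        m1 = fit_gmm(vol, K=1, seed=0)
        m2 = fit_gmm(vol, K=2, seed=0)
        with pytest.raises(VetbrainError):
            transform_intensities(vol, m1, m2)

    def test_mask_and_affine_untouched(self, rng):
        vol = volume_from_samples(rng.normal(0, 1, 8000), (20, 20, 20))
        model = fit_gmm(vol, K=1, seed=0)
        out = transform_intensities(vol, model, perturb_model(model, AugmentationSpec(), rng))
        assert np.array_equal(out.affine, vol.affine)


@pytest.fixture(scope="module")
def canonical_pair(clean_phantom):
    spec, ref, truth = clean_phantom
    vol = resample_to_iso_cube(ref, side=64)
    mask = truth_mask_on_grid(spec, vol.affine, vol.shape)
    return spec, vol, mask


class TestGeometricAugment:
    def test_flip_is_involution(self, canonical_pair):
        spec, vol, mask = canonical_pair
        s = AugmentationSpec(flip=True)
        v1, m1 = geometric_augment(vol, mask, s)
        v2, m2 = geometric_augment(v1, m1, s)
        assert np.array_equal(v2.voxels, vol.voxels)
        assert np.array_equal(m2.voxels, mask.voxels)

    def test_identity_parameters(self, canonical_pair):
        spec, vol, mask = canonical_pair
        v, m = geometric_augment(vol, mask, AugmentationSpec())
        assert np.array_equal(v.voxels, vol.voxels)
        assert np.array_equal(m.voxels, mask.voxels)

    def test_rotation_matches_analytic_oracle(self, canonical_pair):
        spec, vol, mask = canonical_pair
        theta = 10.0
        _, rotated = geometric_augment(vol, mask, AugmentationSpec(rotation_deg=theta))
        # oracle: voxel i is brain iff the back-rotated index point lies in the
        # analytic ellipsoid (rotation about the RL axis = index axes (1, 2))
        c = (np.array(vol.shape) - 1) / 2.0
        t = np.deg2rad(-theta)
        R = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])
        idx = np.indices(vol.shape, dtype=np.float64).reshape(3, -1)
        back = R @ (idx - c[:, None]) + c[:, None]
        world = vol.affine[:3, :3] @ back + vol.affine[:3, 3:4]
        axes = np.asarray(spec.brain_axes_mm, float)
        oracle = (((world / axes[:, None]) ** 2).sum(axis=0) <= 1.0).reshape(vol.shape)
        inter = np.logical_and(rotated.voxels > 0, oracle).sum()
        dice = 2 * inter / (rotated.voxels.sum() + oracle.sum())
        assert dice >= 0.97

    def test_mask_stays_binary_under_rotation_and_zoom(self, canonical_pair):
        spec, vol, mask = canonical_pair
        _, m = geometric_augment(vol, mask, AugmentationSpec(rotation_deg=7.0, zoom_factor=1.1))
        assert set(np.unique(m.voxels)) <= {0, 1}

    def test_zoom_discarding_mask_refused(self, canonical_pair):
        spec, vol, mask = canonical_pair
        with pytest.raises(ValueError):
            AugmentationSpec(zoom_factor=3.0)  # outside the configured band
        big = AugmentationSpec(zoom_factor=2.5, zoom_band=(0.4, 2.5))
        with pytest.raises(VetbrainError, match="discard"):
            geometric_augment(vol, mask, big)


class TestAugmentStudy:
    def test_pool_size_and_determinism(self, clean_phantom):
        spec, ref, truth = clean_phantom
        vol = resample_to_iso_cube(ref, side=48)
        mask = truth_mask_on_grid(spec, vol.affine, vol.shape)
        pairs, manifest = augment_study(vol, mask, n_augmentations=2, seed=9, subject_id="dog1")
        assert len(pairs) == 2 and len(manifest) == 2
        assert all(m["subject"] == "dog1" for m in manifest)
        pairs2, manifest2 = augment_study(vol, mask, n_augmentations=2, seed=9, subject_id="dog1")
        for (a, am), (b, bm) in zip(pairs, pairs2):
            assert np.array_equal(a.voxels, b.voxels)
            assert np.array_equal(am.voxels, bm.voxels)
        assert manifest == manifest2
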