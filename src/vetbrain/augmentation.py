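"""Training-set expansion: GMM intensity perturbation and paired geometry.

Intensity augmentation fits a K-component Gaussian mixture (K drawn from
{1, 2, 3}) to the foreground intensity histogram, shifts each component's
mean by a signed uniform draw from [0.01, 3.0] and its standard deviation
by a signed uniform draw from [0.01, 0.1] (floored at 0.01), and remaps
every foreground voxel through the posterior-weighted component transfer

    x  ->  sum_k gamma_k(x) * (sigma'_k / sigma_k * (x - mu_k) + mu'_k)

with gamma_k the responsibility of component k under the *original*
mixture.  Anatomy is untouched: the mask and affine never change under
intensity augmentation.  Geometric augmentation (left-right flip, rotation
about the right-left axis, center zoom) applies one identical spatial
transform to image and mask, nearest-neighbour for the mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .errors import DegenerateInputError, VetbrainError
from .geometry import BrainMask, ImageVolume, foreground_mask

__all__ = [
    "GmmIntensityModel",
    "AugmentationSpec",
    "fit_gmm",
    "perturb_model",
    "transform_intensities",
    "geometric_augment",
    "augment_study",
]


@dataclass
class GmmIntensityModel:
    """K weighted Gaussian components over foreground intensities."""

    weights: np.ndarray
    means: np.ndarray
    stds: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.means = np.asarray(self.means, dtype=float).ravel()
        self.stds = np.asarray(self.stds, dtype=float).ravel()
        if not (len(self.weights) == len(self.means) == len(self.stds)):
            raise ValueError("weights, means and stds must have equal length")
        if not 1 <= self.K <= 3:
            raise ValueError("K must be in {1, 2, 3}")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        if np.any(self.stds <= 0):
            raise ValueError("stds must be strictly positive")

    @property
    def K(self) -> int:
        return len(self.means)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior component probabilities, shape (len(x), K)."""
        x = np.asarray(x, dtype=np.float64)[:, None]
        log_pdf = (
            -0.5 * ((x - self.means) / self.stds) ** 2
            - np.log(self.stds)
            - 0.5 * np.log(2 * np.pi)
            + np.log(self.weights)
        )
        log_pdf -= log_pdf.max(axis=1, keepdims=True)
        p = np.exp(log_pdf)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class AugmentationSpec:
    """One augmentation draw: intensity-perturbation ranges plus geometry."""

    mean_shift_range: tuple[float, float] = (0.01, 3.0)
    std_shift_range: tuple[float, float] = (0.01, 0.1)
    flip: bool = False
    rotation_deg: float = 0.0
    zoom_factor: float = 1.0
    seed: int = 0
    zoom_band: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if self.zoom_factor <= 0:
            raise ValueError("zoom_factor must be > 0")
        lo, hi = self.zoom_band
        if not lo <= self.zoom_factor <= hi:
            raise ValueError(f"zoom_factor {self.zoom_factor} outside band {self.zoom_band}")

    def to_dict(self) -> dict:
        return {
            "mean_shift_range": list(self.mean_shift_range),
            "std_shift_range": list(self.std_shift_range),
            "flip": self.flip,
            "rotation_deg": self.rotation_deg,
            "zoom_factor": self.zoom_factor,
            "seed": self.seed,
            "zoom_band": list(self.zoom_band),
        }


def fit_gmm(vol: ImageVolume, K: int, seed: int) -> GmmIntensityModel:
    """EM fit of a K-component mixture to the foreground intensities.

    Deterministic given the seed; components are returned sorted by mean.
    """
    if not 1 <= K <= 3:
        raise VetbrainError("K must be in {1, 2, 3}")
    x = vol.voxels[foreground_mask(vol.voxels)].astype(np.float64)
    if x.size < 10 * K:
        raise VetbrainError(f"need >= {10 * K} foreground voxels to fit K={K} components")
    gm = GaussianMixture(
        n_components=K, covariance_type="full", random_state=int(seed), n_init=2, max_iter=200
    ).fit(x[:, None])
    means = gm.means_.ravel()
    stds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    return GmmIntensityModel(gm.weights_.ravel()[order], means[order], stds[order])


def perturb_model(
    model: GmmIntensityModel, spec: AugmentationSpec, rng: np.random.Generator
) -> GmmIntensityModel:
    """Randomly shift each component's mean and standard deviation.

    Means move by a signed uniform draw from ``spec.mean_shift_range``;
    standard deviations by a signed uniform draw from
    ``spec.std_shift_range``, floored at 0.01.  Weights are unchanged.
    """
    means = model.means.copy()
    stds = model.stds.copy()
    for k in range(model.K):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        means[k] += sign * rng.uniform(*spec.mean_shift_range)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        stds[k] = max(stds[k] + sign * rng.uniform(*spec.std_shift_range), 0.01)
    return GmmIntensityModel(model.weights.copy(), means, stds)


def transform_intensities(
    vol: ImageVolume, model: GmmIntensityModel, perturbed: GmmIntensityModel
) -> ImageVolume:
    """Remap foreground intensities from the fitted mixture to the perturbed one.

    Each foreground voxel moves through the responsibility-weighted
    per-component affine transfer; background voxels and the affine are
    untouched, so anatomy is preserved by construction.
    """
    if model.K != perturbed.K:
        raise VetbrainError("original and perturbed mixtures must share K")
    fg = foreground_mask(vol.voxels)
    x = vol.voxels[fg].astype(np.float64)
    gamma = model.responsibilities(x)
    mapped = (
        gamma
        * (perturbed.stds / model.stds * (x[:, None] - model.means) + perturbed.means)
    ).sum(axis=1)
    out = vol.voxels.astype(np.float64).copy()
    out[fg] = mapped
    return ImageVolume(out, vol.affine, vol.modality_tag)


def _apply_geometry(
    data: np.ndarray, spec: AugmentationSpec, order: int
) -> np.ndarray:
    """Flip (left-right axis), rotate about the RL axis, zoom about center."""
    out = data
    if spec.flip:
        out = out[::-1, :, :]
    if spec.rotation_deg != 0.0:
        # the RL axis is voxel axis 0 on the LAS grid: rotate in the (A, S) plane
        out = ndimage.rotate(
            out, spec.rotation_deg, axes=(1, 2), reshape=False, order=order, mode="constant"
        )
    if spec.zoom_factor != 1.0:
        center = (np.array(out.shape) - 1) / 2.0
        matrix = np.eye(3) / spec.zoom_factor
        offset = center - matrix @ center
        out = ndimage.affine_transform(
            out, matrix, offset=offset, order=order, mode="constant"
        )
    return np.ascontiguousarray(out)


def geometric_augment(
    vol: ImageVolume, mask: BrainMask, spec: AugmentationSpec
) -> tuple[ImageVolume, BrainMask]:
    """Apply one identical spatial transform to image and mask.

    The mask is interpolated nearest-neighbour and stays binary.  A zoom
    that would push more than 5% of the mask voxels outside the field of
    view is refused, mirroring the manual guard against cropping away the
    region of interest.
    """
    if vol.shape != mask.shape:
        raise VetbrainError("image and mask must share one grid")
    before = int(mask.voxels.sum())
    if before > 0:
        # forward-map mask voxels: rotation R(+deg) in the (A, S) plane, then
        # zoom about the grid center; refuse if > 5% leave the field of view
        idx = np.argwhere(mask.voxels > 0).astype(np.float64)
        center = (np.array(mask.shape) - 1) / 2.0
        pts = idx - center
        t = np.deg2rad(spec.rotation_deg)
        rot = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])
        pts = pts @ rot.T
        pts = pts * spec.zoom_factor + center
        outside = np.any((pts < -0.5) | (pts > np.array(mask.shape) - 0.5), axis=1)
        if outside.mean() > 0.05:
            raise VetbrainError(
                f"transform would discard {outside.mean():.1%} of the mask "
                "from the field of view"
            )
    new_mask = _apply_geometry(mask.voxels.astype(np.float32), spec, order=0) > 0.5
    new_img = _apply_geometry(vol.voxels.astype(np.float32), spec, order=1)
    return (
        ImageVolume(new_img, vol.affine.copy(), vol.modality_tag),
        BrainMask(new_mask.astype(np.uint8), mask.affine.copy()),
    )


def draw_spec(
    rng: np.random.Generator,
    mask_fraction: float,
    seed: int,
    rotation_max_deg: float = 10.0,
    zoom_band: tuple[float, float] = (0.8, 1.2),
) -> AugmentationSpec:
    """Draw one augmentation: random flip, rotation, and direction-aware zoom.

    Zoom direction follows the mask-to-foreground ratio: volumes dominated
    by non-brain tissue (ratio < 0.25) are zoomed in, others zoomed out.
    """
    flip = bool(rng.random() < 0.5)
    rotation = float(rng.uniform(-rotation_max_deg, rotation_max_deg))
    lo, hi = zoom_band
    if mask_fraction < 0.25:
        zoom = float(rng.uniform(1.0, hi))
    else:
        zoom = float(rng.uniform(lo, 1.0))
    return AugmentationSpec(
        flip=flip, rotation_deg=rotation, zoom_factor=zoom, seed=seed, zoom_band=zoom_band
    )


def augment_study(
    vol: ImageVolume,
    mask: BrainMask,
    n_augmentations: int,
    seed: int,
    subject_id: str = "",
) -> tuple[list[tuple[ImageVolume, BrainMask]], list[dict]]:
    """Produce ``n_augmentations`` augmented copies plus a JSON-able manifest.

    Each copy draws K in {1, 2, 3}, fits and perturbs a mixture, remaps
    intensities, then applies a random geometric transform to image and
    mask together.  Everything is a deterministic function of (input, seed);
    the manifest records per-sample specs for exact reproduction.
    """
    rng = np.random.default_rng(seed)
    fg_count = int(foreground_mask(vol.voxels).sum())
    mask_fraction = mask.count() / max(fg_count, 1)
    out: list[tuple[ImageVolume, BrainMask]] = []
    manifest: list[dict] = []
    for i in range(n_augmentations):
        sample_seed = int(rng.integers(0, 2**31 - 1))
        sample_rng = np.random.default_rng(sample_seed)
        K = int(sample_rng.integers(1, 4))
        spec = draw_spec(sample_rng, mask_fraction, seed=sample_seed)
        model = fit_gmm(vol, K, seed=sample_seed)
        perturbed = perturb_model(model, spec, sample_rng)
        intens = transform_intensities(vol, model, perturbed)
        try:
            img_aug, mask_aug = geometric_augment(intens, mask, spec)
        except VetbrainError:
            # zoom guard tripped: keep the intensity augmentation only
            spec.zoom_factor = 1.0
            spec.rotation_deg = 0.0
            img_aug, mask_aug = geometric_augment(intens, mask, spec)
        out.append((img_aug, mask_aug))
        manifest.append(
            {"subject": subject_id, "index": i, "K": K, "spec": spec.to_dict()}
        )
    return out, manifest
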