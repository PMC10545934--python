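"""Training-time augmentation: photometric, dihedral, and elastic transforms.

Photometric transforms touch the input image only; geometric and elastic
transforms apply the identical spatial map to the image and its labeled mask
(the mask resampled label-preservingly, order 0). Elastic deformation is
intended for raw-mask training targets; when the target is a flow field it
should be skipped, since the flow of a deformed mask would need re-encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "AugmentConfig",
    "DihedralTransform",
    "sample_dihedral",
    "intensity_augment",
    "geometric_augment",
    "elastic_augment",
]


@dataclass
class AugmentConfig:
    """Augmentation parameters.

    Defaults follow the protocol used for downstream segmentation training:
    multiplicative intensity gain U(0.6, 2.0), additive bias U(-0.2, 0.2),
    Gaussian noise of strength 0.02, flips/rotations with probability 0.5 per
    axis, and a smooth random elastic field (alpha in pixels of displacement,
    sigma the Gaussian smoothing scale in pixels).
    """

    intensity_lo: float = 0.6
    intensity_hi: float = 2.0
    bias_lo: float = -0.2
    bias_hi: float = 0.2
    noise_sigma: float = 0.02
    flip_prob: float = 0.5
    elastic_alpha: float = 10.0
    elastic_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_lo > self.intensity_hi:
            raise ValueError("intensity_lo must be <= intensity_hi")
        if self.bias_lo > self.bias_hi:
            raise ValueError("bias_lo must be <= bias_hi")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def intensity_augment(
    image: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    clip: bool = True,
    eps: float = 1e-6,
) -> np.ndarray:
    """Random joint intensity change: ``clip(c * image + b + noise, 0, 1)``.

    ``c ~ U(intensity_lo, intensity_hi)``, ``b ~ U(bias_lo, bias_hi)``, noise
    iid Normal(0, noise_sigma). The mask is never touched by photometric
    transforms. Input must already be scaled to [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size and (image.min() < -eps or image.max() > 1.0 + eps):
        raise ValueError("image must be scaled to [0, 1] before intensity augmentation")
    c = rng.uniform(cfg.intensity_lo, cfg.intensity_hi)
    b = rng.uniform(cfg.bias_lo, cfg.bias_hi)
    out = c * image + b
    if cfg.noise_sigma > 0:
        out = out + rng.normal(0.0, cfg.noise_sigma, size=image.shape)
    return np.clip(out, 0.0, 1.0) if clip else out


@dataclass(frozen=True)
class DihedralTransform:
    """A flip/90-degree-rotation element; exactly invertible on pixel grids."""

    flip_y: bool
    flip_x: bool
    k_rot: int  # number of CCW 90-degree rotations, 0..3

    def apply(self, arr: np.ndarray) -> np.ndarray:
        out = arr
        if self.flip_y:
            out = np.flip(out, axis=0)
        if self.flip_x:
            out = np.flip(out, axis=1)
        return np.rot90(out, self.k_rot).copy()

    def apply_inverse(self, arr: np.ndarray) -> np.ndarray:
        out = np.rot90(arr, -self.k_rot)
        if self.flip_x:
            out = np.flip(out, axis=1)
        if self.flip_y:
            out = np.flip(out, axis=0)
        return out.copy()


def sample_dihedral(cfg: AugmentConfig, rng: np.random.Generator) -> DihedralTransform:
    """Flip each axis with probability ``flip_prob`` independently; with the
    same probability apply a uniformly chosen multiple of 90 degrees."""
    flip_y = bool(rng.random() < cfg.flip_prob)
    flip_x = bool(rng.random() < cfg.flip_prob)
    k = int(rng.integers(4)) if rng.random() < cfg.flip_prob else 0
    return DihedralTransform(flip_y=flip_y, flip_x=flip_x, k_rot=k)


def geometric_augment(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one sampled dihedral transform jointly to image and mask.

    Flips and 90-degree rotations permute pixels, so per-label pixel counts
    are preserved exactly and the mask needs no interpolation.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask must share spatial shape")
    t = sample_dihedral(cfg, rng)
    return t.apply(image), t.apply(mask)


def elastic_augment(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth random elastic deformation applied jointly to image and mask.

    A per-component iid U(-1, 1) displacement field is smoothed with a
    Gaussian of std ``elastic_sigma`` and scaled by ``elastic_alpha``; the
    image is warped bilinearly and the mask by nearest neighbor with the same
    field, so no new label ids can appear.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask must share spatial shape")
    if cfg.elastic_alpha == 0:
        return image.copy(), mask.copy()
    if cfg.elastic_sigma <= 0:
        raise ValueError("elastic_sigma must be > 0 when elastic_alpha > 0 (unsmoothed fields tear)")

    shape = mask.shape[:2]
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, size=shape), cfg.elastic_sigma) * cfg.elastic_alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, size=shape), cfg.elastic_sigma) * cfg.elastic_alpha
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    coords = np.stack([yy + dy, xx + dx])
    warped_image = ndimage.map_coordinates(image, coords, order=1, mode="reflect")
    warped_mask = ndimage.map_coordinates(mask, coords, order=0, mode="reflect")
    return warped_image, warped_mask
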