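"""Stochastic data augmentation with exact landmark remapping.

Four treatments — Gaussian blur, brightness/contrast, rotation and
rectangular occlusion — are each applied independently with probability
0.5 (configurable).  Only rotation moves landmarks; occluded landmarks
keep their true positions (the label describes where the point *is*, not
whether it is visible), and points rotated out of the canvas keep their
coordinates but are flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

from .schema import LandmarkSet, N_CARAPACE_POINTS, N_POINTS, update_validity
from .synthetic import AnnotatedImage

__all__ = [
    "AugmentationConfig",
    "apply_photometric",
    "apply_rotation",
    "apply_occlusion",
    "augment_sample",
    "sample_decisions",
]


@dataclass
class AugmentationConfig:
    p_blur: float = 0.5
    p_photometric: float = 0.5
    p_rotation: float = 0.5
    p_occlusion: float = 0.5
    sigma_range: tuple[float, float] = (0.5, 3.0)          # px
    brightness_range: tuple[float, float] = (-40.0, 40.0)  # additive shift
    contrast_range: tuple[float, float] = (0.7, 1.3)       # multiplicative
    rotation_range: tuple[float, float] = (-30.0, 30.0)    # degrees
    n_occlusions: tuple[int, int] = (1, 3)
    occlusion_area: tuple[float, float] = (0.02, 0.10)     # fraction of image

    def validate(self):
        for p in (self.p_blur, self.p_photometric, self.p_rotation,
                  self.p_occlusion):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (self.sigma_range, self.brightness_range,
                       self.contrast_range, self.rotation_range,
                       self.occlusion_area):
            if lo > hi:
                raise ValueError("ranges must be ordered (lo <= hi)")
        if self.n_occlusions[0] > self.n_occlusions[1]:
            raise ValueError("occlusion count range must be ordered")
        lo, hi = self.occlusion_area
        if not (0.0 < lo <= hi < 1.0) and not (lo == hi == 0.0):
            raise ValueError("occlusion area fractions must lie in (0, 1)")


def apply_photometric(image: np.ndarray, sigma: float, brightness: float,
                      contrast: float) -> np.ndarray:
    """Gaussian blur then v' = clip(contrast*(v-128) + 128 + brightness)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if contrast <= 0:
        raise ValueError("contrast factor must be positive")
    img = image.astype(np.float64)
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
    img = contrast * (img - 128.0) + 128.0 + brightness
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _rotate_coords(coords: np.ndarray, angle_deg: float, cx: float,
                   cy: float) -> np.ndarray:
    """Landmark map matching the image rotation (about the pixel center).

    The image rotates counter-clockwise on screen; with y pointing down
    this is x' = cx + dx cos(t) + dy sin(t), y' = cy - dx sin(t) + dy cos(t).
    """
    t = np.deg2rad(angle_deg)
    dx = coords[:, 0] - cx
    dy = coords[:, 1] - cy
    out = np.empty_like(coords)
    out[:, 0] = cx + dx * np.cos(t) + dy * np.sin(t)
    out[:, 1] = cy - dx * np.sin(t) + dy * np.cos(t)
    return out


def apply_rotation(image: np.ndarray, landmarks: LandmarkSet,
                   angle_deg: float,
                   fill: float | tuple | None = None
                   ) -> tuple[np.ndarray, LandmarkSet]:
    """Rotate image and landmarks about the canvas center.

    The canvas size is fixed; exposed corners are filled with ``fill`` (a
    border-median estimate of the background when not given).  Landmarks
    leaving the frame keep coordinates but get ``valid=False``; bounding-box
    corner points are recomputed from the rotated carapace points since an
    axis-aligned box does not rotate onto itself.
    """
    if landmarks.frame != "pixel":
        raise ValueError("rotation operates on pixel-frame landmarks")
    H, W = image.shape[:2]
    if fill is None:
        border = np.concatenate([image[0], image[-1], image[:, 0],
                                 image[:, -1]])
        fill = float(np.median(border))
    out_img = _sk_rotate(image.astype(np.float64), angle_deg, resize=False,
                         order=1, cval=float(np.mean(fill)), mode="constant",
                         preserve_range=True)
    out_img = np.clip(np.round(out_img), 0, 255).astype(np.uint8)

    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    rotated = _rotate_coords(landmarks.coords[:N_CARAPACE_POINTS], angle_deg,
                             cx, cy)
    lm = LandmarkSet(rotated, frame="pixel", width=W, height=H,
                     schema=landmarks.schema)
    lm = update_validity(lm)
    if landmarks.n_points == N_POINTS:
        lm = lm.with_bbox()
    return out_img, lm


def apply_occlusion(image: np.ndarray, rng: np.random.Generator,
                    n_range: tuple[int, int] = (1, 3),
                    area_range: tuple[float, float] = (0.02, 0.10)
                    ) -> np.ndarray:
    """Overwrite 0..k axis-aligned rectangles with random uniform colors."""
    H, W = image.shape[:2]
    out = image.copy()
    k = int(rng.integers(n_range[0], n_range[1] + 1))
    for _ in range(k):
        frac = rng.uniform(*area_range)
        aspect = rng.uniform(0.6, 1.6)
        n_px = frac * H * W
        w = int(np.clip(round(np.sqrt(n_px * aspect)), 1, W))
        h = int(np.clip(round(n_px / w), 1, H))
        x0 = int(rng.integers(0, W - w + 1))
        y0 = int(rng.integers(0, H - h + 1))
        color = rng.integers(0, 256, size=3, dtype=np.int64)
        out[y0:y0 + h, x0:x0 + w] = color.astype(np.uint8)
    return out


def sample_decisions(config: AugmentationConfig,
                     rng: np.random.Generator) -> dict:
    """Bernoulli application decisions plus the sampled transform params.

    Factored out of :func:`augment_sample` so the application frequencies
    can be audited directly.
    """
    config.validate()
    rec: dict = {}
    rec["blur"] = ({"sigma": float(rng.uniform(*config.sigma_range))}
                   if rng.random() < config.p_blur else None)
    rec["photometric"] = (
        {"brightness": float(rng.uniform(*config.brightness_range)),
         "contrast": float(rng.uniform(*config.contrast_range))}
        if rng.random() < config.p_photometric else None)
    rec["rotation"] = (
        {"angle": float(rng.uniform(*config.rotation_range))}
        if rng.random() < config.p_rotation else None)
    rec["occlusion"] = ({} if rng.random() < config.p_occlusion else None)
    return rec


def augment_sample(sample: AnnotatedImage, config: AugmentationConfig,
                   rng: np.random.Generator) -> AnnotatedImage:
    """Apply each treatment independently with its probability."""
    rec = sample_decisions(config, rng)
    img = sample.image
    lm = sample.landmarks.copy()
    if rec["blur"] is not None:
        img = apply_photometric(img, rec["blur"]["sigma"], 0.0, 1.0)
    if rec["photometric"] is not None:
        img = apply_photometric(img, 0.0, rec["photometric"]["brightness"],
                                rec["photometric"]["contrast"])
    if rec["rotation"] is not None:
        img, lm = apply_rotation(img, lm, rec["rotation"]["angle"])
    if rec["occlusion"] is not None:
        img = apply_occlusion(img, rng, config.n_occlusions,
                              config.occlusion_area)
    return AnnotatedImage(image=img, landmarks=lm, params=sample.params,
                          augment=rec, split=sample.split)
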