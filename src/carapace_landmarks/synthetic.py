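"""Procedural generation of carapace-like annotated images.

Real mitten-crab photographs are not publicly deposited, so the package
ships a procedural generator that emulates the geometry the annotation
schema describes: a convex super-ellipse body, twelve marginal teeth in
three groups of four (adjacent teeth sharing their junction point), a flat
rear edge and an M-shaped neck groove, over a textured background with a
linear illumination gradient.  Every image comes with exact ground-truth
landmarks placed analytically on the outline, so localization error is
measured against a noiseless reference.

The generator does not attempt photorealism: it reproduces the landmark
topology and the local appearance cues (outline bumps for teeth, a darker
polyline for the groove) that the detection networks rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .schema import LandmarkSet, build_schema, write_annotation

__all__ = [
    "CarapaceParams",
    "JitterConfig",
    "AnnotatedImage",
    "sample_params",
    "landmarks_from_params",
    "outline_polygon",
    "render",
    "make_dataset",
    "generate_dataset",
    "default_test_size",
]

# Angular layout (degrees; image frame, x rightward, y downward, so 270 deg
# points toward the top of the image = the crab's front).
_FRONTAL_ARC = (225.0, 315.0)     # left -> right across the top
_LEFT_ARC = (220.0, 156.0)        # front -> rear down the left edge
_RIGHT_ARC = (320.0, 384.0)       # front -> rear down the right edge
_REAR_ANGLES = (115.0, 90.0, 65.0)  # left -> right along the bottom


@dataclass
class CarapaceParams:
    """Geometry, texture and illumination of one synthetic carapace."""

    image_size: int = 128
    center: tuple[float, float] = (64.0, 64.0)
    semi_axes: tuple[float, float] = (42.0, 37.0)   # (a horizontal, b vertical)
    orientation: float = 0.0                        # radians
    superellipse_exponent: float = 2.5
    tooth_amplitudes: np.ndarray = field(
        default_factory=lambda: np.full(12, 5.5))   # px, outward
    groove_offset: float = -4.5                     # px from center, body frame
    groove_amplitude: float = 6.0                   # px
    groove_halfwidth: float = 17.5                  # px
    illumination_strength: float = 0.2              # 0..1
    illumination_angle: float = 0.7                 # radians
    texture_seed: int = 0
    background_seed: int = 1

    def validate(self):
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        if np.any(np.asarray(self.tooth_amplitudes) < 0):
            raise ValueError("tooth amplitudes must be non-negative")
        extent = max(a, b) + float(np.max(self.tooth_amplitudes))
        cx, cy = self.center
        s = self.image_size
        if (cx - extent < 1 or cy - extent < 1
                or cx + extent > s - 2 or cy + extent > s - 2):
            raise ValueError("carapace does not fit inside the image")


@dataclass
class JitterConfig:
    """Relative sampling ranges for :func:`sample_params`.

    All geometric ranges are fractions of the image size (or multiplicative
    factors), so one config works at any resolution.
    """

    center_jitter: float = 0.035        # +- fraction of image size
    scale_range: tuple[float, float] = (0.88, 1.12)
    # shooting angles of the source imagery are near-uniform (the camera
    # was held aligned above each crab), so the un-augmented renders get
    # only a small in-plane pose wobble; larger rotations enter through
    # the augmentation protocol
    orientation_range: tuple[float, float] = (-0.08, 0.08)  # radians
    amplitude_factor_range: tuple[float, float] = (0.65, 1.35)
    groove_factor_range: tuple[float, float] = (0.8, 1.2)
    illumination_range: tuple[float, float] = (0.0, 0.4)

    @classmethod
    def zero(cls) -> "JitterConfig":
        return cls(center_jitter=0.0, scale_range=(1.0, 1.0),
                   orientation_range=(0.0, 0.0),
                   amplitude_factor_range=(1.0, 1.0),
                   groove_factor_range=(1.0, 1.0),
                   illumination_range=(0.2, 0.2))


@dataclass
class AnnotatedImage:
    """An image plus its ground-truth landmarks and provenance."""

    image: np.ndarray                 # (H, W, 3) uint8
    landmarks: LandmarkSet            # pixel frame, 39 points
    params: CarapaceParams | None = None
    augment: dict | None = None
    split: str | None = None


def _template_params(image_size: int) -> CarapaceParams:
    s = float(image_size)
    return CarapaceParams(
        image_size=image_size,
        center=(s / 2.0, s / 2.0),
        semi_axes=(0.33 * s, 0.29 * s),
        orientation=0.0,
        tooth_amplitudes=np.full(12, 0.042 * s),
        groove_offset=-0.12 * 0.29 * s,
        groove_amplitude=0.16 * 0.29 * s,
        groove_halfwidth=0.42 * 0.33 * s,
        illumination_strength=0.2,
        illumination_angle=0.7,
    )


def sample_params(rng_seed: int, jitter: JitterConfig | None = None,
                  image_size: int = 128) -> CarapaceParams:
    """Draw one parameter set; deterministic for a given seed."""
    jitter = jitter or JitterConfig()
    rng = np.random.default_rng(rng_seed)
    t = _template_params(image_size)
    s = float(image_size)
    cj = jitter.center_jitter * s
    center = (t.center[0] + rng.uniform(-cj, cj),
              t.center[1] + rng.uniform(-cj, cj))
    scale = rng.uniform(*jitter.scale_range, size=2)
    semi_axes = (t.semi_axes[0] * scale[0], t.semi_axes[1] * scale[1])
    orientation = rng.uniform(*jitter.orientation_range)
    amps = t.tooth_amplitudes * rng.uniform(
        *jitter.amplitude_factor_range, size=12)
    gf = rng.uniform(*jitter.groove_factor_range)
    params = CarapaceParams(
        image_size=image_size,
        center=center,
        semi_axes=semi_axes,
        orientation=float(orientation),
        tooth_amplitudes=amps,
        groove_offset=t.groove_offset,
        groove_amplitude=t.groove_amplitude * gf,
        groove_halfwidth=t.groove_halfwidth * min(scale[0], 1.0),
        illumination_strength=float(rng.uniform(*jitter.illumination_range)),
        illumination_angle=float(rng.uniform(0.0, 2.0 * np.pi)),
        texture_seed=int(rng.integers(0, 2 ** 31 - 1)),
        background_seed=int(rng.integers(0, 2 ** 31 - 1)),
    )
    params.validate()
    return params


# ---------------------------------------------------------------------------
# geometry


def _base_radius(params: CarapaceParams, angles_rad: np.ndarray) -> np.ndarray:
    a, b = params.semi_axes
    p = params.superellipse_exponent
    c = np.abs(np.cos(angles_rad) / a) ** p
    s = np.abs(np.sin(angles_rad) / b) ** p
    return (c + s) ** (-1.0 / p)


def _body_to_world(params: CarapaceParams, pts: np.ndarray) -> np.ndarray:
    th = params.orientation
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return pts @ R.T + np.asarray(params.center)


def _rim_points(params: CarapaceParams, angles_deg: np.ndarray,
                radial_offset: np.ndarray | float = 0.0) -> np.ndarray:
    ang = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    r = _base_radius(params, ang) + radial_offset
    body = np.stack([r * np.cos(ang), r * np.sin(ang)], axis=-1)
    return _body_to_world(params, body)


# The M-shape of the groove: relative depths of the seven vertices; the
# five interior vertices alternate down-up-down-up along the polyline.
_GROOVE_PATTERN = np.array([0.0, 1.0, 0.15, 0.7, 0.15, 1.0, 0.0])


def landmarks_from_params(params: CarapaceParams) -> LandmarkSet:
    """Place the 37 carapace points analytically; bbox corners appended."""
    params.validate()
    amps = np.asarray(params.tooth_amplitudes, dtype=np.float64)
    sections = []
    for (lo, hi), group_amps in zip(
            (_FRONTAL_ARC, _LEFT_ARC, _RIGHT_ARC),
            (amps[0:4], amps[4:8], amps[8:12])):
        angles = np.linspace(lo, hi, 9)
        offsets = np.zeros(9)
        offsets[1::2] = group_amps       # peaks sit at odd positions
        sections.append(_rim_points(params, angles, offsets))
    rear = _rim_points(params, np.array(_REAR_ANGLES))
    gx = np.linspace(-params.groove_halfwidth, params.groove_halfwidth, 7)
    gy = params.groove_offset + params.groove_amplitude * _GROOVE_PATTERN
    groove = _body_to_world(params, np.stack([gx, gy], axis=-1))
    coords = np.vstack(sections + [rear, groove])
    lm = LandmarkSet(coords, frame="pixel", width=params.image_size,
                     height=params.image_size, schema=build_schema())
    return lm.with_bbox()


def outline_polygon(params: CarapaceParams,
                    base_step_deg: float = 3.0) -> np.ndarray:
    """Closed outline through all tooth landmarks, (n, 2) world coords.

    Outside the tooth arcs the base super-ellipse is sampled densely; inside
    them the polygon passes exactly through the start/peak/end landmarks, so
    the rendered rim coincides with the annotation.
    """
    amps = np.asarray(params.tooth_amplitudes, dtype=np.float64)
    entries: list[tuple[float, np.ndarray]] = []
    sectors = []
    for (lo, hi), group_amps in zip(
            (_FRONTAL_ARC, _LEFT_ARC, _RIGHT_ARC),
            (amps[0:4], amps[4:8], amps[8:12])):
        angles = np.linspace(lo, hi, 9)
        offsets = np.zeros(9)
        offsets[1::2] = group_amps
        pts = _rim_points(params, angles, offsets)
        for ang, pt in zip(angles, pts):
            entries.append((ang % 360.0, pt))
        sectors.append((min(lo, hi), max(lo, hi)))

    def in_sector(angle):
        for lo, hi in sectors:
            if lo <= angle <= hi or lo <= angle + 360.0 <= hi:
                return True
        return False

    base_angles = np.arange(0.0, 360.0, base_step_deg)
    keep = [a for a in base_angles if not in_sector(a)]
    if keep:
        pts = _rim_points(params, np.array(keep))
        entries.extend(zip([a % 360.0 for a in keep], pts))
    entries.sort(key=lambda e: e[0])
    return np.array([pt for _, pt in entries])


# ---------------------------------------------------------------------------
# rendering


def _noise_field(rng, shape, sigma, amplitude):
    return ndimage.gaussian_filter(rng.uniform(-1.0, 1.0, shape),
                                   sigma) * amplitude


def render(params: CarapaceParams, size: int | None = None) -> AnnotatedImage:
    """Rasterize one carapace; deterministic for given params."""
    size = size or params.image_size
    if size < 64:
        raise ValueError("image size must be at least 64")
    if size != params.image_size:
        raise ValueError("params were built for a different image size")
    params.validate()
    H = W = size
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    bg_rng = np.random.default_rng(params.background_seed)
    bg_base = bg_rng.uniform(75.0, 105.0)
    bg = bg_base + _noise_field(bg_rng, (H, W), 3.0, 18.0)
    ramp = (xx * np.cos(params.illumination_angle)
            + yy * np.sin(params.illumination_angle))
    ramp = (ramp - ramp.mean()) / max(ramp.max() - ramp.min(), 1.0)
    bg = bg + ramp * params.illumination_strength * 80.0

    tx_rng = np.random.default_rng(params.texture_seed)
    shell_base = tx_rng.uniform(155.0, 185.0)
    shell = shell_base + _noise_field(tx_rng, (H, W), 2.0, 12.0)
    shell = shell + ramp * params.illumination_strength * 40.0

    poly = outline_polygon(params)
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(H, W))
    mask = np.zeros((H, W), dtype=bool)
    mask[rr, cc] = True

    gray = np.where(mask, shell, bg)

    # groove: darker polyline through the 7 groove points
    lm = landmarks_from_params(params)
    groove = lm.coords[30:37]
    groove_mask = np.zeros((H, W), dtype=bool)
    gpts = np.round(groove).astype(int)
    for (x0, y0), (x1, y1) in zip(gpts[:-1], gpts[1:]):
        rr, cc = draw_line(int(np.clip(y0, 0, H - 1)),
                           int(np.clip(x0, 0, W - 1)),
                           int(np.clip(y1, 0, H - 1)),
                           int(np.clip(x1, 0, W - 1)))
        groove_mask[rr, cc] = True
    groove_mask = ndimage.binary_dilation(groove_mask, iterations=1)
    gray = np.where(groove_mask & mask, gray * 0.55, gray)

    gray = gray + tx_rng.normal(0.0, 2.5, (H, W))
    tint_bg = np.array([1.06, 1.0, 0.9])
    tint_shell = np.array([0.95, 1.0, 0.78])
    tint = np.where(mask[..., None], tint_shell, tint_bg)
    img = np.clip(gray[..., None] * tint, 0.0, 255.0).astype(np.uint8)
    return AnnotatedImage(image=img, landmarks=lm, params=params)


# ---------------------------------------------------------------------------
# datasets


def default_test_size(n_total: int) -> int:
    """One-tenth split convention (4600 -> 460)."""
    return n_total // 10


def _sample_seed(seed: int, index: int) -> int:
    return int((seed * 1_000_003 + index * 7919 + 17) % (2 ** 31 - 1))


def make_dataset(n: int, seed: int, image_size: int = 128,
                 jitter: JitterConfig | None = None,
                 split: str | None = None) -> list[AnnotatedImage]:
    """Render ``n`` annotated images in memory, seeded per sample."""
    out = []
    for i in range(n):
        params = sample_params(_sample_seed(seed, i), jitter=jitter,
                               image_size=image_size)
        sample = render(params)
        sample.split = split
        out.append(sample)
    return out


def generate_dataset(n_train: int, n_test: int, seed: int, out_dir,
                     image_size: int = 128,
                     jitter: JitterConfig | None = None) -> list[dict]:
    """Write PNG images, annotation JSON and a JSON-lines manifest.

    Returns the manifest records (path, split, seed per sample).
    """
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    manifest = []
    for i in range(n_train + n_test):
        split = "train" if i < n_train else "test"
        sseed = _sample_seed(seed, i)
        params = sample_params(sseed, jitter=jitter, image_size=image_size)
        sample = render(params)
        name = f"carapace_{i:05d}"
        img_path = out_dir / "images" / f"{name}.png"
        ann_path = out_dir / "annotations" / f"{name}.json"
        iio.imwrite(img_path, sample.image)
        write_annotation(ann_path, sample.landmarks, f"{name}.png")
        manifest.append({"image": str(img_path.relative_to(out_dir)),
                         "annotation": str(ann_path.relative_to(out_dir)),
                         "split": split, "seed": sseed})
    with open(out_dir / "manifest.jsonl", "w") as fh:
        for rec in manifest:
            fh.write(json.dumps(rec) + "\n")
    return manifest
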