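"""The 37+2-point carapace annotation schema.

A Chinese mitten crab carapace is annotated with 37 anatomical landmarks:
twelve marginal teeth (four frontal, four on each lateral edge), each
described by a start point, a tooth peak and an end point, with adjacent
teeth sharing their junction point (so each 4-tooth group needs 9 points);
three points on the flat rear edge; and seven points tracing the M-shaped
neck groove.  For coordinate regression the upper-left and lower-right
corners of the crab's bounding rectangle are appended as two extra points,
giving 39 points and a flattened vector of 78 coordinate values.

Canonical ordering: P1-P9 frontal teeth left-to-right, P10-P18 left
lateral edge front-to-rear, P19-P27 right lateral edge front-to-rear,
P28-P30 rear edge left-to-right, P31-P37 groove left-to-right, P38/P39
bounding-box corners.

Coordinate frames
-----------------
``pixel``      0-based continuous coordinates, origin top-left, x along
               columns (rightward), y along rows (downward); the center of
               pixel (row r, col c) is at (x=c, y=r).
``normalized`` both axes mapped to approximately [-1, 1] with the
               pixel-center convention x' = (2(x+1) - (W+1)) / W, so an
               in-frame coordinate lies in [-(W-1)/W, (W-1)/W].  An
               alternative endpoint convention x' = 2x/(W-1) - 1 is
               available via ``convention="endpoint"`` but is not the
               default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LandmarkSchema",
    "LandmarkSet",
    "BoundingBox",
    "build_schema",
    "flatten",
    "unflatten",
    "to_normalized",
    "to_pixel",
    "compute_bbox",
    "write_annotation",
    "read_annotation",
    "N_CARAPACE_POINTS",
    "N_POINTS",
]

N_CARAPACE_POINTS = 37
N_POINTS = 39

GROUPS = ("frontal_teeth", "left_teeth", "right_teeth", "rear_edge",
          "neck_groove", "bbox")


@dataclass(frozen=True)
class SchemaPoint:
    id: int          # 1-based, contiguous
    name: str
    group: str


@dataclass(frozen=True)
class LandmarkSchema:
    points: tuple[SchemaPoint, ...]
    # (group, start_id, peak_id, end_id) per tooth; the sharing rule is
    # end_id(tooth t) == start_id(tooth t+1) within each group.
    teeth: tuple[tuple[str, int, int, int], ...]

    @property
    def n_carapace(self) -> int:
        return sum(1 for p in self.points if p.group != "bbox")

    @property
    def n_total(self) -> int:
        return len(self.points)

    def group_ids(self, group: str) -> list[int]:
        return [p.id for p in self.points if p.group == group]

    def validate(self):
        ids = [p.id for p in self.points]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("schema ids must be unique and contiguous")
        if self.n_carapace != N_CARAPACE_POINTS:
            raise ValueError("schema must have 37 carapace points")
        if self.n_total != N_POINTS:
            raise ValueError("schema must have 39 points including bbox")
        teeth_by_group: dict[str, list] = {}
        for g, s, p, e in self.teeth:
            teeth_by_group.setdefault(g, []).append((s, p, e))
        for g, teeth in teeth_by_group.items():
            for (s0, p0, e0), (s1, p1, e1) in zip(teeth, teeth[1:]):
                if e0 != s1:
                    raise ValueError(
                        f"sharing rule violated in {g}: tooth ending at "
                        f"{e0} followed by tooth starting at {s1}")


def _tooth_group(prefix: str, group: str, first_id: int):
    """Nine points for a 4-tooth group; junctions are single shared points."""
    points, teeth = [], []
    pid = first_id
    names = []
    for t in range(1, 5):
        if t == 1:
            names.append(f"{prefix}_t1_start")
        names.append(f"{prefix}_t{t}_peak")
        if t < 4:
            names.append(f"{prefix}_t{t}{t + 1}_junction")
        else:
            names.append(f"{prefix}_t4_end")
    for name in names:
        points.append(SchemaPoint(pid, name, group))
        pid += 1
    base = first_id
    for t in range(4):
        teeth.append((group, base + 2 * t, base + 2 * t + 1, base + 2 * t + 2))
    return points, teeth


def build_schema() -> LandmarkSchema:
    """The canonical 39-point schema (37 carapace + 2 bbox corners)."""
    points: list[SchemaPoint] = []
    teeth: list[tuple[str, int, int, int]] = []
    for prefix, group, first in (("frontal", "frontal_teeth", 1),
                                 ("left", "left_teeth", 10),
                                 ("right", "right_teeth", 19)):
        p, t = _tooth_group(prefix, group, first)
        points.extend(p)
        teeth.extend(t)
    for i, name in enumerate(("rear_left", "rear_mid", "rear_right")):
        points.append(SchemaPoint(28 + i, name, "rear_edge"))
    for i in range(7):
        points.append(SchemaPoint(31 + i, f"groove_{i + 1}", "neck_groove"))
    points.append(SchemaPoint(38, "bbox_upper_left", "bbox"))
    points.append(SchemaPoint(39, "bbox_lower_right", "bbox"))
    schema = LandmarkSchema(points=tuple(points), teeth=tuple(teeth))
    schema.validate()
    return schema


@dataclass(frozen=True)
class BoundingBox:
    upper_left: tuple[float, float]
    lower_right: tuple[float, float]

    def __post_init__(self):
        if (self.upper_left[0] > self.lower_right[0]
                or self.upper_left[1] > self.lower_right[1]):
            raise ValueError("bounding box corners are not ordered")

    def contains(self, x: float, y: float) -> bool:
        return (self.upper_left[0] <= x <= self.lower_right[0]
                and self.upper_left[1] <= y <= self.lower_right[1])


@dataclass
class LandmarkSet:
    """Ordered named 2-D points in a declared coordinate frame."""

    coords: np.ndarray                      # (n, 2) as (x, y)
    frame: str = "pixel"                    # "pixel" | "normalized"
    width: int | None = None
    height: int | None = None
    valid: np.ndarray | None = None
    schema: LandmarkSchema = field(default_factory=build_schema)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        n = self.coords.shape[0]
        if n not in (N_CARAPACE_POINTS, N_POINTS):
            raise ValueError(f"expected 37 or 39 points, got {n}")
        if self.frame not in ("pixel", "normalized"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.coords.copy(), frame=self.frame,
                           width=self.width, height=self.height,
                           valid=self.valid.copy(), schema=self.schema)

    def with_bbox(self, margin: float = 0.0) -> "LandmarkSet":
        """Append the two bounding-box corner points (pixel frame only)."""
        if self.n_points == N_POINTS:
            return self.copy()
        if self.frame != "pixel":
            raise ValueError("bbox augmentation requires the pixel frame")
        box = compute_bbox(self, margin=margin)
        coords = np.vstack([self.coords,
                            [box.upper_left, box.lower_right]])
        valid = np.concatenate([self.valid, [True, True]])
        return LandmarkSet(coords, frame="pixel", width=self.width,
                           height=self.height, valid=valid,
                           schema=self.schema)


# ---------------------------------------------------------------------------
# flattening


def flatten(landmarks: LandmarkSet) -> np.ndarray:
    """Interleave the 39 points into a length-78 vector (x1,y1,...,x39,y39)."""
    if landmarks.n_points != N_POINTS:
        raise ValueError(
            f"flatten requires the full {N_POINTS}-point set, got "
            f"{landmarks.n_points} (append bbox corners first)")
    return landmarks.coords.reshape(-1).copy()


def unflatten(vector, frame: str = "pixel", width=None, height=None,
              schema: LandmarkSchema | None = None) -> LandmarkSet:
    vector = np.asarray(vector, dtype=np.float64)
    if vector.shape != (2 * N_POINTS,):
        raise ValueError(f"expected a length-{2 * N_POINTS} vector")
    return LandmarkSet(vector.reshape(N_POINTS, 2), frame=frame,
                       width=width, height=height,
                       schema=schema or build_schema())


# ---------------------------------------------------------------------------
# coordinate frames


def _normalize_1d(v, size, convention):
    if convention == "pixel_center":
        return (2.0 * (v + 1.0) - (size + 1.0)) / size
    elif convention == "endpoint":
        return 2.0 * v / (size - 1.0) - 1.0
    raise ValueError(f"unknown convention {convention!r}")


def _denormalize_1d(v, size, convention):
    if convention == "pixel_center":
        return (size * v + size - 1.0) / 2.0
    elif convention == "endpoint":
        return (v + 1.0) * (size - 1.0) / 2.0
    raise ValueError(f"unknown convention {convention!r}")


def to_normalized(landmarks: LandmarkSet, width: int | None = None,
                  height: int | None = None,
                  convention: str = "pixel_center") -> LandmarkSet:
    """Map pixel coordinates to the signed normalized frame."""
    if landmarks.frame != "pixel":
        raise ValueError("landmarks are not in the pixel frame")
    width = width if width is not None else landmarks.width
    height = height if height is not None else landmarks.height
    if not width or not height or width <= 0 or height <= 0:
        raise ValueError("positive width and height are required")
    out = landmarks.copy()
    out.coords[:, 0] = _normalize_1d(landmarks.coords[:, 0], width, convention)
    out.coords[:, 1] = _normalize_1d(landmarks.coords[:, 1], height, convention)
    out.frame = "normalized"
    out.width, out.height = width, height
    return out


def to_pixel(landmarks: LandmarkSet, width: int | None = None,
             height: int | None = None,
             convention: str = "pixel_center") -> LandmarkSet:
    """Inverse of :func:`to_normalized` (exact to machine precision)."""
    if landmarks.frame != "normalized":
        raise ValueError("landmarks are not in the normalized frame")
    width = width if width is not None else landmarks.width
    height = height if height is not None else landmarks.height
    if not width or not height or width <= 0 or height <= 0:
        raise ValueError("positive width and height are required")
    out = landmarks.copy()
    out.coords[:, 0] = _denormalize_1d(landmarks.coords[:, 0], width,
                                       convention)
    out.coords[:, 1] = _denormalize_1d(landmarks.coords[:, 1], height,
                                       convention)
    out.frame = "pixel"
    out.width, out.height = width, height
    return out


def update_validity(landmarks: LandmarkSet) -> LandmarkSet:
    """Recompute in-frame validity flags from coordinates (pixel frame)."""
    if landmarks.frame != "pixel":
        raise ValueError("validity is defined in the pixel frame")
    if not landmarks.width or not landmarks.height:
        raise ValueError("width/height required")
    out = landmarks.copy()
    x, y = out.coords[:, 0], out.coords[:, 1]
    out.valid = ((x >= 0) & (x <= out.width - 1)
                 & (y >= 0) & (y <= out.height - 1))
    return out


# ---------------------------------------------------------------------------
# bounding boxes


def compute_bbox(landmarks: LandmarkSet, margin: float = 0.0) -> BoundingBox:
    """Tight box over the in-frame carapace points, expanded by ``margin``.

    The box is clamped to the image bounds when dimensions are known.
    """
    if landmarks.frame != "pixel":
        raise ValueError("bbox is computed in the pixel frame")
    pts = landmarks.coords[:N_CARAPACE_POINTS]
    val = landmarks.valid[:N_CARAPACE_POINTS]
    if not val.any():
        raise ValueError("no in-frame points to bound")
    pts = pts[val]
    x0, y0 = pts.min(axis=0) - margin
    x1, y1 = pts.max(axis=0) + margin
    if landmarks.width and landmarks.height:
        x0 = max(x0, 0.0)
        y0 = max(y0, 0.0)
        x1 = min(x1, landmarks.width - 1.0)
        y1 = min(y1, landmarks.height - 1.0)
    return BoundingBox((x0, y0), (x1, y1))


# ---------------------------------------------------------------------------
# annotation JSON


def write_annotation(path, landmarks: LandmarkSet, image_name: str):
    """Write one annotation file (pixel frame) for one image."""
    if landmarks.frame != "pixel":
        raise ValueError("annotations are stored in the pixel frame")
    doc = {
        "image": image_name,
        "width": landmarks.width,
        "height": landmarks.height,
        "frame": "pixel",
        "points": [
            {"id": p.id, "name": p.name,
             "x": float(landmarks.coords[i, 0]),
             "y": float(landmarks.coords[i, 1])}
            for i, p in enumerate(landmarks.schema.points)
            if i < landmarks.n_points
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_annotation(path, schema: LandmarkSchema | None = None) -> LandmarkSet:
    """Read an annotation file; missing bbox corners are computed."""
    doc = json.loads(Path(path).read_text())
    schema = schema or build_schema()
    by_id = {p["id"]: (p["x"], p["y"]) for p in doc["points"]}
    n = N_POINTS if 38 in by_id and 39 in by_id else N_CARAPACE_POINTS
    coords = np.array([by_id[i] for i in range(1, N_CARAPACE_POINTS + 1)],
                      dtype=np.float64)
    lm = LandmarkSet(coords, frame="pixel", width=doc["width"],
                     height=doc["height"], schema=schema)
    if n == N_POINTS:
        coords = np.vstack([coords, [by_id[38], by_id[39]]])
        lm = LandmarkSet(coords, frame="pixel", width=doc["width"],
                         height=doc["height"], schema=schema)
    else:
        lm = lm.with_bbox()
    return lm
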