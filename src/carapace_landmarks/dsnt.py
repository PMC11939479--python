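"""Differentiable spatial-to-numerical transform (soft-argmax) core.

Converts per-landmark heatmaps into continuous coordinates by taking the
expectation of signed coordinate grids under the softmax-normalized map:

    X[i, j] = (2j - (n+1)) / n,   Y[i, j] = (2i - (m+1)) / m   (1-based),
    x_k = <Z'_k, X>,              y_k = <Z'_k, Y>,

where Z'_k is the spatial softmax of channel k and <.,.> is the Frobenius
inner product.  The transform is exact for symmetric unimodal maps, fully
differentiable, and its outputs lie strictly inside (-1, 1).

Also provided: the Jensen-Shannon heatmap regularizer that pulls each
normalized map toward a Gaussian centered on the target point, Gaussian
target-heatmap rendering for dense heatmap regression, and hard argmax
decoding.

All functions accept either numpy arrays or autodiff ``Tensor`` inputs;
Tensor inputs stay in the differentiation graph.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "CoordinateGrids",
    "build_grids",
    "normalize_heatmaps",
    "dsnt_expectation",
    "target_distribution",
    "dsnt_regularizer",
    "render_target_heatmaps",
    "decode_argmax",
]

_EPS = 1e-12


class CoordinateGrids:
    """The signed X and Y reference-axis matrices, shape (m, n) each."""

    def __init__(self, X: np.ndarray, Y: np.ndarray):
        self.X = X
        self.Y = Y

    @property
    def shape(self):
        return self.X.shape


def build_grids(m: int, n: int) -> CoordinateGrids:
    """X[i,j] = (2j-(n+1))/n and Y[i,j] = (2i-(m+1))/m with 1-based i, j."""
    if m < 1 or n < 1:
        raise ValueError("grid dimensions must be positive")
    j = np.arange(1, n + 1, dtype=np.float64)
    i = np.arange(1, m + 1, dtype=np.float64)
    x_axis = (2.0 * j - (n + 1)) / n
    y_axis = (2.0 * i - (m + 1)) / m
    X = np.broadcast_to(x_axis, (m, n)).copy()
    Y = np.broadcast_to(y_axis[:, None], (m, n)).copy()
    return CoordinateGrids(X, Y)


def normalize_heatmaps(Z):
    """Per-channel spatial softmax over the trailing two axes.

    Input shape (..., m, n); each (m, n) slice of the output is positive
    and sums to one.  Invariant to per-channel additive shifts.
    """
    if isinstance(Z, Tensor):
        shift = float(Z.data.max())
        e = (Z - shift).exp()
        denom = e.sum(axis=(-2, -1), keepdims=True)
        return e / denom
    Z = np.asarray(Z, dtype=np.float64)
    e = np.exp(Z - Z.max(axis=(-2, -1), keepdims=True))
    return e / e.sum(axis=(-2, -1), keepdims=True)


def dsnt_expectation(Zn, grids: CoordinateGrids):
    """Coordinate expectations x_k = <Z'_k, X>, y_k = <Z'_k, Y>.

    ``Zn`` has shape (..., m, n) of normalized heatmaps; returns an array
    (or Tensor) of shape (..., 2) ordered (x, y).
    """
    X, Y = grids.X, grids.Y
    if isinstance(Zn, Tensor):
        if Zn.shape[-2:] != X.shape:
            raise ValueError("heatmap and grid shapes differ")
        x = (Zn * X).sum(axis=(-2, -1))
        y = (Zn * Y).sum(axis=(-2, -1))
        nshape = x.shape + (1,)
        from .autodiff import concat
        return concat([x.reshape(nshape), y.reshape(nshape)], axis=-1)
    Zn = np.asarray(Zn, dtype=np.float64)
    if Zn.shape[-2:] != X.shape:
        raise ValueError("heatmap and grid shapes differ")
    x = (Zn * X).sum(axis=(-2, -1))
    y = (Zn * Y).sum(axis=(-2, -1))
    return np.stack([x, y], axis=-1)


def target_distribution(target_xy: np.ndarray, grids: CoordinateGrids,
                        sigma_t: float = 1.0) -> np.ndarray:
    """Unit-mass Gaussians on the grid centered at normalized targets.

    ``sigma_t`` is in grid cells.  ``target_xy``: (..., 2) normalized
    coordinates; returns (..., m, n) distributions summing to one.
    """
    if sigma_t <= 0:
        raise ValueError("sigma_t must be positive")
    m, n = grids.shape
    target_xy = np.asarray(target_xy, dtype=np.float64)
    # continuous 0-based grid indices of the target
    jj = (n * target_xy[..., 0] + n - 1.0) / 2.0
    ii = (m * target_xy[..., 1] + m - 1.0) / 2.0
    rows = np.arange(m, dtype=np.float64)
    cols = np.arange(n, dtype=np.float64)
    d2 = ((rows[:, None] - ii[..., None, None]) ** 2
          + (cols[None, :] - jj[..., None, None]) ** 2)
    g = np.exp(-d2 / (2.0 * sigma_t ** 2))
    return g / g.sum(axis=(-2, -1), keepdims=True)


def _js_divergence(P, Q: np.ndarray):
    """Jensen-Shannon divergence; P may be a Tensor, Q is constant."""
    if isinstance(P, Tensor):
        from .autodiff import where  # noqa: F401  (not needed; logs clamped)
        M = (P + Q) * 0.5
        logM = (M + _EPS).log()
        kl_pm = (P * ((P + _EPS).log() - logM)).sum(axis=(-2, -1))
        logQ = np.log(Q + _EPS)
        kl_qm = ((logQ - logM) * Q).sum(axis=(-2, -1))
        return (kl_pm + kl_qm) * 0.5
    P = np.asarray(P, dtype=np.float64)
    M = 0.5 * (P + Q)
    kl_pm = np.sum(P * (np.log(P + _EPS) - np.log(M + _EPS)), axis=(-2, -1))
    kl_qm = np.sum(Q * (np.log(Q + _EPS) - np.log(M + _EPS)), axis=(-2, -1))
    return 0.5 * (kl_pm + kl_qm)


def dsnt_regularizer(Zn, target_xy, grids: CoordinateGrids,
                     sigma_t: float = 1.0):
    """Mean Jensen-Shannon divergence between heatmaps and target Gaussians.

    Zero iff each normalized map coincides with the unit-mass Gaussian of
    std ``sigma_t`` (grid cells) centered on its target; bounded by ln 2
    per channel.
    """
    Q = target_distribution(target_xy, grids, sigma_t=sigma_t)
    js = _js_divergence(Zn, Q)
    if isinstance(js, Tensor):
        return js.mean()
    return float(np.mean(js))


def render_target_heatmaps(landmarks_xy: np.ndarray, sigma_px: float,
                           height: int, width: int,
                           valid: np.ndarray | None = None) -> np.ndarray:
    """Unnormalized Gaussian targets with peak value 1 at each landmark.

    ``landmarks_xy``: (..., n_points, 2) pixel coordinates (x, y).
    Landmarks outside the frame (or flagged invalid) yield all-zero
    channels.  Returns (..., n_points, height, width) float32.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    pts = np.asarray(landmarks_xy, dtype=np.float64)
    rows = np.arange(height, dtype=np.float64)
    cols = np.arange(width, dtype=np.float64)
    x = pts[..., 0][..., None, None]
    y = pts[..., 1][..., None, None]
    d2 = (rows[:, None] - y) ** 2 + (cols[None, :] - x) ** 2
    hm = np.exp(-d2 / (2.0 * sigma_px ** 2))
    in_frame = ((pts[..., 0] >= 0) & (pts[..., 0] <= width - 1)
                & (pts[..., 1] >= 0) & (pts[..., 1] <= height - 1))
    if valid is not None:
        in_frame = in_frame & np.asarray(valid, dtype=bool)
    hm = hm * in_frame[..., None, None]
    return hm.astype(np.float32)


def decode_argmax(Z: np.ndarray) -> np.ndarray:
    """Hard argmax decoding of (..., m, n) heatmaps to pixel (x, y).

    Ties break to the first occurrence in row-major order, so a constant
    channel decodes to (0, 0).
    """
    Z = np.asarray(Z)
    if Z.shape[-1] == 0 or Z.shape[-2] == 0:
        raise ValueError("empty heatmap")
    m, n = Z.shape[-2:]
    flat = Z.reshape(Z.shape[:-2] + (m * n,))
    idx = flat.argmax(axis=-1)
    rows, cols = np.divmod(idx, n)
    return np.stack([cols, rows], axis=-1).astype(np.float64)
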