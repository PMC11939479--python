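"""Training losses and evaluation metrics for coordinate regression.

Losses: L1, Smooth L1 (quadratic below the transition beta, linear minus
beta/2 beyond), Wing (logarithmic within the width w, L1 minus a constant
beyond) and the DSNT combined loss (coordinate MSE plus the
Jensen-Shannon heatmap regularizer).

Metrics: MAE, MSE and the pooled coefficient of determination R^2, all in
the normalized coordinate frame so the three heads are comparable.  The
R^2 pooling convention is a single ratio of residual to total sum of
squares over all samples, points and both axes.

All losses accept numpy arrays or autodiff Tensors; Tensor inputs stay
differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, where as t_where
from .dsnt import CoordinateGrids, dsnt_regularizer

__all__ = [
    "LossConfig",
    "l1_loss",
    "smooth_l1_loss",
    "wing_loss",
    "mse_loss",
    "dsnt_combined_loss",
    "r_squared",
    "mae_mse_metrics",
    "make_loss",
]

# Wing defaults: the customary pixel-space width 10 and curvature 2 from
# landmark-regression practice, rescaled to the normalized frame of a
# 256-px face crop (the convention the parameters were designed for).
WING_W_DEFAULT = 10.0 / 256.0
WING_EPS_DEFAULT = 2.0 / 256.0


@dataclass
class LossConfig:
    kind: str = "l1"                 # l1 | smooth_l1 | wing | dsnt_combined
    wing_w: float = WING_W_DEFAULT
    wing_eps: float = WING_EPS_DEFAULT
    smooth_beta: float = 1.0
    dsnt_lambda: float = 1.0
    dsnt_sigma_t: float = 1.0

    def validate(self):
        if self.kind not in ("l1", "smooth_l1", "wing", "dsnt_combined"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        for v in (self.wing_w, self.wing_eps, self.smooth_beta,
                  self.dsnt_sigma_t):
            if v <= 0:
                raise ValueError("loss parameters must be positive")
        if self.dsnt_lambda < 0:
            raise ValueError("dsnt_lambda must be non-negative")


def _check_same_length(pred, target):
    ps = pred.shape if not isinstance(pred, Tensor) else pred.data.shape
    ts = np.asarray(target).shape if not isinstance(target, Tensor) \
        else target.data.shape
    if ps != ts:
        raise ValueError(f"prediction shape {ps} != target shape {ts}")


def _diff(pred, target):
    _check_same_length(pred, target)
    if isinstance(pred, Tensor) or isinstance(target, Tensor):
        return pred - target if isinstance(pred, Tensor) \
            else Tensor(np.asarray(pred)) - target
    return np.asarray(pred, dtype=np.float64) - np.asarray(
        target, dtype=np.float64)


def l1_loss(pred, target):
    """Mean absolute difference."""
    d = _diff(pred, target)
    if isinstance(d, Tensor):
        return d.abs().mean()
    return float(np.mean(np.abs(d)))


def mse_loss(pred, target):
    """Mean squared difference (the Euclidean loss of the DSNT head)."""
    d = _diff(pred, target)
    if isinstance(d, Tensor):
        return (d * d).mean()
    return float(np.mean(d ** 2))


def smooth_l1_loss(pred, target, beta: float = 1.0):
    """0.5 d^2 / beta for |d| < beta, |d| - beta/2 beyond; both branches
    meet at beta/2 so the loss is C1-continuous."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    d = _diff(pred, target)
    if isinstance(d, Tensor):
        a = d.abs()
        quad = (d * d) * (0.5 / beta)
        lin = a - 0.5 * beta
        return t_where(a.data < beta, quad, lin).mean()
    a = np.abs(d)
    return float(np.mean(np.where(a < beta, 0.5 * a ** 2 / beta,
                                  a - 0.5 * beta)))


def wing_loss(pred, target, w: float = WING_W_DEFAULT,
              eps: float = WING_EPS_DEFAULT):
    """w*ln(1+|d|/eps) for |d| < w, |d| - C beyond, C = w - w*ln(1+w/eps).

    Logarithmic near zero (amplifying small and medium errors) and exactly
    L1 minus a constant in the linear regime.
    """
    if w <= 0 or eps <= 0:
        raise ValueError("wing parameters must be positive")
    C = w - w * np.log1p(w / eps)
    d = _diff(pred, target)
    if isinstance(d, Tensor):
        a = d.abs()
        log_branch = ((a * (1.0 / eps)) + 1.0).log() * w
        lin_branch = a - C
        return t_where(a.data < w, log_branch, lin_branch).mean()
    a = np.abs(d)
    return float(np.mean(np.where(a < w, w * np.log1p(a / eps), a - C)))


def dsnt_combined_loss(pred_coords, target_coords, normalized_heatmaps,
                       grids: CoordinateGrids,
                       config: LossConfig | None = None):
    """Coordinate MSE plus lambda times the JS heatmap regularizer."""
    config = config or LossConfig(kind="dsnt_combined")
    if normalized_heatmaps is None:
        raise ValueError("dsnt_combined_loss requires the normalized "
                         "heatmaps alongside the coordinates")
    euc = mse_loss(pred_coords, target_coords)
    target = (target_coords.data if isinstance(target_coords, Tensor)
              else np.asarray(target_coords, dtype=np.float64))
    reg = dsnt_regularizer(normalized_heatmaps, target, grids,
                           sigma_t=config.dsnt_sigma_t)
    if isinstance(euc, Tensor) or isinstance(reg, Tensor):
        return euc + reg * config.dsnt_lambda
    return float(euc + config.dsnt_lambda * reg)


def make_loss(config: LossConfig):
    """Coordinate-space loss closure for a config (dsnt handled separately)."""
    config.validate()
    if config.kind == "l1":
        return l1_loss
    if config.kind == "smooth_l1":
        return lambda p, t: smooth_l1_loss(p, t, beta=config.smooth_beta)
    if config.kind == "wing":
        return lambda p, t: wing_loss(p, t, w=config.wing_w,
                                      eps=config.wing_eps)
    raise ValueError("dsnt_combined loss needs heatmaps; use "
                     "dsnt_combined_loss directly")


# ---------------------------------------------------------------------------
# metrics (numpy only)


def r_squared(pred, target) -> float:
    """Pooled coefficient of determination over all coordinate values.

    R^2 = 1 - sum (t - p)^2 / sum (t - mean(t))^2, pooled over samples,
    points and both axes; at most 1, negative when predictions are worse
    than the target mean.
    """
    pred = np.asarray(pred, dtype=np.float64).ravel()
    target = np.asarray(target, dtype=np.float64).ravel()
    if pred.shape != target.shape:
        raise ValueError("prediction and target sizes differ")
    if target.size < 2:
        raise ValueError("need at least two values")
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("target variance is zero; R^2 undefined")
    ss_res = float(np.sum((target - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def mae_mse_metrics(pred, target) -> tuple[float, float]:
    """(MAE, MSE) over all coordinate values in the normalized frame."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    target = np.asarray(target, dtype=np.float64).ravel()
    if pred.shape != target.shape:
        raise ValueError("prediction and target sizes differ")
    d = pred - target
    return float(np.mean(np.abs(d))), float(np.mean(d ** 2))
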