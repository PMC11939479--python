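"""Scikit-learn-style estimators for the three landmark-regression heads.

Each estimator wraps one network (fully-connected, Gaussian-heatmap or
DSNT), a loss and a seeded Adam training loop behind the standard
``fit`` / ``predict`` / ``score`` interface, so the models compose with
sklearn model selection and pipelines.

Input conventions
-----------------
X : uint8 or float array (n, H, W, 3), square RGB images.
y : float array (n, n_points, 2), landmark coordinates in the signed
    normalized frame (pixel-center convention, ~[-1, 1]).

``predict`` always returns normalized coordinates of shape
(n, n_points, 2); ``score`` is the pooled coefficient of determination
over all coordinate values.

Training stops early when the mean epoch training loss drops below
``convergence_threshold`` (the threshold applies to the head's own
training-loss scale: coordinate loss for FC/DSNT, pixelwise heatmap loss
for HM).
"""

from __future__ import annotations

import ctypes
import gc
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

from . import dsnt as dsnt_ops
from .autodiff import Tensor
from .losses import LossConfig, dsnt_combined_loss, make_loss, \
    mae_mse_metrics, r_squared
from .networks import build_network, full_network_spec, tiny_network_spec
from .nn import Adam

__all__ = [
    "TrainingTrace",
    "FCLandmarkRegressor",
    "HeatmapLandmarkRegressor",
    "DSNTLandmarkRegressor",
]


@dataclass
class TrainingTrace:
    """Per-epoch training history."""

    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_mae: list[float] = field(default_factory=list)
    train_mse: list[float] = field(default_factory=list)
    train_r2: list[float] = field(default_factory=list)
    test_mae: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)
    test_r2: list[float] = field(default_factory=list)
    converged: bool = False
    converged_epoch: int | None = None

    def __len__(self):
        return len(self.epoch)


def _release_memory():
    """Collect graph cycles and return freed arenas to the OS.

    Backward graphs hold large temporaries in reference cycles; glibc keeps
    the freed blocks in-process otherwise, which inflates resident memory
    over long training runs on small machines.
    """
    gc.collect()
    try:
        ctypes.CDLL("libc.so.6").malloc_trim(0)
    except OSError:  # non-glibc platforms
        pass


def _prepare_images(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 4 or X.shape[-1] != 3 or X.shape[1] != X.shape[2]:
        raise ValueError("X must be (n, S, S, 3) square RGB images")
    X = X.astype(np.float32) / 255.0 if X.dtype == np.uint8 \
        else X.astype(np.float32)
    return np.ascontiguousarray(((X - 0.5) * 2.0).transpose(0, 3, 1, 2))


def _norm_to_pixel(coords: np.ndarray, size: int) -> np.ndarray:
    return (size * coords + size - 1.0) / 2.0


def _pixel_to_norm(coords: np.ndarray, size: int) -> np.ndarray:
    return (2.0 * coords + 1.0 - size) / size


class _BaseLandmarkRegressor(BaseEstimator, RegressorMixin):
    _head: str = ""

    def __init__(self, image_size=48, n_points=39, preset="tiny", epochs=30,
                 batch_size=16, learning_rate=1e-3,
                 convergence_threshold=1e-3, loss="l1",
                 wing_w=10.0 / 256.0, wing_eps=2.0 / 256.0, smooth_beta=1.0,
                 random_state=0):
        self.image_size = image_size
        self.n_points = n_points
        self.preset = preset
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.convergence_threshold = convergence_threshold
        self.loss = loss
        self.wing_w = wing_w
        self.wing_eps = wing_eps
        self.smooth_beta = smooth_beta
        self.random_state = random_state

    # -- head hooks ----------------------------------------------------------
    def _batch_loss(self, net, xb, yb):
        """Return (loss Tensor, decoded normalized coords (n, p, 2))."""
        raise NotImplementedError

    def _predict_batch(self, net, xb) -> np.ndarray:
        raise NotImplementedError

    # -- sklearn API ---------------------------------------------------------
    def _loss_config(self) -> LossConfig:
        cfg = LossConfig(kind=self.loss, wing_w=self.wing_w,
                         wing_eps=self.wing_eps,
                         smooth_beta=self.smooth_beta)
        cfg.validate()
        return cfg

    def _make_spec(self):
        if self.preset == "tiny":
            return tiny_network_spec(self._head, image_size=self.image_size,
                                     n_points=self.n_points)
        if self.preset == "full":
            spec = full_network_spec(self._head, n_points=self.n_points)
            if self.image_size != spec.image_size:
                raise ValueError("the full preset runs at 512x512 input")
            return spec
        raise ValueError(f"unknown preset {self.preset!r}")

    def fit(self, X, y, eval_set=None):
        """Train the network; optionally track metrics on ``eval_set``.

        eval_set : optional (X_test, y_test) pair evaluated once per epoch
        (in eval mode) and recorded in ``trace_``.
        """
        X = _prepare_images(X)
        y = np.asarray(y, dtype=np.float64)
        if y.shape != (X.shape[0], self.n_points, 2):
            raise ValueError(
                f"y must be (n, {self.n_points}, 2) normalized coordinates")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if X.shape[2] != self.image_size:
            raise ValueError("images do not match image_size")
        spec = self._make_spec()
        net = build_network(spec, seed=self.random_state)
        opt = Adam(net.parameters(), lr=self.learning_rate)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.random_state, 0xA57]))
        trace = TrainingTrace()
        n = X.shape[0]
        bs = min(self.batch_size, n)
        for epoch in range(1, self.epochs + 1):
            net.train()
            order = rng.permutation(n)
            losses, preds, targets = [], [], []
            for start in range(0, n - bs + 1, bs):
                idx = order[start:start + bs]
                xb = Tensor(X[idx])
                yb = y[idx]
                loss, coords = self._batch_loss(net, xb, yb)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
                preds.append(coords)
                targets.append(yb)
            mean_loss = float(np.mean(losses))
            p = np.concatenate(preds)
            t = np.concatenate(targets)
            mae, mse = mae_mse_metrics(p, t)
            trace.epoch.append(epoch)
            trace.train_loss.append(mean_loss)
            trace.train_mae.append(mae)
            trace.train_mse.append(mse)
            trace.train_r2.append(r_squared(p, t))
            if not np.isfinite(mean_loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} "
                    f"(loss={mean_loss}); lower the learning rate")
            if eval_set is not None:
                pe = self._predict_arrays(net, _prepare_images(eval_set[0]))
                te = np.asarray(eval_set[1], dtype=np.float64)
                emae, emse = mae_mse_metrics(pe, te)
                trace.test_mae.append(emae)
                trace.test_mse.append(emse)
                trace.test_r2.append(r_squared(pe, te))
            _release_memory()
            if mean_loss < self.convergence_threshold:
                trace.converged = True
                trace.converged_epoch = epoch
                break
        self.spec_ = spec
        self.model_ = net
        self.trace_ = trace
        self.n_epochs_ = len(trace)
        self.converged_ = trace.converged
        return self

    def _predict_arrays(self, net, X: np.ndarray) -> np.ndarray:
        net.eval()
        out = []
        bs = max(self.batch_size, 1)
        for start in range(0, X.shape[0], bs):
            out.append(self._predict_batch(net, Tensor(X[start:start + bs])))
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise NotFittedError("call fit before predict")
        return self._predict_arrays(self.model_, _prepare_images(X))

    def score(self, X, y) -> float:
        """Pooled R^2 over all coordinate values."""
        return r_squared(self.predict(X), np.asarray(y, dtype=np.float64))

    # -- persistence ---------------------------------------------------------
    def save(self, path):
        """Serialize the fitted model (weights, BN buffers, constructor
        params) to a single ``.npz`` file."""
        import json

        if not hasattr(self, "model_"):
            raise NotFittedError("call fit before save")
        meta = {"class": type(self).__name__, "params": self.get_params()}
        np.savez(path, __meta__=np.array(json.dumps(meta)),
                 **self.model_.state_arrays())

    @staticmethod
    def load(path):
        """Rebuild a fitted estimator saved with :meth:`save`."""
        import json

        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        classes = {c.__name__: c for c in (FCLandmarkRegressor,
                                           HeatmapLandmarkRegressor,
                                           DSNTLandmarkRegressor)}
        est = classes[meta["class"]](**meta["params"])
        spec = est._make_spec()
        net = build_network(spec, seed=est.random_state)
        net.load_state_arrays({k: data[k] for k in data.files
                               if k != "__meta__"})
        net.eval()
        est.spec_ = spec
        est.model_ = net
        est.n_epochs_ = 0
        est.converged_ = False
        return est

    def predict_confidence(self, X) -> np.ndarray | None:
        """Per-point confidence in [0, 1], or None for the FC head.

        HM: peak value of each predicted heatmap (targets peak at 1),
        clipped to [0, 1].  DSNT: peak of the softmax-normalized map.
        """
        return None


class FCLandmarkRegressor(_BaseLandmarkRegressor):
    """Fully-connected coordinate regression (GDConv + FC head).

    Fast and end-to-end differentiable, but the FC stage ties features to
    absolute spatial positions, which limits generalization to poses not
    seen in training.
    """

    _head = "fc"

    def _batch_loss(self, net, xb, yb):
        out = net(xb)                                  # (n, 2p)
        target = yb.reshape(yb.shape[0], -1)
        loss = make_loss(self._loss_config())(out, target)
        coords = out.data.reshape(yb.shape).astype(np.float64)
        return loss, coords

    def _predict_batch(self, net, xb):
        out = net(xb).data
        return out.reshape(out.shape[0], self.n_points, 2).astype(np.float64)


class HeatmapLandmarkRegressor(_BaseLandmarkRegressor):
    """Gaussian-heatmap regression with hard argmax decoding.

    Trains the decoder to reproduce per-landmark Gaussian target maps
    (pixelwise loss); decoding quantizes to the pixel grid, so accuracy at
    low resolution is bounded by the argmax step.
    """

    _head = "hm"

    def __init__(self, image_size=48, n_points=39, preset="tiny", epochs=30,
                 batch_size=16, learning_rate=1e-3,
                 convergence_threshold=1e-3, loss="l1",
                 wing_w=10.0 / 256.0, wing_eps=2.0 / 256.0, smooth_beta=1.0,
                 random_state=0, sigma_px=None):
        super().__init__(image_size=image_size, n_points=n_points,
                         preset=preset, epochs=epochs, batch_size=batch_size,
                         learning_rate=learning_rate,
                         convergence_threshold=convergence_threshold,
                         loss=loss, wing_w=wing_w, wing_eps=wing_eps,
                         smooth_beta=smooth_beta, random_state=random_state)
        self.sigma_px = sigma_px

    def _sigma(self) -> float:
        # 7 px at the 512 working resolution, scaled proportionally
        return self.sigma_px if self.sigma_px is not None \
            else 7.0 * self.image_size / 512.0

    def _batch_loss(self, net, xb, yb):
        raw = net(xb)                                  # (n, p, H, W)
        s = self.image_size
        pix = _norm_to_pixel(yb, s)
        targets = dsnt_ops.render_target_heatmaps(pix, self._sigma(), s, s)
        loss = make_loss(self._loss_config())(raw, targets)
        coords = _pixel_to_norm(dsnt_ops.decode_argmax(raw.data), s)
        return loss, coords

    def _predict_batch(self, net, xb):
        raw = net(xb).data
        return _pixel_to_norm(dsnt_ops.decode_argmax(raw), self.image_size)

    def predict_heatmaps(self, X) -> np.ndarray:
        """Raw heatmap stacks (n, p, H, W) for inspection/confidence."""
        if not hasattr(self, "model_"):
            raise NotFittedError("call fit before predict")
        self.model_.eval()
        return self.model_(Tensor(_prepare_images(X))).data

    def predict_confidence(self, X) -> np.ndarray:
        return np.clip(self.predict_heatmaps(X).max(axis=(-2, -1)), 0.0, 1.0)


class DSNTLandmarkRegressor(_BaseLandmarkRegressor):
    """Coordinate regression through the differentiable spatial-to-numerical
    transform: spatial softmax over a low-resolution landmark map followed
    by a coordinate expectation, trained with MSE plus a Jensen-Shannon
    heatmap regularizer.  Fully differentiable and quantization-free."""

    _head = "dsnt"

    def __init__(self, image_size=48, n_points=39, preset="tiny", epochs=30,
                 batch_size=16, learning_rate=1e-3,
                 convergence_threshold=1e-3, loss="dsnt_combined",
                 wing_w=10.0 / 256.0, wing_eps=2.0 / 256.0, smooth_beta=1.0,
                 random_state=0, dsnt_lambda=1.0, dsnt_sigma_t=1.0):
        super().__init__(image_size=image_size, n_points=n_points,
                         preset=preset, epochs=epochs, batch_size=batch_size,
                         learning_rate=learning_rate,
                         convergence_threshold=convergence_threshold,
                         loss=loss, wing_w=wing_w, wing_eps=wing_eps,
                         smooth_beta=smooth_beta, random_state=random_state)
        self.dsnt_lambda = dsnt_lambda
        self.dsnt_sigma_t = dsnt_sigma_t

    def _batch_loss(self, net, xb, yb):
        coords, zn = net.forward_coords(xb)            # (n, p, 2), (n, p, m, n)
        if self.loss == "dsnt_combined":
            cfg = LossConfig(kind="dsnt_combined",
                             dsnt_lambda=self.dsnt_lambda,
                             dsnt_sigma_t=self.dsnt_sigma_t)
            fs = zn.shape[-1]
            grids = dsnt_ops.build_grids(fs, fs)
            loss = dsnt_combined_loss(coords, Tensor(yb), zn, grids,
                                      config=cfg)
        else:
            loss = make_loss(self._loss_config())(coords, Tensor(yb))
        return loss, coords.data.astype(np.float64)

    def _predict_batch(self, net, xb):
        coords, _ = net.forward_coords(xb)
        return coords.data.astype(np.float64)

    def predict_heatmaps(self, X) -> np.ndarray:
        """Normalized heatmap stacks (n, p, m, n)."""
        if not hasattr(self, "model_"):
            raise NotFittedError("call fit before predict")
        self.model_.eval()
        _, zn = self.model_.forward_coords(Tensor(_prepare_images(X)))
        return zn.data

    def predict_confidence(self, X) -> np.ndarray:
        return self.predict_heatmaps(X).max(axis=(-2, -1))
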