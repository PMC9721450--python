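"""Reduced-scale convolutional classifier with class-activation maps.

A deliberately small conv net (three 3x3 conv/ReLU/max-pool blocks,
global average pooling, one linear output with sigmoid) implemented
directly in numpy, trained with the same loop contract as a full-scale
network: binary cross-entropy loss, SGD with momentum 0.9 and weight
decay, random horizontal/vertical flip augmentation, and a
reduce-on-plateau learning-rate schedule (factor 0.1 after a 10-epoch
loss plateau). Global average pooling makes the class-activation map
exact: CAM = classifier-weight-weighted sum of the final convolutional
feature maps, upsampled to the input size and min-max normalised to
[0, 1].

Inputs are region-masked crops: pixels outside the region of interest
are zeroed, the crop is resized to ``input_size`` and normalised to
mean 0 / sd 1 (see :func:`region_crop`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["CNNConfig", "TinyCNNClassifier", "region_crop",
           "cnn_train", "cnn_cam"]


@dataclass(frozen=True)
class CNNConfig:
    """Training hyper-parameters.

    Defaults mirror a standard full-scale recipe (256 px inputs,
    lr 0.001, batch 64, 100 epochs); :meth:`tiny` returns the
    desk-scale preset used throughout the tests — 64 px inputs and a
    larger lr suited to the small net trained from scratch — with the
    identical loop contract.
    """

    input_size: int = 256
    architecture: str = "tiny"
    pretrained: bool = False
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-5
    lr_drop_factor: float = 0.1
    plateau_epochs: int = 10
    epochs: int = 100
    batch_size: int = 64
    augment_flips: bool = True
    seed: int = 0
    channels: tuple[int, ...] = (8, 16, 32)
    head_lr_scale: float = 1.0  # per-layer lr multiplier for the linear head

    def __post_init__(self) -> None:
        for name in ("input_size", "lr", "momentum", "lr_drop_factor",
                     "plateau_epochs", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.architecture != "tiny":
            raise NotImplementedError(
                "only the reduced 'tiny' architecture is implemented; a "
                "full residual network is a documented configuration, not "
                "a supported one")

    @classmethod
    def tiny(cls, **overrides) -> "CNNConfig":
        base = cls(input_size=64, lr=0.02, batch_size=4,
                   channels=(16, 32, 128))
        return replace(base, **overrides) if overrides else base


def region_crop(pixels, region_mask, input_size: int = 64,
                return_support: bool = False):
    """Region-masked, resized, standardised crop for the CNN.

    Pixels outside the region are zeroed, the square bounding box of
    the region (plus a 2 px margin) is cropped, resized to
    ``input_size`` with bilinear interpolation, and standardised to
    mean 0 / sd 1. With ``return_support=True`` also returns the
    region support mapped through the same geometry (nearest-
    neighbour), e.g. for comparing activation maps inside vs outside
    the region.
    """
    pixels = np.asarray(pixels, dtype=float)
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("region mask is empty")
    x = np.where(mask, pixels, 0.0)
    rr, cc = np.nonzero(mask)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    # square box centred on the region
    side = max(r1 - r0, c1 - c0) + 4
    rc, cc_ = (r0 + r1) // 2, (c0 + c1) // 2
    half = side // 2
    box = np.zeros((side, side))
    sup = np.zeros((side, side))
    rs, re = max(rc - half, 0), min(rc - half + side, pixels.shape[0])
    cs, ce = max(cc_ - half, 0), min(cc_ - half + side, pixels.shape[1])
    box[:re - rs, :ce - cs] = x[rs:re, cs:ce]
    sup[:re - rs, :ce - cs] = mask[rs:re, cs:ce]

    def resize(arr, order):
        out = ndimage.zoom(arr, input_size / side, order=order,
                           grid_mode=True, mode="grid-constant")
        return out[:input_size, :input_size]

    crop = resize(box, order=1)
    sd = crop.std()
    crop = (crop - crop.mean()) / (sd if sd > 0 else 1.0)
    if return_support:
        return crop, resize(sup, order=0) > 0.5
    return crop


# ---------------------------------------------------------------------------
# numpy layers
# ---------------------------------------------------------------------------

def _conv_forward(x, w, b):
    """3x3 same-padding convolution. x: (N,C,H,W); w: (F,C,3,3)."""
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # N,C,H,W,3,3
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, wd, -1)
    out = cols @ w.reshape(w.shape[0], -1).T + b
    return out.transpose(0, 3, 1, 2), cols


def _conv_backward(dout, cols, w, x_shape):
    n, c, h, wd = x_shape
    f = w.shape[0]
    dflat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
    colsf = cols.reshape(-1, w.reshape(f, -1).shape[1])
    dw = (dflat.T @ colsf).reshape(w.shape)
    db = dflat.sum(axis=0)
    dcols = (dflat @ w.reshape(f, -1)).reshape(n, h, wd, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, wd + 2))
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di:di + h, dj:dj + wd] += \
                dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _pool_forward(x):
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dout, idx, x_shape):
    n, c, h, w = x_shape
    dr = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dr.reshape(n, c, h, w)


class TinyCNNClassifier(ClassifierMixin, BaseEstimator):
    """Small numpy CNN for region-masked lesion crops.

    ``fit(X, y)`` expects ``X`` of shape (N, H, W) with H = W =
    ``config.input_size``. Deterministic for a fixed config seed.
    """

    def __init__(self, config: CNNConfig | None = None):
        self.config = config

    def _init_params(self, rng):
        cfg = self.config
        chans = (1,) + tuple(cfg.channels)
        self.weights_ = []
        self.biases_ = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            fan_in = cin * 9
            self.weights_.append(
                rng.normal(0, np.sqrt(2.0 / fan_in), (cout, cin, 3, 3)))
            self.biases_.append(np.zeros(cout))
        self.fc_w_ = rng.normal(0, np.sqrt(1.0 / chans[-1]), chans[-1])
        self.fc_b_ = 0.0
        # running statistics of the batch-normalised GAP features
        self.bn_mean_ = np.zeros(chans[-1])
        self.bn_var_ = np.ones(chans[-1])

    _BN_EPS = 1e-5
    _BN_MOMENTUM = 0.1

    def _forward(self, x, keep_maps=False, batch_stats=False):
        caches = []
        h = x[:, None, :, :]
        for w, b in zip(self.weights_, self.biases_):
            out, cols = _conv_forward(h, w, b)
            relu = np.where(out > 0, 1.0, 0.01)  # leaky: avoids dead units
            out = out * relu
            # downsample until the maps reach 8x8, then keep resolution
            if out.shape[2] > 8:
                pooled, idx = _pool_forward(out)
            else:
                pooled, idx = out, None
            caches.append((h.shape, cols, relu, idx, out.shape))
            h = pooled
        gap = h.mean(axis=(2, 3))
        # batch norm on the GAP features: conditions the linear head
        if batch_stats and gap.shape[0] > 1:
            mu, var = gap.mean(axis=0), gap.var(axis=0)
            self.bn_mean_ = ((1 - self._BN_MOMENTUM) * self.bn_mean_
                             + self._BN_MOMENTUM * mu)
            self.bn_var_ = ((1 - self._BN_MOMENTUM) * self.bn_var_
                            + self._BN_MOMENTUM * var)
        else:
            mu, var = self.bn_mean_, self.bn_var_
        xhat = (gap - mu) / np.sqrt(var + self._BN_EPS)
        logit = xhat @ self.fc_w_ + self.fc_b_
        if keep_maps:
            return logit, h
        return logit, xhat, var, h, caches

    def _train_step(self, x, y, state, lr):
        cfg = self.config
        n = x.shape[0]
        logit, xhat, var, maps, caches = self._forward(x, batch_stats=True)
        p = 1.0 / (1.0 + np.exp(-logit))
        loss = float(np.mean(
            -(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12))))
        dlogit = (p - y) / n
        dfc_w = xhat.T @ dlogit
        dfc_b = dlogit.sum()
        dxhat = np.outer(dlogit, self.fc_w_)
        # batch-norm backward (batch statistics)
        inv_sd = 1.0 / np.sqrt(var + self._BN_EPS)
        if n > 1:
            dgap = (inv_sd / n) * (n * dxhat - dxhat.sum(axis=0)
                                   - xhat * (dxhat * xhat).sum(axis=0))
        else:
            dgap = dxhat * inv_sd
        dh = (dgap[:, :, None, None]
              * np.ones_like(maps) / (maps.shape[2] * maps.shape[3]))
        grads_w, grads_b = [], []
        for (x_shape, cols, relu, idx, out_shape), w in zip(
                reversed(caches), reversed(self.weights_)):
            dout = _pool_backward(dh, idx, out_shape) if idx is not None else dh
            dout = dout * relu
            dh, dw, db = _conv_backward(dout, cols, w, x_shape)
            grads_w.append(dw)
            grads_b.append(db)
        grads_w.reverse()
        grads_b.reverse()

        params = self.weights_ + self.biases_ + [self.fc_w_]
        grads = grads_w + grads_b + [dfc_w]
        # clip the global gradient norm; keeps high-lr runs stable
        gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads) + dfc_b ** 2)
        if gnorm > 5.0:
            scale = 5.0 / gnorm
            grads = [g * scale for g in grads]
            dfc_b *= scale
        for i, (prm, g) in enumerate(zip(params, grads)):
            g = g + cfg.weight_decay * prm
            eta = lr * cfg.head_lr_scale if prm is self.fc_w_ else lr
            state[i] = cfg.momentum * state[i] - eta * g
            prm += state[i]
        self.fc_b_ -= lr * cfg.head_lr_scale * dfc_b
        return loss

    def fit(self, X, y):
        cfg = self.config if self.config is not None else CNNConfig.tiny()
        self.config = cfg
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or X.shape[1:] != (cfg.input_size, cfg.input_size):
            raise ValueError(
                f"X must be (N, {cfg.input_size}, {cfg.input_size})")
        rng = np.random.default_rng(cfg.seed)
        self._init_params(rng)
        state = [np.zeros_like(p) for p in
                 self.weights_ + self.biases_ + [self.fc_w_]]
        batch = cfg.batch_size
        if X.shape[0] < batch:
            warnings.warn(
                f"dataset ({X.shape[0]}) smaller than one batch ({batch}); "
                "reducing batch size", stacklevel=2)
            batch = X.shape[0]
        lr = cfg.lr
        best_loss, stale = np.inf, 0
        self.loss_history_ = []
        self.lr_history_ = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(X.shape[0])
            losses = []
            for start in range(0, X.shape[0], batch):
                sel = order[start:start + batch]
                xb = X[sel].copy()
                if cfg.augment_flips:
                    flip_h = rng.random(sel.size) < 0.5
                    flip_v = rng.random(sel.size) < 0.5
                    xb[flip_h] = xb[flip_h, :, ::-1]
                    xb[flip_v] = xb[flip_v, ::-1, :]
                losses.append(self._train_step(xb, y[sel], state, lr))
            epoch_loss = float(np.mean(losses))
            self.loss_history_.append(epoch_loss)
            self.lr_history_.append(lr)
            # reduce-on-plateau schedule
            if epoch_loss < best_loss - 1e-6:
                best_loss, stale = epoch_loss, 0
            else:
                stale += 1
                if stale >= cfg.plateau_epochs:
                    lr *= cfg.lr_drop_factor
                    stale = 0
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        logit, _ = self._forward(X, keep_maps=True)
        p1 = 1.0 / (1.0 + np.exp(-logit))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def cam(self, image) -> np.ndarray:
        """Class-activation map for one input crop, in [0, 1].

        Classifier-weight-weighted sum of the final conv feature maps
        (the batch-norm scale folds into the weights), referenced
        against the network's response to an empty (all-zero) input so
        that regions carrying no information score ~0, taken as
        evidence magnitude, bilinearly upsampled to the input size and
        min-max normalised. The empty-input reference is needed
        because leaky activations give a nonzero constant response on
        the zeroed-out background of region-masked crops.
        """
        x = np.asarray(image, dtype=float)[None, :, :]
        _, maps = self._forward(x, keep_maps=True)
        # the crop's background constant (zeroed pixels after the
        # crop standardisation), read off the corners
        bg = float(np.median([x[0, 0, 0], x[0, 0, -1],
                              x[0, -1, 0], x[0, -1, -1]]))
        _, ref = self._forward(np.full_like(x, bg), keep_maps=True)
        # per-channel normalisation folds into the weights (affine BN)
        eff_w = self.fc_w_ / np.sqrt(self.bn_var_ + self._BN_EPS)
        cam = np.abs(np.tensordot(eff_w, (maps - ref)[0], axes=(0, 0)))
        cam = ndimage.zoom(cam, x.shape[1] / cam.shape[0], order=1,
                           grid_mode=True, mode="grid-constant")
        cam = cam[:x.shape[1], :x.shape[2]]
        lo, hi = cam.min(), cam.max()
        return (cam - lo) / (hi - lo) if hi > lo else np.zeros_like(cam)


def cnn_train(crops, labels, config: CNNConfig | None = None
              ) -> TinyCNNClassifier:
    """Train the reduced-scale classifier on region-masked crops."""
    return TinyCNNClassifier(config or CNNConfig.tiny()).fit(
        np.asarray(crops, dtype=float), np.asarray(labels, dtype=float))


def cnn_cam(model: TinyCNNClassifier, image) -> np.ndarray:
    """Class-activation heatmap of one crop, in [0, 1]."""
    return model.cam(image)
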