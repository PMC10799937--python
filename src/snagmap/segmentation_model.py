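"""Encoder-decoder network with ordinal energy heads, written in numpy.

The network maps a 4-band patch to K per-level probability maps through a
U-shaped encoder-decoder: strided (pooled) 3x3 convolution blocks with batch
normalisation on the way down, nearest-neighbour upsampling with skip
concatenation on the way up, and a 1x1 head with a sigmoid per energy level.
Per-level sigmoids (rather than a softmax over levels) realise the ordinal
scheme: each head predicts "level >= j present", and the cumulative-product
decoder in :mod:`snagmap.energy_encoding` enforces the nesting.

Forward and backward passes are hand-derived (im2col convolutions, standard
batch-norm gradients, Adam updates), which keeps the whole pipeline
dependency-light and bit-reproducible on a single CPU thread.  The ``small``
preset (~30k parameters) is sized for desk-scale experiments; ``full`` is a
wider variant of the same topology.

Training optimises the Focal Tversky loss, mean over levels of
``(1 - TI_j)^gamma`` with the Tversky index ``TI = TP/(TP + a*FP + b*FN)``
computed on soft predictions; the default ``b > a`` weighs false negatives
more heavily, countering the class imbalance of sparse small crowns, and
``gamma > 1`` focuses training on hard levels.  Model selection is by count
accuracy, not loss: after each epoch the validation patches are decoded to
instances and the checkpoint with the lowest count MAE per patch is kept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .energy_encoding import (EnergyMap, energy_to_ordinal, instances_to_energy,
                              monotone_enforce)
from .geodata_io import RasterTile, RunConfig
from .instance_extraction import watershed_instances

logger = logging.getLogger("snagmap")

_F = np.float32

PRESETS = {"small": (8, 16, 32), "full": (24, 48, 96)}


@dataclass
class LossConfig:
    """Focal Tversky parameters; alpha weighs FP, beta FN, gamma focuses."""

    alpha: float = 0.4
    beta: float = 0.6
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1 and self.gamma >= 1):
            raise ValueError("require alpha, beta in [0,1] and gamma >= 1")


# ---------------------------------------------------------------------------
# layers


class _Conv:
    """Same-padding convolution with kernel 3 or 1, im2col matmul."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, std, (cout, cin * k * k)).astype(_F)
        self.b = np.zeros(cout, dtype=_F)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if self.k == 1:
            mat = x.transpose(0, 2, 3, 1).reshape(-1, c)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            cols = sliding_window_view(xp, (3, 3), axis=(2, 3))
            mat = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(-1, c * 9)
        y = mat @ self.W.T + self.b
        if train:
            self._cache = (mat, (n, c, h, w))
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mat, (n, c, h, w) = self._cache
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.dW += dy_mat.T @ mat
        self.db += dy_mat.sum(axis=0)
        if self.k == 1:
            dx_mat = dy_mat @ self.W
            return dx_mat.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        # full correlation with spatially flipped kernels, in/out swapped
        w4 = self.W.reshape(self.cout, self.cin, 3, 3)
        v = np.ascontiguousarray(w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                                 ).reshape(self.cin, self.cout * 9)
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = sliding_window_view(dyp, (3, 3), axis=(2, 3))
        dy_cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)
                                       ).reshape(-1, self.cout * 9)
        dx = dy_cols @ v.T
        return dx.reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _BatchNorm:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=_F)
        self.beta = np.zeros(c, dtype=_F)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=_F)
        self.running_var = np.ones(c, dtype=_F)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(_F)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(_F)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd.astype(_F))
        return (self.gamma[None, :, None, None] * xhat
                + self.beta[None, :, None, None]).astype(_F)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        n_eff = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma += (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / n_eff
                * (n_eff * dxhat - s1 - xhat * s2)).astype(_F)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return []


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    xv = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xv.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    return flat.max(axis=-1), idx


def _maxpool_back(dy: np.ndarray, idx: np.ndarray, shape) -> np.ndarray:
    n, c, h, w = shape
    out = np.zeros((n, c, h // 2, w // 2, 4), dtype=_F)
    np.put_along_axis(out, idx[..., None], dy[..., None], axis=-1)
    return out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5) \
              .reshape(n, c, h, w)


def _upsample(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample_back(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class EnergyNet:
    """U-shaped network: 4 input bands -> K sigmoid energy-level heads."""

    def __init__(self, in_bands: int, K: int, widths: tuple[int, int, int],
                 rng: np.random.Generator):
        self.in_bands, self.K, self.widths = in_bands, K, widths
        c1, c2, c3 = widths
        self.enc1 = [_Conv(in_bands, c1, 3, rng), _BatchNorm(c1), _ReLU()]
        self.enc2 = [_Conv(c1, c2, 3, rng), _BatchNorm(c2), _ReLU()]
        self.enc3 = [_Conv(c2, c3, 3, rng), _BatchNorm(c3), _ReLU()]
        self.dec2 = [_Conv(c3 + c2, c2, 3, rng), _BatchNorm(c2), _ReLU()]
        self.dec1 = [_Conv(c2 + c1, c1, 3, rng), _BatchNorm(c1), _ReLU()]
        self.head = _Conv(c1, K, 1, rng)
        self._layers = (self.enc1 + self.enc2 + self.enc3 + self.dec2
                        + self.dec1 + [self.head])

    @staticmethod
    def _block(block, x, train):
        for layer in block:
            x = layer.forward(x, train)
        return x

    @staticmethod
    def _block_back(block, dy):
        for layer in reversed(block):
            dy = layer.backward(dy)
        return dy

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Inference pass: (N, bands, H, W) in [0,1] -> (N, K, H, W) in [0,1].

        Inputs whose sides are not divisible by the downsampling factor are
        reflect-padded internally and the output cropped back.
        """
        if x.ndim != 4 or x.shape[1] != self.in_bands:
            raise ValueError(f"expected (N, {self.in_bands}, H, W) input")
        x = x.astype(_F)
        n, _, h, w = x.shape
        ph, pw = (-h) % 4, (-w) % 4
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        e1 = self._block(self.enc1, x, False)
        p1, _ = _maxpool(e1)
        e2 = self._block(self.enc2, p1, False)
        p2, _ = _maxpool(e2)
        e3 = self._block(self.enc3, p2, False)
        d2 = self._block(self.dec2, np.concatenate([_upsample(e3), e2], axis=1), False)
        d1 = self._block(self.dec1, np.concatenate([_upsample(d2), e1], axis=1), False)
        logits = self.head.forward(d1, False).astype(np.float64)
        probs = 1.0 / (1.0 + np.exp(-logits))
        if ph or pw:
            probs = probs[:, :, :h, :w]
        return probs.astype(_F)

    def backward(self, dprobs: np.ndarray) -> None:
        """Accumulate gradients given dL/dprobs (before the sigmoid)."""
        probs, e1_shape, e2_shape, (c1, c2, c3), (ph, pw) = self._cache
        if ph or pw:
            full = np.zeros(probs.shape, dtype=_F)
            full[:, :, :dprobs.shape[2], :dprobs.shape[3]] = dprobs
            dprobs = full
        dlogits = dprobs * probs * (1.0 - probs)
        dd1 = self.head.backward(dlogits)
        dcat1 = self._block_back(self.dec1, dd1)
        dd2_up, de1_skip = dcat1[:, :c2], dcat1[:, c2:]
        dcat2 = self._block_back(self.dec2, _upsample_back(dd2_up))
        de3_up, de2_skip = dcat2[:, :c3], dcat2[:, c3:]
        dp2 = self._block_back(self.enc3, _upsample_back(de3_up))
        de2 = _maxpool_back(dp2, self._idx2, e2_shape) + de2_skip
        dp1 = self._block_back(self.enc2, de2)
        de1 = _maxpool_back(dp1, self._idx1, e1_shape) + de1_skip
        self._block_back(self.enc1, de1)

    def forward_train(self, x: np.ndarray) -> np.ndarray:
        """Training pass: caches activations for :meth:`backward`.

        Sides must be divisible by 4 (training patches are sized that way).
        """
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("training patches must have sides divisible by 4")
        x = x.astype(_F)
        e1 = self._block(self.enc1, x, True)
        p1, self._idx1 = _maxpool(e1)
        e2 = self._block(self.enc2, p1, True)
        p2, self._idx2 = _maxpool(e2)
        e3 = self._block(self.enc3, p2, True)
        d2 = self._block(self.dec2, np.concatenate([_upsample(e3), e2], axis=1), True)
        d1 = self._block(self.dec1, np.concatenate([_upsample(d2), e1], axis=1), True)
        logits = self.head.forward(d1, True)
        probs = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        self._cache = (probs.astype(_F), e1.shape, e2.shape, self.widths, (0, 0))
        return probs.astype(_F)

    def zero_grad(self) -> None:
        for layer in self._layers:
            for _, grad in layer.params():
                grad[...] = 0

    def parameters(self):
        return [pg for layer in self._layers for pg in layer.params()]

    def state(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers:
            for p, _ in layer.params():
                out.append(p.copy())
            if isinstance(layer, _BatchNorm):
                out.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        i = 0
        for layer in self._layers:
            for p, _ in layer.params():
                p[...] = state[i]
                i += 1
            if isinstance(layer, _BatchNorm):
                layer.running_mean[...] = state[i]
                layer.running_var[...] = state[i + 1]
                i += 2


def build_network(in_bands: int = 4, K: int = 5, width_preset: str = "small",
                  seed: int = 0) -> EnergyNet:
    """Construct the encoder-decoder for K ordinal energy levels."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if width_preset not in PRESETS:
        raise ValueError(f"unknown preset {width_preset!r}; pick from {list(PRESETS)}")
    return EnergyNet(in_bands, K, PRESETS[width_preset], np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# loss


def _tversky_terms(pred: np.ndarray, target: np.ndarray, cfg: LossConfig,
                   smooth: float):
    axes = tuple(range(1, pred.ndim))  # per level (axis 0), sum the rest
    tp = (pred * target).sum(axis=axes)
    fp = (pred * (1.0 - target)).sum(axis=axes)
    fn = ((1.0 - pred) * target).sum(axis=axes)
    num = tp + smooth
    den = tp + cfg.alpha * fp + cfg.beta * fn + smooth
    return tp, fp, fn, num, den


def focal_tversky_loss(pred: np.ndarray, target: np.ndarray,
                       cfg: LossConfig | None = None,
                       smooth: float = 1.0) -> float:
    """Mean over levels of (1 - TI_j)^gamma on soft predictions.

    ``pred`` and ``target`` are (K, ...) with level as the leading axis.
    The smoothing constant makes an empty level (no target, no prediction)
    score TI = 1, hence zero loss.
    """
    cfg = cfg or LossConfig()
    if pred.shape != target.shape:
        raise ValueError("prediction and target shapes must match")
    pred64 = pred.astype(np.float64)
    tgt64 = target.astype(np.float64)
    _, _, _, num, den = _tversky_terms(pred64, tgt64, cfg, smooth)
    ti = num / den
    return float(np.mean((1.0 - ti) ** cfg.gamma))


def focal_tversky_grad(pred: np.ndarray, target: np.ndarray,
                       cfg: LossConfig, smooth: float = 1.0) -> tuple[float, np.ndarray]:
    """Loss and its analytic gradient with respect to the predictions."""
    pred64 = pred.astype(np.float64)
    tgt64 = target.astype(np.float64)
    _, _, _, num, den = _tversky_terms(pred64, tgt64, cfg, smooth)
    ti = num / den
    loss = float(np.mean((1.0 - ti) ** cfg.gamma))
    K = pred.shape[0]
    shape = (K,) + (1,) * (pred.ndim - 1)
    # dTI/dp = (t*den - num*(t + alpha*(1-t) - beta*t)) / den^2
    dden_dp = tgt64 + cfg.alpha * (1.0 - tgt64) - cfg.beta * tgt64
    dti = (tgt64 * den.reshape(shape) - num.reshape(shape) * dden_dp) \
        / (den ** 2).reshape(shape)
    outer = cfg.gamma * (1.0 - ti) ** (cfg.gamma - 1.0)
    dloss = -(outer.reshape(shape) * dti) / K
    return loss, dloss.astype(_F)


# ---------------------------------------------------------------------------
# augmentation


def augment(image: np.ndarray, instances: np.ndarray, rng: np.random.Generator,
            geometric_p: float = 0.35, spectral_p: float = 0.35,
            max_rotation_deg: float = 180.0, max_shear: float = 0.2,
            scale_range: tuple[float, float] = (0.9, 1.1)
            ) -> tuple[np.ndarray, np.ndarray]:
    """Jointly warp image and instance labels; jitter the spectrum image-only.

    Geometric: an affine (rotation + shear + anisotropic scale) about the
    patch centre, bilinear for the image and nearest for the labels, applied
    with probability ``geometric_p``.  Spectral: global brightness and
    per-band gain jitter with probability ``spectral_p`` — the target is
    untouched.  Energy targets must be re-encoded from the warped labels.
    """
    img = image.astype(_F)
    lab = instances
    if rng.uniform() < geometric_p:
        theta = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
        shear = rng.uniform(-max_shear, max_shear)
        sx = rng.uniform(*scale_range)
        sy = rng.uniform(*scale_range)
        mat = (np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
               @ np.array([[sx, shear], [0.0, sy]]))
        h, w = lab.shape
        centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        inv = np.linalg.inv(mat)
        offset = centre - inv @ centre
        img = np.stack([
            ndimage.affine_transform(band, inv, offset=offset, order=1, mode="reflect")
            for band in img]).astype(_F)
        lab = ndimage.affine_transform(lab, inv, offset=offset, order=0,
                                       mode="constant", cval=0)
    if rng.uniform() < spectral_p:
        gain = rng.uniform(0.85, 1.15)
        per_band = rng.uniform(0.92, 1.08, size=(img.shape[0], 1, 1)).astype(_F)
        offset = rng.uniform(-0.04, 0.04)
        img = np.clip(img * gain * per_band + offset, 0.0, 1.0).astype(_F)
    return img, lab


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p -= (self.lr * (self.m[i] / corr1)
                  / (np.sqrt(self.v[i] / corr2) + eps)).astype(p.dtype)


@dataclass
class TrainState:
    """Outcome of a training run, with the best-count-MAE checkpoint loaded."""

    network: EnergyNet
    best_epoch: int
    best_val_count_mae: float
    history: pd.DataFrame
    config_hash: str = ""
    splits: dict = field(default_factory=dict)


def _count_instances(labels: np.ndarray) -> int:
    return int(np.unique(labels[labels > 0]).size)


def split_indices(n: int, rng: np.random.Generator,
                  ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)):
    """Shuffled train/validation/test split, each part non-empty."""
    if n < 3:
        raise ValueError("need at least 3 patches for an 8:1:1 split")
    order = rng.permutation(n)
    n_val = max(1, round(ratios[1] * n))
    n_test = max(1, round(ratios[2] * n))
    n_train = n - n_val - n_test
    return (order[:n_train].tolist(), order[n_train:n_train + n_val].tolist(),
            order[n_train + n_val:].tolist())


def train(bundles: list, cfg: RunConfig | None = None,
          network: EnergyNet | None = None) -> TrainState:
    """Train on scene bundles with an 8:1:1 split and count-MAE selection.

    Each bundle contributes one patch (image + instance truth).  Control
    (background-only) patches are welcome.  After every epoch the validation
    patches are decoded (cumulative-product enforcement + watershed) and the
    count MAE per patch is recorded; the returned network carries the
    parameters of the epoch with the minimum validation count MAE.
    """
    cfg = cfg or RunConfig()
    rng = np.random.default_rng(cfg.seed)
    K = cfg.energy_levels
    loss_cfg = LossConfig(cfg.loss_alpha, cfg.loss_beta, cfg.loss_gamma)
    network = network or build_network(4, K, cfg.width_preset, seed=cfg.seed)

    images = [b.image.pixels.astype(_F) / 255.0 for b in bundles]
    instances = [b.truth_instances for b in bundles]
    idx_train, idx_val, idx_test = split_indices(len(bundles), rng)

    optimiser = _Adam(network.parameters(), cfg.learning_rate)
    history = []
    best = (np.inf, -1, None)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(idx_train)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            xs, ts = [], []
            for i in batch:
                img, lab = augment(images[i], instances[i], rng,
                                   cfg.augment_geometric, cfg.augment_spectral)
                energy = instances_to_energy(lab, K,
                                             normalisation=cfg.energy_normalisation)
                ts.append(energy_to_ordinal(energy).masks.astype(_F))
                xs.append(img)
            x = np.stack(xs)
            target = np.stack(ts).transpose(1, 0, 2, 3)  # (K, N, H, W)
            network.zero_grad()
            probs = network.forward_train(x)
            loss, dprobs = focal_tversky_grad(probs.transpose(1, 0, 2, 3),
                                              target, loss_cfg)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (batch starting {start}); "
                    f"prob range [{probs.min():.3g}, {probs.max():.3g}]")
            network.backward(dprobs.transpose(1, 0, 2, 3))
            optimiser.step()
            losses.append(loss)
        val_mae = validation_count_mae(network, [images[i] for i in idx_val],
                                       [instances[i] for i in idx_val], cfg)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_count_mae": val_mae})
        logger.info("epoch %d: loss %.4f, val count MAE %.3f",
                    epoch, history[-1]["train_loss"], val_mae)
        if val_mae < best[0]:
            best = (val_mae, epoch, network.state())
    if best[2] is not None:
        network.load_state(best[2])
    return TrainState(network, best[1], float(best[0]), pd.DataFrame(history),
                      cfg.config_hash,
                      {"train": idx_train, "val": idx_val, "test": idx_test})


def validation_count_mae(network: EnergyNet, images: list, instances: list,
                         cfg: RunConfig) -> float:
    """Count MAE per patch after full decode (enforce + watershed)."""
    errors = []
    for img, lab in zip(images, instances):
        probs = network.forward(img[None])[0]
        energy = monotone_enforce(probs, cfg.energy_threshold)
        pred_labels = watershed_instances(energy, cfg.min_pixels)
        errors.append(abs(_count_instances(lab) - _count_instances(pred_labels)))
    return float(np.mean(errors)) if errors else float("nan")


# ---------------------------------------------------------------------------
# prediction


def predict(network: EnergyNet, tile: RasterTile,
            cfg: RunConfig | None = None) -> EnergyMap:
    """Predict an EnergyMap for a whole tile with centre-weighted stitching.

    Large rasters are processed in overlapping patches whose per-level
    probabilities are blended with a triangular centre weight before the
    cumulative-product decode, suppressing tile-edge artefacts.
    """
    cfg = cfg or RunConfig()
    if tile.n_bands != network.in_bands:
        raise ValueError(f"network expects {network.in_bands} bands, "
                         f"tile has {tile.n_bands}")
    x = tile.pixels.astype(_F) / 255.0
    h, w = tile.shape
    ps, ov = cfg.patch_size, cfg.patch_overlap
    if h <= ps and w <= ps:
        probs = network.forward(x[None])[0]
    else:
        acc = np.zeros((network.K, h, w))
        wacc = np.zeros((h, w))
        win = np.minimum(np.arange(1, ps + 1), np.arange(ps, 0, -1)).astype(float)
        weight = np.outer(win, win)

        def starts(size):
            step = ps - ov
            out = list(range(0, max(size - ps, 0) + 1, step))
            if out[-1] + ps < size:
                out.append(size - ps)
            return out

        for r0 in starts(h):
            for c0 in starts(w):
                patch = x[:, r0:r0 + ps, c0:c0 + ps]
                p = network.forward(patch[None])[0]
                acc[:, r0:r0 + ps, c0:c0 + ps] += p * weight
                wacc[r0:r0 + ps, c0:c0 + ps] += weight
        probs = acc / wacc
    return monotone_enforce(probs, cfg.energy_threshold, tile.transform, tile.crs)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path, network: EnergyNet, cfg: RunConfig) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(network.state())}
    meta = json.dumps({"in_bands": network.in_bands, "K": network.K,
                       "widths": network.widths, "config_hash": cfg.config_hash})
    np.savez(path, meta=meta, **arrays)


def load_checkpoint(path) -> EnergyNet:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    net = EnergyNet(meta["in_bands"], meta["K"], tuple(meta["widths"]),
                    np.random.default_rng(0))
    net.load_state([data[f"p{i}"] for i in range(len(data.files) - 1)])
    return net
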