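"""7-channel-in / 1-channel-out U-Net fusion network: build, train, apply.

The network is the classic encoder–decoder with skip connections,
configured for focal-stack fusion: the seven planes enter channel-wise
in focal order (fd1..fd7) and a single all-in-focus image comes out.
Encoder: ``depth`` groups of [3×3 conv+ReLU ×2, 2×2 stride-2 max-pool]
with filter widths doubling from ``base_filters``; bottleneck: two convs
at ``base_filters·2^depth`` with dropout between them; decoder: ``depth``
groups of [2×2 transposed conv, skip concatenation, 3×3 conv+ReLU ×2];
head: 1×1 conv, linear activation, clamped to [0, 1] at inference. All
3×3 convolutions use 'same' padding, so a side-S input yields a S/2^depth
bottleneck and a S×S×1 output. The network is fully convolutional:
parameter count does not depend on the input side.

Implemented on the in-package NumPy layer library (:mod:`focusfuse.nn`);
training uses Adam on a mean-squared-error loss and is bit-reproducible
given the config seed.
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Adam, Conv2D, ConvTranspose2, Dropout, MaxPool2, ReLU
from .stackio import FocalStack, resize_image

log = logging.getLogger(__name__)

WEIGHTS_FORMAT_VERSION = 1

__all__ = [
    "UNetConfig",
    "LayerCensus",
    "TrainingConfig",
    "UNet",
    "TrainingDivergedError",
    "build_unet",
    "layer_census",
    "train_unet",
    "fuse_unet",
    "save_weights",
    "load_weights",
]


@dataclass
class UNetConfig:
    """Architecture hyperparameters.

    input_side must be divisible by 2^depth. The reference configuration
    (depth 4, base 64) gives encoder widths 64/128/256/512 and a
    1024-filter bottleneck — a 640-px input reaches a 40×40×1024
    bottleneck. ``base_filters`` scales the whole width ladder, which is
    how CPU-budget training runs keep the same topology.
    """

    input_side: int = 640
    in_channels: int = 7
    base_filters: int = 64
    depth: int = 4
    dropout_p: float = 0.5
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.input_side % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_side {self.input_side} must be divisible by "
                f"2^depth = {2 ** self.depth}"
            )
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")

    @property
    def bottleneck_filters(self) -> int:
        return self.base_filters * 2 ** self.depth

    @property
    def bottleneck_side(self) -> int:
        return self.input_side // 2 ** self.depth

    @property
    def encoder_filters(self) -> list[int]:
        return [self.base_filters * 2 ** i for i in range(self.depth)]


@dataclass
class LayerCensus:
    """Countable layer inventory of a constructed network.

    Counted by category over the constructed graph: 3×3 conv+ReLU pairs,
    max-pooling layers, transposed-convolution (up-conv) layers, and the
    1×1 output convolution. Note that for the depth-4 reference topology
    the literal group structure yields 18 conv+ReLU layers (4·2 encoder
    + 2 bottleneck + 4·2 decoder); some published descriptions of this
    architecture print 20 without locating the two extra convolutions.
    """

    conv_relu_3x3: int
    max_pool: int
    up_conv: int
    output_conv_1x1: int

    @property
    def total(self) -> int:
        return self.conv_relu_3x3 + self.max_pool + self.up_conv + self.output_conv_1x1


@dataclass
class TrainingConfig:
    """Optimization settings; Adam on MSE, 80/20 train/held-out split."""

    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 50
    split_fraction: float = 0.8
    seed: int = 0


class TrainingDivergedError(RuntimeError):
    pass


class UNet:
    """Fusion network; see module docstring for the topology."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f = cfg.base_filters
        self.enc: list[tuple] = []
        c_in = cfg.in_channels
        widths = cfg.encoder_filters
        for d, w in enumerate(widths):
            c1 = Conv2D(c_in, w, 3, rng, name=f"enc{d}.conv1")
            c2 = Conv2D(w, w, 3, rng, name=f"enc{d}.conv2")
            self.enc.append((c1, ReLU(), c2, ReLU(), MaxPool2()))
            c_in = w
        wb = cfg.bottleneck_filters
        self.bott = (
            Conv2D(c_in, wb, 3, rng, name="bott.conv1"),
            ReLU(),
            Dropout(cfg.dropout_p),
            Conv2D(wb, wb, 3, rng, name="bott.conv2"),
            ReLU(),
        )
        self.dec: list[tuple] = []
        c_in = wb
        for d, w in enumerate(reversed(widths)):
            up = ConvTranspose2(c_in, w, rng, name=f"dec{d}.up")
            c1 = Conv2D(2 * w, w, 3, rng, name=f"dec{d}.conv1")
            c2 = Conv2D(w, w, 3, rng, name=f"dec{d}.conv2")
            self.dec.append((up, c1, ReLU(), c2, ReLU()))
            c_in = w
        self.head = Conv2D(c_in, cfg.out_channels, 1, rng, name="head")

    # -- parameter plumbing ------------------------------------------------
    def params(self):
        ps = []
        for group in self.enc:
            for layer in group:
                ps.extend(layer.params())
        for layer in self.bott:
            ps.extend(layer.params())
        for group in self.dec:
            for layer in group:
                ps.extend(layer.params())
        ps.extend(self.head.params())
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Forward pass; pass a generator to enable dropout (training)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (B, {self.cfg.in_channels}, H, W) input, got {x.shape}"
            )
        if x.shape[2] % 2 ** self.cfg.depth or x.shape[3] % 2 ** self.cfg.depth:
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by 2^depth"
            )
        skips = []
        for c1, r1, c2, r2, pool in self.enc:
            x = r2.forward(c2.forward(r1.forward(c1.forward(x))))
            skips.append(x)
            x = pool.forward(x)
        c1, r1, drop, c2, r2 = self.bott
        x = drop.forward(r1.forward(c1.forward(x)), rng)
        x = r2.forward(c2.forward(x))
        self._bottleneck_shape = x.shape
        for (up, c1, r1, c2, r2), skip in zip(self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=1)
            x = r2.forward(c2.forward(r1.forward(c1.forward(x))))
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.head.backward(np.ascontiguousarray(dy, dtype=np.float32))
        dskips = []
        for up, c1, r1, c2, r2 in reversed(self.dec):
            dy = c1.backward(r1.backward(c2.backward(r2.backward(dy))))
            w = dy.shape[1] // 2
            dskips.append(dy[:, :w])
            dy = up.backward(dy[:, w:])
        c1, r1, drop, c2, r2 = self.bott
        dy = c1.backward(r1.backward(drop.backward(c2.backward(r2.backward(dy)))))
        for (c1, r1, c2, r2, pool), dskip in zip(reversed(self.enc), reversed(dskips)):
            dy = pool.backward(dy)
            dy = dy + dskip
            dy = c1.backward(r1.backward(c2.backward(r2.backward(dy))))

    # -- shape contracts ---------------------------------------------------
    def bottleneck_shape(self, side: int | None = None) -> tuple[int, int, int]:
        """(H, W, C) of the deepest feature map for a side×side input."""
        side = side or self.cfg.input_side
        s = side // 2 ** self.cfg.depth
        return (s, s, self.cfg.bottleneck_filters)

    def output_shape(self, side: int | None = None) -> tuple[int, int, int]:
        side = side or self.cfg.input_side
        return (side, side, self.cfg.out_channels)


def build_unet(cfg: UNetConfig, seed: int = 0) -> UNet:
    """Construct the network with He-initialized weights (seeded)."""
    return UNet(cfg, seed=seed)


def layer_census(net: UNet) -> LayerCensus:
    """Count layers by category over the constructed graph."""
    conv_relu = 0
    pools = 0
    ups = 0
    out1x1 = 0
    for group in list(net.enc) + [net.bott] + list(net.dec):
        for layer in group:
            if isinstance(layer, Conv2D) and layer.k == 3:
                conv_relu += 1
            elif isinstance(layer, MaxPool2):
                pools += 1
            elif isinstance(layer, ConvTranspose2):
                ups += 1
    if isinstance(net.head, Conv2D) and net.head.k == 1:
        out1x1 = 1
    return LayerCensus(conv_relu_3x3=conv_relu, max_pool=pools, up_conv=ups,
                       output_conv_1x1=out1x1)


@dataclass
class TrainingHistory:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_mse: float = np.inf


def _to_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for stack, target in dataset:
        planes = stack.planes if isinstance(stack, FocalStack) else np.asarray(stack)
        xs.append(np.asarray(planes, dtype=np.float32))
        t = np.asarray(target, dtype=np.float32)
        ys.append(t[None] if t.ndim == 2 else t)
    return np.stack(xs), np.stack(ys)


def train_unet(net: UNet, dataset, tcfg: TrainingConfig | None = None) -> TrainingHistory:
    """Train on (stack, target) pairs with Adam + MSE; returns the history.

    The dataset is split tcfg.split_fraction / rest into train and
    held-out subsets (seed-deterministic). Per-epoch train and held-out
    MSE are recorded and the parameters of the best held-out epoch are
    restored at the end. Fully deterministic given tcfg.seed.
    """
    tcfg = tcfg or TrainingConfig()
    X, Y = _to_arrays(dataset)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to train")
    rng = np.random.default_rng(tcfg.seed)
    perm = rng.permutation(n)
    n_train = max(1, int(round(tcfg.split_fraction * n)))
    n_train = min(n_train, n - 1)  # keep the held-out set non-empty
    tr, va = perm[:n_train], perm[n_train:]
    opt = Adam(net.params(), lr=tcfg.learning_rate)
    hist = TrainingHistory()
    best_state = net.get_state()

    def eval_mse(idx) -> float:
        tot = 0.0
        for i in idx:
            out = net.forward(X[i : i + 1])
            tot += float(np.mean((out - Y[i : i + 1]) ** 2))
        return tot / len(idx)

    for epoch in range(tcfg.epochs):
        order = rng.permutation(n_train)
        ep_loss = 0.0
        n_batches = 0
        for start in range(0, n_train, tcfg.batch_size):
            bidx = tr[order[start : start + tcfg.batch_size]]
            xb, yb = X[bidx], Y[bidx]
            opt.zero_grad()
            out = net.forward(xb, rng=rng)
            diff = out - yb
            loss = float(np.mean(diff ** 2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches} "
                    f"(learning_rate={tcfg.learning_rate})"
                )
            net.backward(2.0 * diff / diff.size)
            opt.step()
            ep_loss += loss
            n_batches += 1
        hist.train_mse.append(ep_loss / max(1, n_batches))
        val = eval_mse(va)
        hist.val_mse.append(val)
        if val < hist.best_val_mse:
            hist.best_val_mse = val
            hist.best_epoch = epoch
            best_state = net.get_state()
        log.info("epoch %d: train MSE %.6f, held-out MSE %.6f",
                 epoch, hist.train_mse[-1], val)
    net.set_state(best_state)
    return hist


def fuse_unet(net: UNet, stack: FocalStack | np.ndarray) -> np.ndarray:
    """Single inference pass: 7 planes in, one [0, 1] image out.

    Dropout is disabled; the linear head is clamped to [0, 1]. A stack
    whose side differs from the network's configured input side is
    bilinearly resized first (with a warning).
    """
    planes = stack.planes if isinstance(stack, FocalStack) else np.asarray(stack, float)
    side = planes.shape[1]
    step = 2 ** net.cfg.depth
    if planes.shape[1] != planes.shape[2] or side % step:
        target = net.cfg.input_side
        warnings.warn(
            f"stack side {planes.shape[1:]} incompatible with the network "
            f"(needs square, divisible by {step}); resizing to {target}",
            stacklevel=2,
        )
        planes = np.stack([resize_image(p, target) for p in planes])
    out = net.forward(planes[None].astype(np.float32))
    return np.clip(out[0, 0].astype(float), 0.0, 1.0)


def save_weights(net: UNet, path) -> None:
    """Serialize weights with the embedded config and a format version."""
    meta = json.dumps({"format_version": WEIGHTS_FORMAT_VERSION,
                       "config": asdict(net.cfg)})
    arrays = {f"p{i:03d}": p.value for i, p in enumerate(net.params())}
    np.savez(path, meta=np.array(meta), **arrays)


def load_weights(path) -> UNet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("format_version") != WEIGHTS_FORMAT_VERSION:
            raise ValueError(f"unsupported weights format: {meta.get('format_version')}")
        net = UNet(UNetConfig(**meta["config"]))
        state = [z[f"p{i:03d}"] for i in range(len(net.params()))]
    net.set_state(state)
    return net
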