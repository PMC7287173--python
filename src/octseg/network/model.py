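"""Encoder-decoder fully convolutional network for 3-class B-scan labeling.

Each encoder block is convolution (64 rectangular 7x3 kernels, zero padded)
-> batch norm -> ReLU -> 2x2 max-pool, with the pooling argmax indices handed
to the matched decoder block.  Each decoder block is index-based unpooling
(doubling resolution) -> concatenation with the matched encoder's pre-pool
feature map -> convolution -> batch norm -> ReLU.  The head is a 1x1
convolution to the class channels followed by a per-pixel softmax, so the
output probability map has the input's spatial size.

Input heights/widths need not divide 2^n_blocks: the forward pass reflect-pads
to the next multiple and crops the output back, so the stated I/O sizes
(e.g. 526x75 patches in, 526x75x3 probabilities out) hold as-is.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .layers import (Conv2d, BatchNorm2d, ReLU, MaxPool2x2, MaxUnpool2x2,
                     softmax_channels)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and optimization hyper-parameters.

    Defaults follow the training recipe used on the real cohort: SGD with
    momentum 0.97, learning rate 0.001 cut by 10x every 20 epochs, 60 epochs,
    batches of 4 patches, 64 filters of 7x3 per convolution.
    """

    n_classes: int = 3
    n_blocks: int = 4
    kernel_shape: tuple[int, int] = (7, 3)
    filters_per_conv: int = 64
    batch_size: int = 4
    momentum: float = 0.97
    initial_lr: float = 0.001
    lr_drop_factor: float = 0.1
    lr_drop_every_epochs: int = 20
    epochs: int = 60
    seed: int = 0
    dice_mode: str = "global"
    augment: bool = True

    def __post_init__(self):
        kh, kw = self.kernel_shape
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dims must be odd (zero padding preserves size)")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    def lr_at_epoch(self, epoch: int) -> float:
        return self.initial_lr * self.lr_drop_factor ** (
            epoch // self.lr_drop_every_epochs)


def iterations_per_epoch(n_train: int, batch_size: int) -> int:
    """N = ceil(n_training_samples / batch_size) gradient steps per epoch."""
    return -(-n_train // batch_size)


class OCTNet:
    """The segmentation network; layers built from a seeded generator."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.filters_per_conv
        k = config.kernel_shape
        self.enc_conv, self.enc_bn, self.enc_relu, self.enc_pool = [], [], [], []
        cin = 1
        for _ in range(config.n_blocks):
            self.enc_conv.append(Conv2d(cin, f, k, rng))
            self.enc_bn.append(BatchNorm2d(f))
            self.enc_relu.append(ReLU())
            self.enc_pool.append(MaxPool2x2())
            cin = f
        self.dec_unpool, self.dec_conv, self.dec_bn, self.dec_relu = [], [], [], []
        for _ in range(config.n_blocks):
            self.dec_unpool.append(MaxUnpool2x2())
            self.dec_conv.append(Conv2d(2 * f, f, k, rng))
            self.dec_bn.append(BatchNorm2d(f))
            self.dec_relu.append(ReLU())
        self.head = Conv2d(f, config.n_classes, (1, 1), rng)
        self._fwd = None

    # ---------------------------------------------------------- parameters

    def _layers_with_params(self):
        return (self.enc_conv + self.enc_bn + self.dec_conv + self.dec_bn
                + [self.head])

    @property
    def params(self) -> list[np.ndarray]:
        return [p for lay in self._layers_with_params() for p in lay.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for lay in self._layers_with_params() for g in lay.grads]

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params]
        for bn in self.enc_bn + self.dec_bn:
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, s in zip(self.params, state[:n]):
            p[...] = s
        rest = state[n:]
        for i, bn in enumerate(self.enc_bn + self.dec_bn):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]

    # ------------------------------------------------------------- forward

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(B, 1, H, W) intensities -> (B, n_classes, H, W) probabilities."""
        if x.ndim != 4:
            raise ValueError("input must be (batch, 1, rows, cols)")
        B, _, H, W = x.shape
        m = 2 ** self.config.n_blocks
        ph, pw = (-H) % m, (-W) % m
        if H + ph < m or W + pw < m:
            raise ValueError(
                f"input {H}x{W} too small for {self.config.n_blocks} poolings")
        xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect") \
            if (ph or pw) else x

        skips = []
        h = xp
        for conv, bn, relu, pool in zip(self.enc_conv, self.enc_bn,
                                        self.enc_relu, self.enc_pool):
            h = relu.forward(bn.forward(conv.forward(h), training))
            skips.append(h)
            h = pool.forward(h)
        for i in range(self.config.n_blocks - 1, -1, -1):
            up = self.dec_unpool[i].forward(h, self.enc_pool[i].indices)
            cat = np.concatenate([up, skips[i]], axis=1)
            h = self.dec_relu[i].forward(
                self.dec_bn[i].forward(self.dec_conv[i].forward(cat), training))
        logits = self.head.forward(h)
        probs = softmax_channels(logits)
        self._fwd = (probs, (H, W), (ph, pw))
        return probs[:, :, :H, :W]

    def backward(self, dlogits: np.ndarray) -> None:
        """Backprop from dL/dlogits over the *cropped* output region."""
        _, (H, W), (ph, pw) = self._fwd
        f = self.config.filters_per_conv
        if ph or pw:
            # padded border logits never reach the loss -> zero gradient there
            full = np.zeros(dlogits.shape[:2] + (H + ph, W + pw))
            full[:, :, :H, :W] = dlogits
            dlogits = full
        dh = self.head.backward(dlogits)
        dskips = [None] * self.config.n_blocks
        for i in range(self.config.n_blocks):
            dcat = self.dec_conv[i].backward(
                self.dec_bn[i].backward(self.dec_relu[i].backward(dh)))
            dup, dskips[i] = dcat[:, :f], dcat[:, f:]
            dh = self.dec_unpool[i].backward(dup)
        for i in range(self.config.n_blocks - 1, -1, -1):
            dpre = self.enc_pool[i].backward(dh) + dskips[i]
            dh = self.enc_conv[i].backward(
                self.enc_bn[i].backward(self.enc_relu[i].backward(dpre)))


@dataclass
class ModelState:
    """A trained checkpoint: parameters, training history, config snapshot.

    The stored parameters are those of the epoch minimizing validation loss.
    """

    config: NetworkConfig
    state: list[np.ndarray]
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def build(self) -> OCTNet:
        net = OCTNet(self.config)
        net.set_state(self.state)
        return net

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"config": asdict(self.config), "state": self.state,
                         "history": self.history,
                         "best_epoch": self.best_epoch}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        with open(path, "rb") as fh:
            d = pickle.load(fh)
        d["config"]["kernel_shape"] = tuple(d["config"]["kernel_shape"])
        return cls(config=NetworkConfig(**d["config"]), state=d["state"],
                   history=d["history"], best_epoch=d["best_epoch"])


def predict_probabilities(model: ModelState | OCTNet, pixels: np.ndarray) -> np.ndarray:
    """Run one 2-D image through the network; returns (n_classes, H, W)."""
    net = model.build() if isinstance(model, ModelState) else model
    out = net.forward(pixels[None, None, :, :], training=False)
    return out[0]
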