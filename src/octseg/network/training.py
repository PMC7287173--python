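"""Patch-wise training loop: SGD with momentum, stepped LR, best-val checkpoint.

Each epoch runs ceil(n_train / batch_size) gradient steps on shuffled,
optionally augmented patches, minimizing the Soft-Dice loss.  The learning
rate starts at ``initial_lr`` and is cut by ``lr_drop_factor`` every
``lr_drop_every_epochs`` epochs.  After every epoch the validation loss is
evaluated and the parameters of the epoch with minimum validation loss are
the returned checkpoint.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .augment import augment_pair
from .layers import SGDMomentum, softmax_backward
from .loss import soft_dice_loss, soft_dice_grad
from .model import NetworkConfig, OCTNet, ModelState, iterations_per_epoch

PatchPair = tuple[np.ndarray, np.ndarray]  # (image patch, label patch)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return (labels[:, None, :, :] ==
            np.arange(n_classes)[None, :, None, None]).astype(np.float64)


def _batch_loss(net: OCTNet, pairs: list[PatchPair], n_classes: int,
                mode: str) -> float:
    """Mean per-sample Soft-Dice loss in inference mode."""
    total = 0.0
    for img, lab in pairs:
        p = net.forward(img[None, None], training=False)
        total += soft_dice_loss(p, _one_hot(lab[None], n_classes), mode=mode)
    return total / len(pairs)


def train(train_pairs: list[PatchPair], val_pairs: list[PatchPair],
          config: NetworkConfig,
          log_path: str | Path | None = None) -> ModelState:
    """Train the network and return the minimum-validation-loss checkpoint."""
    if not train_pairs:
        raise ValueError("empty training set")
    if not val_pairs:
        raise ValueError("empty validation set")
    net = OCTNet(config)
    opt = SGDMomentum(net.params, config.momentum)
    rng = np.random.default_rng(config.seed)
    n = len(train_pairs)
    steps = iterations_per_epoch(n, config.batch_size)

    history: list[dict] = []
    best_val = np.inf
    best_state = net.get_state()
    best_epoch = -1
    for epoch in range(config.epochs):
        lr = config.lr_at_epoch(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(steps):
            idx = order[s * config.batch_size:(s + 1) * config.batch_size]
            imgs, labs = [], []
            for i in idx:
                img, lab = train_pairs[i]
                if config.augment:
                    img, lab = augment_pair(img, lab, rng)
                imgs.append(img)
                labs.append(lab)
            x = np.stack(imgs)[:, None]
            g = _one_hot(np.stack(labs), config.n_classes)
            p = net.forward(x, training=True)
            epoch_loss += soft_dice_loss(p, g, mode=config.dice_mode)
            dp = soft_dice_grad(p, g)
            net.backward(softmax_backward(p, dp))
            opt.step(net.grads, lr)
        train_loss = epoch_loss / steps
        val_loss = _batch_loss(net, val_pairs, config.n_classes, config.dice_mode)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "lr": lr})
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.get_state()
            best_epoch = epoch
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            wr = csv.DictWriter(fh, fieldnames=["epoch", "train_loss",
                                                "val_loss", "lr"])
            wr.writeheader()
            wr.writerows(history)
    return ModelState(config=config, state=best_state, history=history,
                      best_epoch=best_epoch)
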