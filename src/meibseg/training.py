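"""Network training: multi-class soft Dice loss, L1 regularization, Adam
with step decay (lr × 0.8 every 5 epochs), best-validation checkpointing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import MeibNet, image_to_input, _resize_nearest
from .synthetic import LabeledImage

__all__ = ["TrainConfig", "TrainHistory", "dice_loss", "l1_penalty", "train",
           "one_hot", "prepare_batch"]

_SMOOTH = 1e-6


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-4
    lr_decay_factor: float = 0.8
    lr_decay_every: int = 5
    batch_size: int = 32
    max_epochs: int = 50
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    l1_weight: float = 1e-6
    seed: int = 0
    input_size: int = 256

    def lr_at_epoch(self, epoch: int) -> float:
        """Closed form of the step schedule: lr0 · decay^⌊epoch/every⌋."""
        return self.learning_rate * self.lr_decay_factor ** (
            epoch // self.lr_decay_every)


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_dsc_mg: list = field(default_factory=list)
    val_dsc_eyelid: list = field(default_factory=list)
    learning_rates: list = field(default_factory=list)
    best_epoch: int = -1

    def to_rows(self):
        return [
            {"epoch": e, "train_loss": l, "val_dsc_mg": m, "val_dsc_eyelid": ey,
             "learning_rate": lr}
            for e, l, m, ey, lr in zip(self.epochs, self.train_loss,
                                       self.val_dsc_mg, self.val_dsc_eyelid,
                                       self.learning_rates)
        ]


def one_hot(mask: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """(H, W) labels -> (C, H, W) one-hot float32."""
    return (np.arange(n_classes)[:, None, None] == mask[None]).astype(np.float32)


def dice_loss(pred_probs: nn.Tensor, target: np.ndarray) -> nn.Tensor:
    """Soft Dice loss, averaged over the 3 classes.

    ``pred_probs``: (N, 3, H, W) per-pixel class probabilities (softmax
    output).  ``target``: (N, H, W) integer labels over {0,1,2}.  Per class,
    L = 1 − 2·|y∩y′| / (|y| + |y′|), with a small smoothing constant so an
    absent class contributes 0 loss when predicted absent.
    """
    if pred_probs.data.ndim != 4:
        raise ValueError("pred_probs must be (N, C, H, W)")
    n, c, h, w = pred_probs.data.shape
    target = np.asarray(target)
    if target.shape != (n, h, w):
        raise ValueError(f"target shape {target.shape} does not match "
                         f"prediction spatial shape {(n, h, w)}")
    tgt = np.stack([one_hot(t, c) for t in target]).astype(
        pred_probs.data.dtype)  # (N, C, H, W)
    inter = (pred_probs * nn.Tensor(tgt)).sum(axis=(0, 2, 3))
    sizes = pred_probs.sum(axis=(0, 2, 3)) + nn.Tensor(tgt.sum(axis=(0, 2, 3)))
    dice = (inter * 2.0 + _SMOOTH) / (sizes + _SMOOTH)
    return (1.0 - dice).mean()


def l1_penalty(network: MeibNet, weight: float) -> float:
    """weight × Σ|w| over convolution kernels (biases and norms excluded)."""
    if weight < 0:
        raise ValueError("l1 weight must be >= 0")
    if weight == 0:
        return 0.0
    total = sum(float(np.abs(m.weight.data).sum())
                for m in network.modules() if isinstance(m, nn.Conv2d))
    return weight * total


def _conv_weights(network):
    return [m.weight for m in network.modules() if isinstance(m, nn.Conv2d)]


def prepare_batch(items: list[LabeledImage], input_size: int):
    """Stack images/masks resized to the network input size."""
    xs = np.concatenate([image_to_input(it.image, input_size) for it in items])
    ys = np.stack([
        it.mask if it.mask.shape == (input_size, input_size)
        else _resize_nearest(it.mask, (input_size, input_size))
        for it in items])
    return xs, ys.astype(np.int64)


def _soft_dice_scores(network, items, input_size):
    """Mean per-region hard DSC of the network on a set (regions 1 and 2)."""
    from .evaluation import region_metrics
    network.eval()
    per_region = {1: [], 2: []}
    for it in items:
        x = nn.Tensor(image_to_input(it.image, input_size))
        pred = network(x).data[0].argmax(axis=0).astype(np.uint8)
        truth = (it.mask if it.mask.shape == pred.shape
                 else _resize_nearest(it.mask, pred.shape))
        for region in (1, 2):
            rec = region_metrics(pred, truth, region)
            if rec.defined:
                per_region[region].append(rec.dsc)
    return (float(np.mean(per_region[2])) if per_region[2] else float("nan"),
            float(np.mean(per_region[1])) if per_region[1] else float("nan"))


def train(network: MeibNet, train_set: list[LabeledImage],
          val_set: list[LabeledImage], config: TrainConfig = TrainConfig(),
          verbose: bool = False):
    """Train with Dice loss + L1, Adam, step-decayed learning rate.

    Returns ``(network, history)`` with the network restored to the
    best-validation-DSC checkpoint.
    """
    if not train_set or not val_set:
        raise ValueError("train_set and val_set must be non-empty")
    rng = np.random.default_rng(config.seed)
    params = list(network.parameters())
    opt = nn.Adam(params, lr=config.learning_rate, beta1=config.adam_beta1,
                  beta2=config.adam_beta2, l1_weight=config.l1_weight,
                  l1_params=_conv_weights(network))
    history = TrainHistory()
    best_score, best_state = -np.inf, None
    n = len(train_set)
    for epoch in range(config.max_epochs):
        opt.lr = config.lr_at_epoch(epoch)
        order = rng.permutation(n)
        network.train()
        losses = []
        for start in range(0, n, config.batch_size):
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            xs, ys = prepare_batch(batch, config.input_size)
            probs = nn.softmax_channels(network(nn.Tensor(xs)))
            loss = dice_loss(probs, ys)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        dsc_mg, dsc_eyelid = _soft_dice_scores(network, val_set,
                                               config.input_size)
        score = np.nanmean([dsc_mg, dsc_eyelid])
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_dsc_mg.append(dsc_mg)
        history.val_dsc_eyelid.append(dsc_eyelid)
        history.learning_rates.append(opt.lr)
        if score > best_score:
            best_score = score
            best_state = {k: v.copy() for k, v in network.state_dict().items()}
            history.best_epoch = epoch
        if verbose:
            print(f"epoch {epoch:3d}  loss {history.train_loss[-1]:.4f}  "
                  f"val DSC (MG {dsc_mg:.3f} / eyelid {dsc_eyelid:.3f})  "
                  f"lr {opt.lr:.2e}")
    if best_state is not None:
        network.load_state_dict(best_state)
    return network, history


def overfit_single(network: MeibNet, item: LabeledImage, *, steps: int = 200,
                   lr: float = 1e-3, input_size: int = 64,
                   l1_weight: float = 0.0):
    """Drive the network onto one labeled image; returns per-step Dice losses.

    A fast sanity oracle: a correctly wired network and loss must be able to
    memorize a single phantom.
    """
    xs, ys = prepare_batch([item], input_size)
    opt = nn.Adam(list(network.parameters()), lr=lr, l1_weight=l1_weight,
                  l1_params=_conv_weights(network))
    network.train()
    losses = []
    x = nn.Tensor(xs)
    for _ in range(steps):
        probs = nn.softmax_channels(network(x))
        loss = dice_loss(probs, ys)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    return losses
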