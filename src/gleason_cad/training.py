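"""Class-balanced training of the per-scale CNNs.

Slides are always split into train/validation/test *before* patch
generation, so no patch from a held-out slide can leak into training.
Class balancing keeps every patch of GP2–GP5 and randomly subsamples the
over-represented GP1 (stroma, ~60% of tissue) down to the median count
of the other four classes.  Training minimizes softmax cross-entropy
with Adam; the checkpoint with the best validation accuracy is returned.
A random-search harness tunes learning rate, batch size and the
convolutional dropout schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from gleason_cad.model import PatchCNN, _Dropout, build_network, softmax
from gleason_cad.patching import PatchRecord


@dataclass
class TrainingConfig:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    rs_budget: int = 10
    patience: int = 5  # early stop on stalled validation accuracy
    conv_dropout_scale: float = 1.0
    val_fraction: float = 0.25  # slide-level, used when no val set given


@dataclass
class BalancingPlan:
    counts_before: dict[int, int]
    counts_after: dict[int, int]
    gp1_target: int
    seed: int


# ---------------------------------------------------------------------------
# Slide-level splitting and class balancing
# ---------------------------------------------------------------------------

def split_slides(
    slide_ids: list[str],
    val_fraction: float,
    seed: int,
    test_fraction: float = 0.0,
) -> tuple[list[str], list[str], list[str]]:
    """Partition slide ids into train/validation/test sets (seeded).

    The partition happens at slide level so that patches from one slide
    never straddle the split.
    """
    ids = sorted(set(slide_ids))
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_val = int(round(val_fraction * len(ids)))
    n_test = int(round(test_fraction * len(ids)))
    val, test, train = ids[:n_val], ids[n_val : n_val + n_test], ids[n_val + n_test :]
    return train, val, test


def balance_classes(
    patches: list[PatchRecord], seed: int
) -> tuple[list[PatchRecord], BalancingPlan]:
    """Subsample GP1 patches to the median count of GP2–GP5.

    Classes 2–5 are kept in full; GP1 is subsampled without replacement
    (seeded) and never oversampled.  Order of the kept patches follows
    the input order.
    """
    before: dict[int, int] = {k: 0 for k in range(1, 6)}
    for p in patches:
        if p.label not in before:
            raise ValueError(f"patch without a valid training label: {p.label!r}")
        before[p.label] += 1
    target = int(np.median([before[k] for k in range(2, 6)]))
    keep_idx = set()
    gp1_positions = [i for i, p in enumerate(patches) if p.label == 1]
    if before[1] > target:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(gp1_positions), size=target, replace=False)
        keep_idx = {gp1_positions[i] for i in chosen}
    else:
        keep_idx = set(gp1_positions)
    kept = [p for i, p in enumerate(patches) if p.label != 1 or i in keep_idx]
    after = {k: 0 for k in range(1, 6)}
    for p in kept:
        after[p.label] += 1
    return kept, BalancingPlan(before, after, gp1_target=target, seed=seed)


# ---------------------------------------------------------------------------
# Optimizer and training loop
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p, _ in params]
            self._v = [np.zeros_like(p) for p, _ in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(params, self._m, self._v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def patches_to_arrays(patches: list[PatchRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patches into (X, y): float32 pixels in [0,1], labels 0..4."""
    x = np.stack([p.pixels for p in patches]).astype(np.float32) / 255.0
    y = np.array([p.label - 1 for p in patches], dtype=np.int64)
    return x, y


def _cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    probs = softmax(logits)
    n = len(y)
    loss = -float(np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def evaluate(model: PatchCNN, x: np.ndarray, y: np.ndarray,
             batch_size: int = 32) -> tuple[float, float]:
    """(loss, accuracy) of ``model`` on (x, y) in eval mode."""
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i : i + batch_size], train=False)
        loss, _ = _cross_entropy(logits, y[i : i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train_scale(
    patches: list[PatchRecord],
    config: TrainingConfig,
    val_patches: list[PatchRecord] | None = None,
) -> tuple[PatchCNN, pd.DataFrame]:
    """Train one pyramid level's CNN on labeled patches of one scale.

    When no validation patches are given, slides are split off for
    validation per ``config.val_fraction`` (slide-level, no leakage).
    Returns the best-validation-accuracy checkpoint and the per-epoch
    history (train/validation loss and accuracy).
    """
    if not patches:
        raise ValueError("no patches to train on")
    scales = {p.scale for p in patches}
    if len(scales) != 1:
        raise ValueError(f"patches mix scales {sorted(scales)}")
    scale = scales.pop()

    if val_patches is None:
        train_ids, val_ids, _ = split_slides(
            [p.slide_id for p in patches], config.val_fraction, config.seed
        )
        val_patches = [p for p in patches if p.slide_id in set(val_ids)]
        patches = [p for p in patches if p.slide_id in set(train_ids)]
    if not patches or not val_patches:
        raise ValueError("empty train or validation set after slide split")

    x_train, y_train = patches_to_arrays(patches)
    x_val, y_val = patches_to_arrays(val_patches)

    model = build_network(scale, seed=config.seed)
    conv_dropouts = [l for l in model.layers[:16] if isinstance(l, _Dropout)]
    for layer, base_rate in zip(conv_dropouts, model.spec.conv_dropout):
        layer.rate = min(0.95, base_rate * config.conv_dropout_scale)

    opt = Adam(config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = []
    best_acc, best_weights, stall = -1.0, model.get_weights(), 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_train))
        epoch_loss, correct = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(x_train[idx], train=True, rng=rng)
            loss, dlogits = _cross_entropy(logits, y_train[idx])
            model.backward(dlogits)
            opt.step(model.parameters())
            epoch_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == y_train[idx]).sum())
        val_loss, val_acc = evaluate(model, x_val, y_val, config.batch_size)
        history.append(
            {
                "epoch": epoch + 1,
                "train_loss": epoch_loss / len(x_train),
                "train_acc": correct / len(x_train),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_acc:
            best_acc, best_weights, stall = val_acc, model.get_weights(), 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    model.set_weights(best_weights)
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Random-search hyper-parameter tuning
# ---------------------------------------------------------------------------

#: Default search space: log-uniform learning rate, batch size, and a
#: multiplier on the convolutional dropout schedule.
DEFAULT_SEARCH_SPACE = {
    "learning_rate": (1e-4, 1e-2),  # log-uniform bounds
    "batch_size": (32, 64, 128),
    "conv_dropout_scale": (0.5, 1.0, 1.5),
}


def sample_config(
    rng: np.random.Generator, base: TrainingConfig, space: dict
) -> TrainingConfig:
    lo, hi = space["learning_rate"]
    lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return replace(
        base,
        learning_rate=lr,
        batch_size=int(rng.choice(space["batch_size"])),
        conv_dropout_scale=float(rng.choice(space["conv_dropout_scale"])),
    )


def random_search(
    patches: list[PatchRecord],
    budget: int,
    seed: int,
    base_config: TrainingConfig | None = None,
    space: dict | None = None,
    val_patches: list[PatchRecord] | None = None,
) -> tuple[TrainingConfig, pd.DataFrame]:
    """Sample ``budget`` configs uniformly and return the best by
    validation accuracy, with a log of every trial."""
    if budget < 1:
        raise ValueError("random-search budget must be >= 1")
    space = space or DEFAULT_SEARCH_SPACE
    if not space:
        raise ValueError("empty search space")
    base = base_config or TrainingConfig()
    rng = np.random.default_rng(seed)
    trials = []
    best_acc, best_config = -1.0, None
    for trial in range(budget):
        cfg = sample_config(rng, base, space)
        cfg = replace(cfg, seed=base.seed + trial)
        _, hist = train_scale(patches, cfg, val_patches=val_patches)
        acc = float(hist["val_acc"].max())
        trials.append(
            {
                "trial": trial,
                "learning_rate": cfg.learning_rate,
                "batch_size": cfg.batch_size,
                "conv_dropout_scale": cfg.conv_dropout_scale,
                "val_acc": acc,
            }
        )
        if acc > best_acc:
            best_acc, best_config = acc, cfg
    return best_config, pd.DataFrame(trials)
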