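"""Staged layer-freezing transfer to a target segmentation task.

Transfer from a (meta-)learned initialization proceeds in stages: the first
``depth`` encoder blocks start frozen at learning rate 1e-3, each stage
unfreezes the deepest still-frozen block, and the final stage trains all
parameters at 1e-4.  For depths >= 2 the penultimate stage applies an
inverse-time learning-rate decay, lr / (1 + 0.0077 * epoch).  Freezing a
block pins its convolution weights, BN affine parameters and BN running
statistics exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .unet import UNet

__all__ = [
    "StageSpec",
    "FreezePlan",
    "make_freeze_plan",
    "run_freeze_stage",
    "fine_tune_layer_freezing",
    "effective_lr",
    "train_supervised",
]

LR_EARLY = 1e-3
LR_FINAL = 1e-4
DECAY_RATE = 0.0077


@dataclass(frozen=True)
class StageSpec:
    """One fine-tuning stage: what is frozen, at what rate, for how long."""

    frozen_blocks: frozenset
    learning_rate: float
    decay_rate: float = 0.0
    n_epochs: int = 100

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.decay_rate < 0 or self.n_epochs < 0:
            raise ValueError("decay_rate and n_epochs must be >= 0")


@dataclass(frozen=True)
class FreezePlan:
    stages: tuple

    def __post_init__(self):
        prev = None
        for st in self.stages:
            if prev is not None and not st.frozen_blocks < prev:
                raise ValueError("frozen sets must strictly shrink stage to stage")
            prev = st.frozen_blocks
        if self.stages and self.stages[-1].frozen_blocks:
            raise ValueError("final stage must freeze nothing")

    def __len__(self):
        return len(self.stages)


def make_freeze_plan(
    depth: int,
    n_epochs_per_stage: int = 100,
    lr_early: float = LR_EARLY,
    lr_final: float = LR_FINAL,
    decay: float = DECAY_RATE,
    n_down_blocks: int = 4,
) -> FreezePlan:
    """Build the (depth + 1)-stage plan for an initial freezing depth.

    Stage 1 freezes encoder blocks {1..depth}; each following stage
    unfreezes the deepest still-frozen block; the last stage trains
    everything at the lower rate.  The inverse-time decay is applied on the
    penultimate stage for depths >= 2 (the staged schedule reported for
    depths two and three).
    """
    if not 0 <= depth <= n_down_blocks:
        raise ValueError(f"freezing depth {depth} exceeds encoder depth {n_down_blocks}")
    stages = []
    for i in range(depth + 1):
        frozen = frozenset(range(1, depth - i + 1))
        last = i == depth
        penultimate = i == depth - 1
        stages.append(
            StageSpec(
                frozen_blocks=frozen,
                learning_rate=lr_final if last else lr_early,
                decay_rate=decay if (penultimate and depth >= 2) else 0.0,
                n_epochs=n_epochs_per_stage,
            )
        )
    return FreezePlan(stages=tuple(stages))


def effective_lr(lr: float, decay: float, epoch: int) -> float:
    """Inverse-time decay: lr / (1 + decay * epoch)."""
    return lr / (1.0 + decay * epoch)


def train_supervised(
    model: UNet,
    examples,
    n_epochs: int,
    lr: float,
    rng: np.random.Generator,
    batch_size: int = 8,
    decay: float = 0.0,
    augment_fn=None,
    val_examples=None,
) -> dict:
    """Plain SGD training on a list of segmentation examples.

    Shuffles each epoch, optionally augments each drawn example, and logs
    per-epoch mean training loss, the effective learning rate, and (when a
    validation split is given) validation loss.  Frozen blocks, if any are
    set on the model, are respected by the SGD step.
    """
    from ..metrics import one_hot

    history = {"epoch": [], "loss": [], "lr": [], "val_loss": []}
    examples = list(examples)
    if not examples:
        raise ValueError("empty training set")
    k = model.spec.n_classes
    for epoch in range(n_epochs):
        lr_e = effective_lr(lr, decay, epoch)
        order = rng.permutation(len(examples))
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            exs = [examples[i] for i in idx]
            if augment_fn is not None:
                exs = [augment_fn(ex, rng) for ex in exs]
            x = np.stack([ex.image for ex in exs])
            y = np.stack([one_hot(ex.mask, k) for ex in exs])
            loss, _ = model.loss_and_grad_flat(x, y, train=True, update_bn_stats=True)
            model.sgd_step(lr_e)
            losses.append(loss)
        history["epoch"].append(epoch)
        history["loss"].append(float(np.mean(losses)))
        history["lr"].append(lr_e)
        if val_examples:
            x = np.stack([ex.image for ex in val_examples])
            y = np.stack([one_hot(ex.mask, k) for ex in val_examples])
            probs = model.forward(x, train=False)
            eps = 1e-7
            n_pix = probs.shape[0] * probs.shape[2] * probs.shape[3]
            history["val_loss"].append(
                float(-np.sum(y * np.log(np.clip(probs, eps, 1.0))) / n_pix)
            )
        else:
            history["val_loss"].append(float("nan"))
    return history


def run_freeze_stage(
    model: UNet,
    stage: StageSpec,
    dataset,
    rng: np.random.Generator,
    batch_size: int = 8,
    augment_fn=None,
    val_examples=None,
) -> dict:
    """Train one stage with its frozen-block set; returns the stage history."""
    model.set_frozen_blocks(stage.frozen_blocks)
    try:
        return train_supervised(
            model,
            dataset,
            n_epochs=stage.n_epochs,
            lr=stage.learning_rate,
            rng=rng,
            batch_size=batch_size,
            decay=stage.decay_rate,
            augment_fn=augment_fn,
            val_examples=val_examples,
        )
    finally:
        model.set_frozen_blocks(frozenset())


def fine_tune_layer_freezing(
    model: UNet,
    plan: FreezePlan,
    target_train_set,
    rng: np.random.Generator,
    batch_size: int = 8,
    augment_fn=None,
    val_examples=None,
) -> list:
    """Run the plan's stages sequentially on the same target training set."""
    histories = []
    for stage in plan.stages:
        histories.append(
            run_freeze_stage(
                model, stage, target_train_set, rng,
                batch_size=batch_size, augment_fn=augment_fn, val_examples=val_examples,
            )
        )
    return histories
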