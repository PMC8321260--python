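"""Configurable 2-D U-Net with hand-written backpropagation.

Encoder of down-sampling blocks (two padded 3x3 conv + BN + ReLU, then 2x2
max-pool), a two-conv bottleneck, and a mirrored decoder whose pooling is
replaced by 2x2 stride-2 transposed convolutions; skip connections
concatenate the pre-pool encoder features with the upsampled decoder
features at matching depth.  The head is a 1x1 convolution producing either
a K-class softmax map or a single sigmoid logit (binary tasks), in both
cases exposed as per-pixel class probabilities that sum to one.

Channel widths are configurable.  ``UNetSpec.reference()`` is the
full-scale configuration whose trainable-parameter total is 4,320,609;
the per-stage widths there are a reconstruction (see docs/methods.md), as
the figure that defines them gives no numbers in text form.
``UNetSpec.tiny()`` is the desk-scale preset used by tests and the
synthetic benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import DTYPE, BatchNorm2d, Conv2d, ConvTranspose2d, MaxPool2d, ReLU

__all__ = [
    "UNetSpec",
    "UNet",
    "count_parameters",
    "build_unet",
    "calibrate_bn_stats",
    "SegmentationObjective",
]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture hyper-parameters of the U-Net."""

    n_down_blocks: int = 4
    base_channels: int = 16
    in_channels: int = 1
    n_classes: int = 2
    input_size: tuple = (256, 256)
    encoder_channels: tuple | None = None  # explicit per-block widths
    bottleneck_channels: int | None = None
    sigmoid_head: bool = False
    up_keep_channels: bool = False  # transposed convs preserve width

    def __post_init__(self):
        h, w = self.input_size
        f = 2 ** self.n_down_blocks
        if h % f or w % f:
            raise ValueError(f"input size {self.input_size} not divisible by {f}")
        if self.encoder_channels is not None and len(self.encoder_channels) != self.n_down_blocks:
            raise ValueError("encoder_channels length must equal n_down_blocks")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes (background + foreground)")

    @property
    def widths(self) -> tuple:
        if self.encoder_channels is not None:
            return tuple(self.encoder_channels)
        return tuple(self.base_channels * 2 ** i for i in range(self.n_down_blocks))

    @property
    def bottleneck(self) -> int:
        if self.bottleneck_channels is not None:
            return self.bottleneck_channels
        return 2 * self.widths[-1]

    @classmethod
    def reference(cls) -> "UNetSpec":
        """Full-scale configuration; 4,320,609 trainable parameters."""
        return cls(
            n_down_blocks=4,
            in_channels=1,
            n_classes=2,
            input_size=(256, 256),
            encoder_channels=(28, 59, 114, 226),
            bottleneck_channels=226,
            sigmoid_head=True,
            up_keep_channels=True,
        )

    @classmethod
    def tiny(cls) -> "UNetSpec":
        """Small preset for tests and the synthetic benchmark."""
        return cls(n_down_blocks=2, base_channels=8, input_size=(32, 32))


class _ConvBlock:
    """Two conv-BN-ReLU units, the repeating motif of every U-Net block."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.relu2 = ReLU()

    def layers(self):
        return [self.conv1, self.bn1, self.conv2, self.bn2]

    def forward(self, x, train, upd):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x), train, upd))
        return self.relu2.forward(self.bn2.forward(self.conv2.forward(h), train, upd))

    def backward(self, dy):
        dh = self.conv2.backward(self.bn2.backward(self.relu2.backward(dy)))
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(dh)))


class UNet:
    """The segmentation model; parameters round-trip to a flat vector."""

    def __init__(self, spec: UNetSpec, rng: np.random.Generator | int | None = None):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.spec = spec
        ws = spec.widths
        self.enc_blocks = []
        c_in = spec.in_channels
        for w in ws:
            self.enc_blocks.append(_ConvBlock(c_in, w, rng))
            c_in = w
        self.pools = [MaxPool2d() for _ in ws]
        self.bottleneck = _ConvBlock(ws[-1], spec.bottleneck, rng)
        self.ups = []
        self.dec_blocks = []
        prev = spec.bottleneck
        for w in reversed(ws):
            up_out = prev if spec.up_keep_channels else w
            self.ups.append(ConvTranspose2d(prev, up_out, rng))
            self.dec_blocks.append(_ConvBlock(up_out + w, w, rng))
            prev = w
        n_out = 1 if spec.sigmoid_head else spec.n_classes
        self.head = Conv2d(ws[0], n_out, 1, rng)
        self._frozen_blocks: frozenset = frozenset()
        self._index = self._build_index()

    # ----- parameter plumbing -------------------------------------------------

    def _param_layers(self):
        """Ordered (block_id, layer) pairs; block_id is the 1-based encoder
        block for freezable layers and 0 elsewhere."""
        out = []
        for i, blk in enumerate(self.enc_blocks, start=1):
            out.extend((i, lyr) for lyr in blk.layers())
        out.extend((0, lyr) for lyr in self.bottleneck.layers())
        for up, blk in zip(self.ups, self.dec_blocks):
            out.append((0, up))
            out.extend((0, lyr) for lyr in blk.layers())
        out.append((0, self.head))
        return out

    def _build_index(self):
        index = []
        offset = 0
        for block_id, lyr in self._param_layers():
            for key, arr in lyr.params.items():
                index.append((block_id, lyr, key, offset, offset + arr.size))
                offset += arr.size
        self._n_params = offset
        return index

    @property
    def n_params(self) -> int:
        return self._n_params

    def count_parameters(self) -> int:
        """Exact number of trainable scalars (BN running stats excluded)."""
        return self._n_params

    def get_flat(self) -> np.ndarray:
        out = np.empty(self._n_params, dtype=DTYPE)
        for _, lyr, key, a, b in self._index:
            out[a:b] = lyr.params[key].ravel()
        return out

    def set_flat(self, theta: np.ndarray):
        if theta.size != self._n_params:
            raise ValueError(f"expected {self._n_params} parameters, got {theta.size}")
        for _, lyr, key, a, b in self._index:
            lyr.params[key][...] = theta[a:b].reshape(lyr.params[key].shape).astype(DTYPE)

    def get_flat_grads(self) -> np.ndarray:
        out = np.empty(self._n_params, dtype=DTYPE)
        for block_id, lyr, key, a, b in self._index:
            if block_id in self._frozen_blocks:
                out[a:b] = 0.0
            else:
                out[a:b] = lyr.grads[key].ravel()
        return out

    def zero_grads(self):
        for _, lyr in self._param_layers():
            lyr.zero_grads()

    # ----- freezing -----------------------------------------------------------

    def set_frozen_blocks(self, blocks):
        """Freeze the given 1-based encoder blocks (params + BN statistics)."""
        blocks = frozenset(int(b) for b in blocks)
        bad = [b for b in blocks if not 1 <= b <= len(self.enc_blocks)]
        if bad:
            raise ValueError(f"no encoder block(s) {bad}")
        self._frozen_blocks = blocks
        for i, blk in enumerate(self.enc_blocks, start=1):
            frozen = i in blocks
            blk.bn1.frozen = frozen
            blk.bn2.frozen = frozen

    @property
    def frozen_blocks(self) -> frozenset:
        return self._frozen_blocks

    def block_param_slices(self, block_id: int):
        """Flat-vector slices owned by one encoder block (for assertions)."""
        return [(a, b) for bid, _, _, a, b in self._index if bid == block_id]

    # ----- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False, update_bn_stats: bool | None = None):
        """Per-pixel class probabilities, shape (N, K, H, W)."""
        if update_bn_stats is None:
            update_bn_stats = train
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 3:
            x = x[:, None]
        h = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # to channels-last
        self._skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, train, update_bn_stats)
            self._skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h, train, update_bn_stats)
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(self._skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=-1)
            h = blk.forward(h, train, update_bn_stats)
        z = self.head.forward(h)  # (N, H, W, n_out)
        if self.spec.sigmoid_head:
            p = 1.0 / (1.0 + np.exp(-z[..., 0]))
            probs = np.stack([1.0 - p, p], axis=-1)
        else:
            z = z - z.max(axis=-1, keepdims=True)
            e = np.exp(z)
            probs = e / e.sum(axis=-1, keepdims=True)
        return np.ascontiguousarray(probs.transpose(0, 3, 1, 2))

    def _backward_from_dlogits(self, dz: np.ndarray) -> None:
        """dz is channels-last (N, H, W, n_out)."""
        dh = self.head.backward(dz)
        skip_grads = []
        for up, blk in zip(reversed(self.ups), reversed(self.dec_blocks)):
            dcat = blk.backward(dh)
            w_skip = blk.conv1.c_in - up.c_out
            skip_grads.append(dcat[..., :w_skip])
            dh = up.backward(np.ascontiguousarray(dcat[..., w_skip:]))
        dh = self.bottleneck.backward(dh)
        # skip_grads were collected shallowest-first; encoder unwinds deepest-first
        for blk, pool, ds in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(skip_grads)
        ):
            dh = pool.backward(dh) + ds
            dh = blk.backward(dh)

    def loss_and_grad_flat(
        self,
        x: np.ndarray,
        y_onehot: np.ndarray,
        train: bool = True,
        update_bn_stats: bool = False,
        class_weights=None,
    ) -> tuple[float, np.ndarray]:
        """Per-example pixel-summed cross-entropy (batch mean) and its flat
        parameter gradient.

        The loss is unweighted by default (the 0.9/0.1 class ratio enters
        the Dice metric, not training); ``class_weights`` optionally weights
        each pixel's term by the weight of its true class.
        """
        probs = self.forward(x, train=train, update_bn_stats=update_bn_stats)
        y = np.ascontiguousarray(y_onehot, dtype=DTYPE)
        if probs.shape != y.shape:
            raise ValueError(f"probs {probs.shape} vs one-hot targets {y.shape}")
        # loss is summed over pixels and averaged over the batch; with this
        # reduction the stated learning rates (1e-3 / 1e-4) take steps of a
        # useful size under plain SGD
        n_b = probs.shape[0]
        eps = 1e-7
        if class_weights is not None:
            w = np.asarray(
                class_weights.weights if hasattr(class_weights, "weights") else class_weights,
                dtype=DTYPE,
            )
            pix_w = np.einsum("nkhw,k->nhw", y, w)[:, None]  # weight of the true class
        else:
            pix_w = np.float32(1.0)
        loss = float(-np.sum(pix_w * y * np.log(np.clip(probs, eps, 1.0))) / n_b)
        if self.spec.sigmoid_head:
            dz = ((pix_w[:, 0] if class_weights is not None else 1.0)
                  * (probs[:, 1] - y[:, 1]) / n_b)[..., None].astype(DTYPE)
        else:
            dz = np.ascontiguousarray(
                (pix_w * (probs - y) / n_b).transpose(0, 2, 3, 1)
            ).astype(DTYPE)
        self.zero_grads()
        self._backward_from_dlogits(dz)
        return loss, self.get_flat_grads()

    def sgd_step(self, lr: float):
        """In-place SGD update from accumulated grads; frozen blocks skipped."""
        for block_id, lyr, key, a, b in self._index:
            if block_id in self._frozen_blocks:
                continue
            lyr.params[key] -= DTYPE(lr) * lyr.grads[key]

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Eval-mode class probabilities for a stack of images."""
        return self.forward(images, train=False)


def calibrate_bn_stats(model: UNet, examples, rng: np.random.Generator,
                       n_passes: int = 10, batch_size: int = 8) -> None:
    """Refresh BN running statistics by forward passes over ``examples``.

    Meta-training treats the objective as a pure function of (theta, batch)
    and therefore never advances running statistics; a meta-learned
    initialization must have its statistics re-estimated before frozen-BN
    fine-tuning or eval-mode inference.  Resets the moments, then runs
    ``n_passes`` shuffled epochs of training-mode forwards with a cumulative
    (1/t) moving average, so the result is the exact mean of the observed
    batch moments rather than a slowly-converging exponential average.
    """
    bns = [lyr for _, lyr in model._param_layers() if isinstance(lyr, BatchNorm2d)]
    saved_momentum = [lyr.momentum for lyr in bns]
    for lyr in bns:
        lyr.running_mean[...] = 0.0
        lyr.running_var[...] = 0.0
    examples = list(examples)
    t = 0
    try:
        for _ in range(n_passes):
            order = rng.permutation(len(examples))
            for start in range(0, len(order), batch_size):
                chunk = [examples[i] for i in order[start : start + batch_size]]
                x = np.stack([ex.image for ex in chunk])
                for lyr in bns:
                    lyr.momentum = 1.0 / (t + 1)
                model.forward(x, train=True, update_bn_stats=True)
                t += 1
    finally:
        for lyr, m in zip(bns, saved_momentum):
            lyr.momentum = m


def build_unet(spec: UNetSpec, rng=None) -> UNet:
    """Construct a seed-reproducible U-Net from its spec."""
    return UNet(spec, rng)


def count_parameters(model: UNet) -> int:
    return model.count_parameters()


class SegmentationObjective:
    """Adapter exposing the U-Net + cross-entropy as a meta-learning objective.

    Batch-statistic BN is used during adaptation but running statistics are
    not advanced, so the objective is a pure function of (theta, batch).
    """

    def __init__(self, model: UNet, augment_fn=None, rng: np.random.Generator | None = None):
        self.model = model
        self.augment_fn = augment_fn
        self.rng = rng

    def _stack(self, batch):
        from ..metrics import one_hot

        exs = list(batch.examples)
        if self.augment_fn is not None:
            exs = [self.augment_fn(ex, self.rng) for ex in exs]
        x = np.stack([ex.image for ex in exs]).astype(DTYPE)
        y = np.stack([one_hot(ex.mask, self.model.spec.n_classes) for ex in exs]).astype(DTYPE)
        return x, y

    def value_and_grad(self, theta: np.ndarray, batch) -> tuple[float, np.ndarray]:
        x, y = self._stack(batch)
        self.model.set_flat(theta)
        return self.model.loss_and_grad_flat(x, y, train=True, update_bn_stats=False)
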