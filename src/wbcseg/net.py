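"""Encoder-decoder per-pixel segmentation network, implemented in NumPy.

The architecture follows the classic U-shaped design: a VGG-style encoder
produces five effective feature layers at successively halved resolution;
the decoder doubles the spatial resolution at each step (nearest-neighbour
upsampling) and concatenates the matching encoder feature layer before two
3×3 convolutions; a final 1×1 convolution classifies every pixel.  Training
supports the freeze/thaw schedule used for transfer learning: the encoder is
held fixed for the first ``freeze_epochs`` epochs and released afterwards.

The implementation is deliberately self-contained — im2col convolutions with
explicit backpropagation and an Adam optimiser — sized for CPU-scale
experiments.  The loss is per-pixel cross-entropy with an optional soft-Dice
term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image import RasterImage, as_rgb_unit

__all__ = ["NetworkSpec", "TrainSchedule", "LossCurve", "UNet",
           "build_network", "train", "predict", "save_model", "load_model"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture parameters.

    ``encoder_levels`` is 5 for the reference configuration; the input side
    must be divisible by 2**(encoder_levels - 1).  ``base_filters`` scales
    the whole network (64 for a VGG16-sized encoder, 8 for the test-scale
    preset).
    """

    input_size: tuple = (512, 512)
    encoder_levels: int = 5
    base_filters: int = 64
    num_classes: int = 2

    def __post_init__(self) -> None:
        h, w = self.input_size
        div = 2 ** (self.encoder_levels - 1)
        if h % div or w % div:
            raise ValueError(
                f"input size {self.input_size} must be divisible by {div} "
                f"for {self.encoder_levels} encoder levels"
            )
        if self.encoder_levels < 2:
            raise ValueError("at least two encoder levels are required")
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")

    @classmethod
    def tiny(cls, input_size=(128, 128), num_classes: int = 2) -> "NetworkSpec":
        """Test-scale preset: 128×128 input, 8 base filters."""
        return cls(input_size=tuple(input_size), base_filters=8,
                   num_classes=num_classes)

    @property
    def channels(self) -> tuple:
        # VGG-style doubling, capped at 8x the base width.
        return tuple(min(self.base_filters * 2 ** l, self.base_filters * 8)
                     for l in range(self.encoder_levels))


@dataclass(frozen=True)
class TrainSchedule:
    """Freeze/thaw training schedule.

    The encoder is frozen for ``freeze_epochs`` epochs, then trained for
    ``unfreeze_epochs`` more.  Defaults mirror the reference recipe:
    50 + 50 epochs, batch size 2, initial learning rate 1e-4.
    """

    freeze_epochs: int = 50
    unfreeze_epochs: int = 50
    batch_size: int = 2
    learning_rate: float = 1e-4
    dice_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.freeze_epochs < 0 or self.unfreeze_epochs < 0:
            raise ValueError("epoch counts must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def total_epochs(self) -> int:
        return self.freeze_epochs + self.unfreeze_epochs


@dataclass
class LossCurve:
    """Per-epoch training and validation losses."""

    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)

    def append(self, epoch: int, train: float, val: float) -> None:
        if not (np.isfinite(train) and np.isfinite(val)):
            raise ValueError(f"non-finite loss at epoch {epoch}")
        self.epochs.append(int(epoch))
        self.train_loss.append(float(train))
        self.val_loss.append(float(val))

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"epoch": self.epochs, "train_loss": self.train_loss,
                      "val_loss": self.val_loss}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# layers

class _Conv:
    """Same-padding convolution with im2col forward/backward."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        fan_in = ksize * ksize * cin
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(fan_in, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.ksize = ksize
        self.cin = cin
        self.cout = cout
        self.dW = None
        self.db = None
        self._cols = None
        self._in_shape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.ksize
        p = k // 2
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = sliding_window_view(x, (k, k), axis=(1, 2))
        # (N, H, W, C, k, k) -> (N*H*W, k*k*C)
        n, h, w = cols.shape[:3]
        cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * x.shape[3])
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        self._cols = self._im2col(x)
        n, h, w, _ = x.shape
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, _ = dout.shape
        dflat = dout.reshape(n * h * w, self.cout).astype(np.float32)
        self.dW = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        self._cols = None
        k = self.ksize
        # full correlation of dout with the flipped kernel gives dx
        Wk = self.W.reshape(k, k, self.cin, self.cout)
        Wflip = Wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(k * k * self.cout, self.cin)
        p = k // 2
        dpad = np.pad(dout, ((0, 0), (p, p), (p, p), (0, 0))) if p else dout
        cols = sliding_window_view(dpad, (k, k), axis=(1, 2))
        cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * self.cout)
        dx = np.ascontiguousarray(cols, dtype=np.float32) @ Wflip
        return dx.reshape(self._in_shape)


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class _MaxPool2:
    def forward(self, x):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, h // 2, w // 2, c, 4)
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._in_shape
        grid = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(grid, self._idx[..., None], dout[..., None], axis=-1)
        grid = grid.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return grid.reshape(n, h, w, c)


class _Upsample2:
    def forward(self, x):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout):
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# model

class UNet:
    """Five-level encoder / upsample-and-concatenate decoder / pixel classifier."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.channels
        L = spec.encoder_levels

        self.enc_blocks = []
        cin = 3
        for l in range(L):
            block = [_Conv(cin, ch[l], 3, rng), _ReLU(),
                     _Conv(ch[l], ch[l], 3, rng), _ReLU()]
            self.enc_blocks.append(block)
            cin = ch[l]
        self.pools = [_MaxPool2() for _ in range(L - 1)]

        self.dec_blocks = []
        self.ups = []
        for l in range(L - 2, -1, -1):
            self.ups.append(_Upsample2())
            cin_dec = ch[l + 1] + ch[l]
            block = [_Conv(cin_dec, ch[l], 3, rng), _ReLU(),
                     _Conv(ch[l], ch[l], 3, rng), _ReLU()]
            self.dec_blocks.append(block)
        self.head = _Conv(ch[0], spec.num_classes, 1, rng)

    # -- parameter access -------------------------------------------------
    def parameters(self) -> dict:
        """Named parameter arrays; encoder names start with ``enc``."""
        params = {}
        for i, block in enumerate(self.enc_blocks):
            for j, layer in enumerate(block):
                if isinstance(layer, _Conv):
                    params[f"enc{i}.conv{j}.W"] = layer.W
                    params[f"enc{i}.conv{j}.b"] = layer.b
        for i, block in enumerate(self.dec_blocks):
            for j, layer in enumerate(block):
                if isinstance(layer, _Conv):
                    params[f"dec{i}.conv{j}.W"] = layer.W
                    params[f"dec{i}.conv{j}.b"] = layer.b
        params["head.W"] = self.head.W
        params["head.b"] = self.head.b
        return params

    def _conv_layers(self):
        out = []
        for i, block in enumerate(self.enc_blocks):
            for layer in block:
                if isinstance(layer, _Conv):
                    out.append((f"enc{i}", layer))
        for i, block in enumerate(self.dec_blocks):
            for layer in block:
                if isinstance(layer, _Conv):
                    out.append((f"dec{i}", layer))
        out.append(("head", self.head))
        return out

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits of shape (N, H, W, num_classes) for input (N, H, W, 3)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for l, block in enumerate(self.enc_blocks):
            for layer in block:
                x = layer.forward(x)
            if l < len(self.pools):
                skips.append(x)
                x = self.pools[l].forward(x)
        self._skip_channels = [s.shape[-1] for s in skips]
        for i, block in enumerate(self.dec_blocks):
            x = self.ups[i].forward(x)
            skip = skips[-(i + 1)]
            x = np.concatenate([x, skip], axis=-1)
            for layer in block:
                x = layer.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = [None] * len(self.pools)
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            for layer in reversed(self.dec_blocks[i]):
                d = layer.backward(d)
            up_ch = d.shape[-1] - self._skip_channels[-(i + 1)]
            dskips[len(self.pools) - 1 - i] = d[..., up_ch:]
            d = self.ups[i].backward(np.ascontiguousarray(d[..., :up_ch]))
        for l in range(len(self.enc_blocks) - 1, -1, -1):
            if l < len(self.pools):
                d = self.pools[l].backward(d)
                d = d + dskips[l]
            for layer in reversed(self.enc_blocks[l]):
                d = layer.backward(d)


def build_network(spec: NetworkSpec, seed: int = 0) -> UNet:
    """Construct a network with deterministic, seed-controlled initialisation."""
    return UNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# loss

def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _loss_and_grad(logits: np.ndarray, masks: np.ndarray, dice_weight: float = 0.0):
    """Mean per-pixel cross-entropy (plus optional soft-Dice term) and its
    gradient with respect to the logits."""
    probs = _softmax(logits.astype(np.float64))
    n_pix = masks.size
    onehot = np.eye(logits.shape[-1], dtype=np.float64)[masks]
    ce = -np.log(np.maximum((probs * onehot).sum(axis=-1), 1e-12)).mean()
    dprobs_ce = None  # CE gradient taken directly in logit space
    dlogits = (probs - onehot) / n_pix
    loss = ce
    if dice_weight > 0.0:
        p_fg = probs[..., 1]
        t_fg = (masks == 1).astype(np.float64)
        eps = 1.0
        inter = (p_fg * t_fg).sum()
        total = p_fg.sum() + t_fg.sum()
        soft_dice = (2 * inter + eps) / (total + eps)
        loss = ce + dice_weight * (1.0 - soft_dice)
        dD_dp = (2 * t_fg * (total + eps) - (2 * inter + eps)) / (total + eps) ** 2
        dL_dp = -dice_weight * dD_dp  # gradient w.r.t. foreground probability
        # chain through softmax: dlogit_k = p_k * (g_k - sum_j g_j p_j)
        g = np.zeros_like(probs)
        g[..., 1] = dL_dp
        dot = (g * probs).sum(axis=-1, keepdims=True)
        dlogits = dlogits + probs * (g - dot)
    return loss, dlogits.astype(np.float32)


# ---------------------------------------------------------------------------
# training

class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.t = 0
        self.m = {}
        self.v = {}

    def step(self, convs, frozen_prefixes=()):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for name, layer in convs:
            if any(name.startswith(p) for p in frozen_prefixes):
                continue
            for pname in ("W", "b"):
                g = layer.dW if pname == "W" else layer.db
                if g is None:
                    continue
                key = f"{name}.{id(layer)}.{pname}"
                m = self.m.get(key, 0.0) * b1 + (1 - b1) * g
                v = self.v.get(key, 0.0) * b2 + (1 - b2) * g * g
                self.m[key] = m
                self.v[key] = v
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                upd = self.lr * mhat / (np.sqrt(vhat) + eps)
                if pname == "W":
                    layer.W -= upd.astype(layer.W.dtype)
                else:
                    layer.b -= upd.astype(layer.b.dtype)


def _coerce_sample(sample, spec: NetworkSpec):
    img, mask = sample[0], sample[1]
    x = as_rgb_unit(img).astype(np.float32)
    m = np.asarray(mask)
    if m.dtype == bool:
        m = m.astype(np.int64)
    if x.shape[:2] != tuple(spec.input_size):
        raise ValueError(
            f"image size {x.shape[:2]} does not match network input "
            f"{tuple(spec.input_size)}"
        )
    if m.shape != x.shape[:2]:
        raise ValueError("mask shape does not match image shape")
    return x, m.astype(np.int64)


def _dataset_loss(model: UNet, data, dice_weight: float, batch: int) -> float:
    losses, weights = [], []
    for i in range(0, len(data), batch):
        xs = np.stack([d[0] for d in data[i:i + batch]])
        ms = np.stack([d[1] for d in data[i:i + batch]])
        loss, _ = _loss_and_grad(model.forward(xs), ms, dice_weight)
        losses.append(loss)
        weights.append(len(xs))
    return float(np.average(losses, weights=weights))


def train(model: UNet, train_set, val_set=None,
          schedule: TrainSchedule | None = None):
    """Train a network under the freeze/thaw schedule.

    ``train_set`` and ``val_set`` are sequences of (image, mask) pairs (a
    third metadata element is tolerated and ignored).  The encoder is frozen
    for the first ``freeze_epochs`` epochs.  Returns ``(model, LossCurve)``.
    When ``val_set`` is None the training set doubles as validation.
    """
    if schedule is None:
        schedule = TrainSchedule()
    if not train_set:
        raise ValueError("training set must be nonempty")
    data = [_coerce_sample(s, model.spec) for s in train_set]
    val = [_coerce_sample(s, model.spec) for s in val_set] if val_set else data

    rng = np.random.default_rng(schedule.seed)
    opt = _Adam(schedule.learning_rate)
    convs = model._conv_layers()
    curve = LossCurve()

    for epoch in range(schedule.total_epochs):
        frozen = ("enc",) if epoch < schedule.freeze_epochs else ()
        order = rng.permutation(len(data))
        batch_losses, batch_sizes = [], []
        for i in range(0, len(order), schedule.batch_size):
            idx = order[i:i + schedule.batch_size]
            xs = np.stack([data[j][0] for j in idx])
            ms = np.stack([data[j][1] for j in idx])
            loss, dlogits = _loss_and_grad(model.forward(xs), ms,
                                           schedule.dice_weight)
            model.backward(dlogits)
            opt.step(convs, frozen_prefixes=frozen)
            batch_losses.append(loss)
            batch_sizes.append(len(idx))
        train_loss = float(np.average(batch_losses, weights=batch_sizes))
        val_loss = _dataset_loss(model, val, schedule.dice_weight,
                                 schedule.batch_size)
        curve.append(epoch, train_loss, val_loss)
    return model, curve


def save_model(model: UNet, path) -> None:
    """Checkpoint the parameters with the architecture spec embedded."""
    import json
    meta = json.dumps({"input_size": list(model.spec.input_size),
                       "encoder_levels": model.spec.encoder_levels,
                       "base_filters": model.spec.base_filters,
                       "num_classes": model.spec.num_classes})
    np.savez(path, __spec__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.parameters())


def load_model(path) -> UNet:
    """Rebuild a network from a checkpoint written by :func:`save_model`."""
    import json
    with np.load(path) as data:
        meta = json.loads(bytes(data["__spec__"]).decode())
        spec = NetworkSpec(input_size=tuple(meta["input_size"]),
                           encoder_levels=meta["encoder_levels"],
                           base_filters=meta["base_filters"],
                           num_classes=meta["num_classes"])
        model = UNet(spec)
        for name, arr in model.parameters().items():
            arr[...] = data[name]
    return model


def predict(model: UNet, image, resize: bool = False):
    """Per-pixel class probabilities and argmax mask for one image.

    The image must match the network input size unless ``resize`` is set, in
    which case it is resampled in and the mask is resampled back out
    (nearest neighbour) to the original shape.
    """
    x = as_rgb_unit(image).astype(np.float32)
    orig_shape = x.shape[:2]
    target = tuple(model.spec.input_size)
    if orig_shape != target:
        if not resize:
            raise ValueError(
                f"image size {orig_shape} does not match network input {target}; "
                "pass resize=True to resample"
            )
        from skimage.transform import resize as _resize
        x = _resize(x, target, order=1, preserve_range=True,
                    anti_aliasing=True).astype(np.float32)
    logits = model.forward(x[None])
    probs = _softmax(logits.astype(np.float64))[0]
    mask = probs.argmax(axis=-1)
    if orig_shape != target:
        from skimage.transform import resize as _resize
        probs = _resize(probs, orig_shape, order=1, preserve_range=True)
        probs = probs / probs.sum(axis=-1, keepdims=True)
        mask = _resize(mask.astype(np.float64), orig_shape, order=0,
                       preserve_range=True).astype(np.int64)
    return probs, mask
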