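"""Enhancement U-Net, counting CNN, training recipes and augmentation.

Two networks form the cascade:

* an encoder/decoder image-regression network ("enhancer") trained with MSE to
  map a normalized T2 part onto its contrast-boosted target, and
* a five-conv-layer regression network ("quantifier") with global average
  pooling and a single linear output unit, trained with MAE on counts
  normalized by the maximum count.

Training presets: ``paper`` is the full-scale recipe (64 base filters,
Adam 1e-4, batch 45, 500/300 epochs, flip/scale/rotation augmentation);
``desk`` (16 base filters, 50/30 epochs, batch 16) and ``mini`` (8 base
filters, reduced depth) are CPU-scale presets for interactive work and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi

from . import nn
from .nn import F32

IMAGE_SHAPE = (80, 96)
COUNT_MAX_DEFAULT = 48


# ---------------------------------------------------------------------------
# Architecture descriptions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnhancerArch:
    """U-Net shape: ``depth`` pooling levels, ``base_filters`` at the top level,
    two 3x3 conv+BN+ReLU blocks per level, transpose-conv upsampling with
    concatenated skip connections, 1x1 conv + sigmoid output head."""

    depth: int = 4
    base_filters: int = 64
    in_channels: int = 1

    def __post_init__(self):
        h, w = IMAGE_SHAPE
        if h % (2**self.depth) or w % (2**self.depth):
            raise ValueError(f"depth {self.depth} does not divide image shape {IMAGE_SHAPE}")


QUANTIFIER_FILTERS = (64, 64, 128, 128, 256)


@dataclass(frozen=True)
class QuantifierArch:
    """Five conv+BN+ReLU layers (64,64,128,128,256 filters at full width),
    2x2 max-pool after layers 2 and 4, global average pooling, one linear unit."""

    width: float = 1.0

    @property
    def conv_filters(self) -> tuple[int, ...]:
        return tuple(max(1, round(f * self.width)) for f in QUANTIFIER_FILTERS)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 45
    epochs_enhancer: int = 500
    epochs_quantifier: int = 300
    augment: bool = True
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_deg: float = 15.0
    seed: int = 0
    enhancer: EnhancerArch = field(default_factory=EnhancerArch)
    quantifier: QuantifierArch = field(default_factory=QuantifierArch)


PRESETS: dict[str, TrainConfig] = {
    "paper": TrainConfig(),
    "desk": TrainConfig(
        batch_size=16,
        epochs_enhancer=50,
        epochs_quantifier=30,
        enhancer=EnhancerArch(depth=4, base_filters=16),
        quantifier=QuantifierArch(width=0.25),
    ),
    "mini": TrainConfig(
        learning_rate=2e-3,
        batch_size=16,
        epochs_enhancer=60,
        epochs_quantifier=60,
        scale_range=(1.0, 1.0),  # flips only: keeps geometry exact at small n
        rotation_deg=0.0,
        enhancer=EnhancerArch(depth=2, base_filters=8),
        quantifier=QuantifierArch(width=0.125),
    ),
}


def preset(name: str, **overrides) -> TrainConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def _double_conv(cin: int, cout: int, rng) -> nn.Sequential:
    return nn.Sequential(
        [
            nn.Conv3x3(cin, cout, rng),
            nn.BatchNorm2d(cout),
            nn.ReLU(),
            nn.Conv3x3(cout, cout, rng),
            nn.BatchNorm2d(cout),
            nn.ReLU(),
        ]
    )


class UNetEnhancer(nn.Layer):
    """Image-to-image regression U-Net with a sigmoid output in [0, 1]."""

    def __init__(self, arch: EnhancerArch, rng: np.random.Generator):
        self.arch = arch
        ch = [arch.base_filters * 2**l for l in range(arch.depth + 1)]
        self.enc = []
        cin = arch.in_channels
        for l in range(arch.depth):
            self.enc.append(_double_conv(cin, ch[l], rng))
            cin = ch[l]
        self.pools = [nn.MaxPool2x2() for _ in range(arch.depth)]
        self.bottleneck = _double_conv(ch[arch.depth - 1], ch[arch.depth], rng)
        self.ups = []
        self.dec = []
        for l in reversed(range(arch.depth)):
            self.ups.append(nn.ConvTranspose2x2(ch[l + 1], ch[l], rng))
            self.dec.append(_double_conv(2 * ch[l], ch[l], rng))
        self.head = nn.Conv1x1(ch[0], 1, rng)
        self.out_act = nn.Sigmoid()

    def sublayers(self):
        return [*self.enc, *self.pools, self.bottleneck, *self.ups, *self.dec, self.head, self.out_act]

    def params(self):
        return [p for l in self.sublayers() for p in l.params()]

    def forward(self, x, train=True):
        d = 2**self.arch.depth
        if x.shape[1] % d or x.shape[2] % d:
            raise ValueError(f"input {x.shape[1]}x{x.shape[2]} not divisible by 2^depth={d}")
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._split = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._split.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            x = dec.forward(x, train)
        x = self.head.forward(x, train)
        return self.out_act.forward(x, train)

    def backward(self, dy):
        dy = self.out_act.backward(dy)
        dy = self.head.backward(dy)
        dskips = []
        for up, dec, csk in zip(reversed(self.ups), reversed(self.dec), reversed(self._split)):
            d = dec.backward(dy)
            dsk, dup = d[..., :csk], d[..., csk:]
            dskips.append(dsk)
            dy = up.backward(np.ascontiguousarray(dup))
        dy = self.bottleneck.backward(dy)
        for enc, pool, dsk in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            dy = pool.backward(dy)
            dy = enc.backward(dy + dsk)
        return dy


class CountQuantifier(nn.Layer):
    """Five-layer conv net with GAP and one linear output unit (normalized count)."""

    def __init__(self, arch: QuantifierArch, rng: np.random.Generator):
        self.arch = arch
        f = arch.conv_filters
        layers: list[nn.Layer] = []
        cin = 1
        for i, cout in enumerate(f):
            layers += [nn.Conv3x3(cin, cout, rng), nn.BatchNorm2d(cout), nn.ReLU()]
            if i in (1, 3):  # pool after conv layers 2 and 4
                layers.append(nn.MaxPool2x2())
            cin = cout
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Dense(f[-1], 1, rng))
        self.net = nn.Sequential(layers)

    def sublayers(self):
        return [self.net]

    def params(self):
        return self.net.params()

    def forward(self, x, train=True):
        return self.net.forward(x, train)

    def backward(self, dy):
        return self.net.backward(dy)


def parameter_count(model: nn.Layer) -> int:
    return int(sum(p.value.size for p in model.params()))


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentDraw:
    flip_x: bool
    flip_y: bool
    scale: float
    angle_deg: float


def draw_augment(rng: np.random.Generator, config: TrainConfig) -> AugmentDraw:
    return AugmentDraw(
        flip_x=bool(rng.random() < 0.5),
        flip_y=bool(rng.random() < 0.5),
        scale=float(rng.uniform(*config.scale_range)),
        angle_deg=float(rng.uniform(-config.rotation_deg, config.rotation_deg)),
    )


def apply_augment(image: np.ndarray, draw: AugmentDraw, order: int = 1) -> np.ndarray:
    """Apply flip + zoom-about-center + rotation with zero fill; output clipped to [0,1]."""
    out = image
    if draw.flip_x:
        out = out[:, ::-1]
    if draw.flip_y:
        out = out[::-1, :]
    if draw.angle_deg == 0.0 and draw.scale == 1.0:
        return np.clip(out, 0.0, 1.0).astype(F32)
    theta = np.deg2rad(draw.angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # inverse map: rotate then scale about the image center
    mat = np.array([[c, -s], [s, c]]) / draw.scale
    center = (np.array(out.shape) - 1) / 2.0
    offset = center - mat @ center
    out = ndi.affine_transform(out, mat, offset=offset, order=order, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0).astype(F32)


def augment_pair(inp: np.ndarray, target, rng: np.random.Generator, config: TrainConfig):
    """One geometric draw applied jointly; scalar count labels pass through."""
    draw = draw_augment(rng, config)
    out_in = apply_augment(inp, draw)
    if isinstance(target, np.ndarray) and target.ndim == 2:
        return out_in, apply_augment(target, draw)
    return out_in, target


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def _as_batch(images: list[np.ndarray]) -> np.ndarray:
    return np.stack(images).astype(F32)[..., None]


def _check_images(images, name):
    if len(images) == 0:
        raise ValueError(f"empty {name} set")
    shape = images[0].shape
    for im in images:
        if im.shape != shape:
            raise ValueError(f"inconsistent image shapes in {name}: {im.shape} vs {shape}")


def train_enhancer(pairs: list[tuple[np.ndarray, np.ndarray]], config: TrainConfig):
    """Train the enhancement net with MSE; returns (model, per-epoch loss history)."""
    if not pairs:
        raise ValueError("empty training set")
    inputs = [p[0] for p in pairs]
    targets = [p[1] for p in pairs]
    _check_images(inputs, "input")
    for i, t in zip(inputs, targets):
        if i.shape != t.shape:
            raise ValueError(f"input/target shape mismatch: {i.shape} vs {t.shape}")
    rng = np.random.default_rng(config.seed)
    model = UNetEnhancer(config.enhancer, rng)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    history = _fit(
        model, opt, inputs, targets, rng, config,
        epochs=config.epochs_enhancer, loss_fn=nn.mse_loss, image_targets=True,
    )
    return model, history


def train_quantifier(images: list[np.ndarray], labels: list[float], config: TrainConfig):
    """Train the counting net with MAE on normalized labels; returns (model, history)."""
    _check_images(images, "training")
    if len(images) != len(labels):
        raise ValueError("images and labels must be aligned")
    labels = [float(v) for v in labels]
    for v in labels:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"normalized label {v} outside [0, 1]")
    rng = np.random.default_rng(config.seed)
    model = CountQuantifier(config.quantifier, rng)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    history = _fit(
        model, opt, images, labels, rng, config,
        epochs=config.epochs_quantifier, loss_fn=nn.mae_loss, image_targets=False,
    )
    return model, history


def _fit(model, opt, inputs, targets, rng, config, *, epochs, loss_fn, image_targets):
    n = len(inputs)
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xs, ts = [], []
            for i in idx:
                x, t = inputs[i], targets[i]
                if config.augment:
                    x, t = augment_pair(x, t, rng, config)
                xs.append(x)
                ts.append(t)
            xb = _as_batch(xs)
            if image_targets:
                tb = _as_batch(ts)
            else:
                tb = np.asarray(ts, dtype=F32)[:, None]
            opt.zero_grad()
            pred = model.forward(xb, train=True)
            loss, dloss = loss_fn(pred, tb)
            model.backward(dloss)
            opt.step()
            losses.append(loss)
            weights.append(len(idx))
        history.append(float(np.average(losses, weights=weights)))
    return history


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _check_shape(image: np.ndarray, expected=None):
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    if expected is not None and image.shape != tuple(expected):
        raise ValueError(f"expected image shape {tuple(expected)}, got {image.shape}")


def enhance(model: UNetEnhancer, image: np.ndarray) -> np.ndarray:
    """Apply the trained enhancer to one part image; output stays in [0,1]."""
    _check_shape(image)
    out = model.forward(_as_batch([image]), train=False)
    return np.clip(out[0, :, :, 0], 0.0, 1.0).astype(F32)


def enhance_batch(model: UNetEnhancer, images: list[np.ndarray]) -> list[np.ndarray]:
    if not images:
        return []
    _check_images(images, "inference")
    out = model.forward(_as_batch(images), train=False)
    return [np.clip(out[i, :, :, 0], 0.0, 1.0).astype(F32) for i in range(len(images))]


def predict_count(model: CountQuantifier, image: np.ndarray, count_max: int = COUNT_MAX_DEFAULT):
    """Predict the normalized burden and rescale to a count; clipped to [0, 1]."""
    _check_shape(image)
    raw = float(model.forward(_as_batch([image]), train=False)[0, 0])
    normalized = float(np.clip(raw, 0.0, 1.0))
    return normalized, normalized * count_max


def predict_count_batch(model: CountQuantifier, images: list[np.ndarray], count_max: int = COUNT_MAX_DEFAULT):
    if not images:
        return []
    _check_images(images, "inference")
    raw = model.forward(_as_batch(images), train=False)[:, 0]
    normalized = np.clip(raw, 0.0, 1.0)
    return [(float(v), float(v) * count_max) for v in normalized]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_SCHEMA = 1


def save_checkpoint(path, model, kind: str) -> None:
    """Write weights plus an architecture record so the model can be rebuilt."""
    import json

    if kind == "enhancer":
        meta = {"depth": model.arch.depth, "base_filters": model.arch.base_filters,
                "in_channels": model.arch.in_channels}
    elif kind == "quantifier":
        meta = {"width": model.arch.width}
    else:
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    weights = nn.get_weights(model)
    np.savez(
        path,
        __schema__=np.array(CHECKPOINT_SCHEMA),
        __kind__=np.array(kind),
        __meta__=np.array(json.dumps(meta)),
        **{f"w{i}": w for i, w in enumerate(weights)},
    )


def load_checkpoint(path):
    import json

    with np.load(path, allow_pickle=False) as data:
        schema = int(data["__schema__"])
        if schema != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {schema}")
        kind = str(data["__kind__"])
        meta = json.loads(str(data["__meta__"]))
        weights = [data[f"w{i}"] for i in range(sum(1 for k in data.files if k.startswith("w")))]
    rng = np.random.default_rng(0)  # placeholder init, immediately overwritten
    if kind == "enhancer":
        model = UNetEnhancer(EnhancerArch(**meta), rng)
    else:
        model = CountQuantifier(QuantifierArch(**meta), rng)
    nn.set_weights(model, weights)
    return model, kind
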