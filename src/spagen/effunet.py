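"""U-shaped cup/disc segmentation network with an MBConv encoder.

The encoder is a seven-stage stack of mobile inverted-bottleneck
(MBConv) blocks with squeeze-and-excitation gating after a stride-2
stem, downsampling the input by 32 overall; the decoder mirrors it with
2x2 stride-2 transposed-convolution upsampling, concatenation of the
corresponding encoder feature maps (skip connections) and pairs of
batch-normalized ReLU convolutions, ending in a 1x1 convolution whose
softmax gives per-pixel class scores (background / disc rim / cup) at
the input resolution.

Everything runs on the CPU via the layer library in :mod:`spagen._nn`;
the default widths are deliberately slim so that desk-scale training
(a handful of images, a few hundred steps) is practical.  Encoder
weights are always randomly initialized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from skimage.transform import resize

from . import _nn
from .errors import DegenerateMaskError
from .geometry import LabelMask

# (expansion, kernel, stride, channels, repeats) for the seven encoder stages
_DEFAULT_STAGES = [
    (1, 3, 1, 8, 1),
    (4, 3, 2, 12, 1),
    (4, 5, 2, 16, 1),
    (4, 3, 2, 24, 1),
    (4, 5, 1, 24, 1),
    (4, 5, 2, 32, 1),
    (4, 3, 1, 32, 1),
]


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 3
    n_classes: int = 3
    stem_channels: int = 8
    stages: tuple = tuple(_DEFAULT_STAGES)
    decoder_channels: tuple = (32, 24, 16, 12, 8)
    input_size: tuple = (512, 512)

    def __post_init__(self) -> None:
        if len(self.stages) != 7:
            raise ValueError("the encoder is defined as seven stages")
        if len(self.decoder_channels) != 5:
            raise ValueError("five decoder blocks are required for the x32 factor")


@dataclass
class TrainSpec:
    epochs: int = 200
    batch_size: int = 1
    learning_rate: float = 1e-3
    loss: str = "cross_entropy"  # or "dice"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("cross_entropy", "dice"):
            raise ValueError(f"unknown loss {self.loss!r}")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class _MBConv(_nn.Module):
    """Expand (1x1) -> depthwise (kxk, stride) -> SE -> project (1x1)."""

    def __init__(self, cin, cout, expand, k, stride, rng):
        mid = cin * expand
        self.expand = None
        if expand != 1:
            self.expand = [_nn.Conv2d(cin, mid, 1, rng=rng, bias=False),
                           _nn.BatchNorm2d(mid), _nn.ReLU()]
        self.dw = [_nn.DepthwiseConv2d(mid, k, stride, rng=rng),
                   _nn.BatchNorm2d(mid), _nn.ReLU()]
        self.se = _nn.SEBlock(mid, rng=rng)
        self.project = [_nn.Conv2d(mid, cout, 1, rng=rng, bias=False),
                        _nn.BatchNorm2d(cout)]
        self.residual = stride == 1 and cin == cout

    def _layers(self):
        return (self.expand or []) + self.dw + [self.se] + self.project

    def params(self):
        return [p for layer in self._layers() for p in layer.params()]

    def forward(self, x, train=True):
        self._xin = x
        h = x
        for layer in self._layers():
            h = layer.forward(h, train)
        return h + x if self.residual else h

    def backward(self, dy):
        d = dy
        for layer in reversed(self._layers()):
            d = layer.backward(d)
        return d + dy if self.residual else d


class _DecoderBlock(_nn.Module):
    """x2 transposed-conv upsampling, skip concat, two conv+BN+ReLU."""

    def __init__(self, cin, skip_c, cout, rng):
        self.up = _nn.ConvTranspose2x2(cin, cout, rng=rng)
        self.skip_c = skip_c
        self.convs = [_nn.Conv2d(cout + skip_c, cout, 3, rng=rng, bias=False),
                      _nn.BatchNorm2d(cout), _nn.ReLU(),
                      _nn.Conv2d(cout, cout, 3, rng=rng, bias=False),
                      _nn.BatchNorm2d(cout), _nn.ReLU()]

    def params(self):
        return self.up.params() + [p for l in self.convs for p in l.params()]

    def forward(self, x, skip=None, train=True):
        h = self.up.forward(x, train)
        self._up_c = h.shape[1]
        if skip is not None:
            h = np.concatenate([h, skip], axis=1)
        for layer in self.convs:
            h = layer.forward(h, train)
        return h

    def backward(self, dy):
        d = dy
        for layer in reversed(self.convs):
            d = layer.backward(d)
        if self.skip_c:
            d, dskip = d[:, :self._up_c], d[:, self._up_c:]
        else:
            dskip = None
        return self.up.backward(d), dskip


class EffUnet:
    """The full encoder-decoder network (fully convolutional, factor 32)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.stem_channels
        self.stem = [_nn.Conv2d(config.in_channels, c, 3, stride=2, rng=rng, bias=False),
                     _nn.BatchNorm2d(c), _nn.ReLU()]
        self.stages: list[list[_MBConv]] = []
        for expand, k, stride, cout, repeats in config.stages:
            blocks = []
            for r in range(repeats):
                blocks.append(_MBConv(c, cout, expand, k, stride if r == 0 else 1, rng))
                c = cout
            self.stages.append(blocks)
        skip_cs = [config.stages[0][3], config.stages[1][3],
                   config.stages[2][3], config.stages[4][3]]  # /2, /4, /8, /16
        dec = config.decoder_channels
        cin = config.stages[6][3]
        self.decoder = []
        for i, cout in enumerate(dec):
            skip_c = skip_cs[len(skip_cs) - 1 - i] if i < len(skip_cs) else 0
            self.decoder.append(_DecoderBlock(cin, skip_c, cout, rng))
            cin = cout
        self.head = _nn.Conv2d(cin, config.n_classes, 1, rng=rng)

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[_nn.Param]:
        out = [p for l in self.stem for p in l.params()]
        for stage in self.stages:
            for block in stage:
                out += block.params()
        for block in self.decoder:
            out += block.params()
        out += self.head.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _all_layers(self):
        out = list(self.stem)
        for stage in self.stages:
            for block in stage:
                out += block._layers()
        for block in self.decoder:
            out += [block.up] + block.convs
        out.append(self.head)
        return out

    def buffers(self) -> list[np.ndarray]:
        """Non-trained state (batch-norm running statistics)."""
        bufs = []
        for layer in self._all_layers():
            if isinstance(layer, _nn.BatchNorm2d):
                bufs += [layer.run_mean, layer.run_var]
        return bufs

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()] \
            + [b.copy() for b in self.buffers()]

    def load_state(self, state) -> None:
        params = self.params()
        buffers = self.buffers()
        if len(state) == len(params):  # legacy: parameters only
            targets = params
        else:
            targets = params + buffers
        for t, v in zip(targets, state):
            if isinstance(t, _nn.Param):
                t.value[...] = v
            else:
                t[...] = v

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = x
        for layer in self.stem:
            h = layer.forward(h, train)
        skips = []
        for i, stage in enumerate(self.stages):
            for block in stage:
                h = block.forward(h, train)
            if i in (0, 1, 2, 4):
                skips.append(h)
        self._skips_used = skips
        for i, block in enumerate(self.decoder):
            skip = skips[len(skips) - 1 - i] if i < len(skips) else None
            h = block.forward(h, skip=skip, train=train)
        return self.head.forward(h, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-pixel class probabilities (softmax of the logits)."""
        return _nn.softmax(self.forward_logits(x, train))

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = [None] * 4
        for i, block in enumerate(reversed(self.decoder)):
            d, dskip = block.backward(d)
            j = len(self.decoder) - 1 - i  # decoder index
            if j < 4 and dskip is not None:
                dskips[3 - j] = dskip
        for i in range(len(self.stages) - 1, -1, -1):
            if i in (0, 1, 2, 4):
                k = {0: 0, 1: 1, 2: 2, 4: 3}[i]
                if dskips[k] is not None:
                    d = d + dskips[k]
            for block in reversed(self.stages[i]):
                d = block.backward(d)
        for layer in reversed(self.stem):
            d = layer.backward(d)


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> EffUnet:
    """Construct the network with reproducible (seeded) initialization."""
    return EffUnet(config or NetworkConfig(), seed=seed)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_image(image: np.ndarray, size: tuple[int, int] = (512, 512),
                     border_threshold: int = 10, mask: np.ndarray | None = None):
    """Crop away black borders and resize to ``size``.

    The crop is the bounding box of pixels whose maximum channel value
    reaches ``border_threshold`` (of 255).  Images are resampled with
    smooth interpolation; a label ``mask``, if given, follows the same
    crop with nearest-neighbor resampling and is returned alongside.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    bright = image.max(axis=2) >= border_threshold
    if not bright.any():
        raise DegenerateMaskError("image is entirely black")
    rows = np.nonzero(bright.any(axis=1))[0]
    cols = np.nonzero(bright.any(axis=0))[0]
    box = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    cropped = image[box]
    out = resize(cropped.astype(float), size, order=1, anti_aliasing=True,
                 preserve_range=True)
    out = np.clip(out, 0, 255).astype(np.uint8)
    if mask is None:
        return out
    m = resize(np.asarray(mask)[box], size, order=0, anti_aliasing=False,
               preserve_range=True).astype(np.asarray(mask).dtype)
    return out, m


def _to_batch(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[None]
    if x.max() > 1.5:
        x = x / 255.0
    return x.transpose(0, 3, 1, 2)


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def _dice_loss(logits, labels, n_classes):
    p = _nn.softmax(logits)
    n, k, h, w = logits.shape
    idx_n, idx_h, idx_w = np.ogrid[:n, :h, :w]
    onehot = np.zeros_like(p)
    onehot[idx_n, labels, idx_h, idx_w] = 1.0
    axes = (0, 2, 3)
    inter = (p * onehot).sum(axis=axes)
    sums = p.sum(axis=axes) + onehot.sum(axis=axes)
    d = (2.0 * inter + 1e-7) / (sums + 1e-7)
    loss = float(1.0 - d.mean())
    # dL/dp then pull back through the softmax
    dldp = -(2.0 * onehot * (sums + 1e-7)[None, :, None, None]
             - 2.0 * (2.0 * inter + 1e-7)[None, :, None, None]) \
        / (sums + 1e-7)[None, :, None, None] ** 2 / k
    dlogits = p * (dldp - (dldp * p).sum(axis=1, keepdims=True))
    return loss, dlogits


def train_segmentation(network: EffUnet, images, masks, spec: TrainSpec | None = None,
                       val_images=None, val_masks=None):
    """Train the network on image/mask pairs; keep the best checkpoint.

    One epoch is one pass over the training pairs.  After each epoch the
    per-pixel accuracy on the validation pairs (the training pairs when
    none are given) is measured and the best-scoring weights are
    retained and restored at the end.  Returns the per-step loss trace.
    """
    spec = spec or TrainSpec()
    x = _to_batch(images)
    y = np.asarray(masks)
    if y.ndim == 2:
        y = y[None]
    y = y.astype(np.int64)
    if x.shape[0] != y.shape[0] or x.shape[2:] != y.shape[1:]:
        raise ValueError("images and masks do not match in count or size")
    xv = _to_batch(val_images) if val_images is not None else x
    yv = (np.asarray(val_masks)[None] if np.asarray(val_masks).ndim == 2
          else np.asarray(val_masks)) if val_masks is not None else y

    rng = np.random.default_rng(spec.seed)
    opt = _nn.Adam(network.params(), lr=spec.learning_rate)
    trace: list[float] = []
    best_acc, best_state = -1.0, None
    n = x.shape[0]
    for _epoch in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            sel = order[start:start + spec.batch_size]
            opt.zero_grad()
            logits = network.forward_logits(x[sel], train=True)
            if spec.loss == "dice":
                loss, dlogits = _dice_loss(logits, y[sel], network.config.n_classes)
            else:
                loss, dlogits = _nn.softmax_cross_entropy(logits, y[sel])
            network.backward(dlogits)
            opt.step()
            trace.append(loss)
        pred = network.forward(xv, train=False).argmax(axis=1)
        acc = float((pred == yv).mean())
        if acc > best_acc:
            best_acc, best_state = acc, network.state()
    if best_state is not None:
        network.load_state(best_state)
    return network, trace


def predict_masks(network: EffUnet, image: np.ndarray) -> LabelMask:
    """Per-pixel argmax segmentation of one RGB image, as a LabelMask.

    Inputs whose sides are not divisible by 32 are reflect-padded and the
    prediction cropped back.  The cup is clipped to the disc as in mask
    loading.
    """
    x = _to_batch(image)
    _, _, h, w = x.shape
    ph = (-h) % 32
    pw = (-w) % 32
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    proba = network.forward(x, train=False)
    labels = proba.argmax(axis=1)[0, :h, :w]
    return LabelMask.from_binary(labels >= 1, labels == 2)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_network(network: EffUnet, path) -> None:
    arrays = {f"p{i:04d}": v for i, v in enumerate(network.state())}
    np.savez(path, __config__=json.dumps(asdict(network.config)), **arrays)


def load_network(path) -> EffUnet:
    with np.load(path, allow_pickle=False) as data:
        doc = json.loads(str(data["__config__"]))
        doc["stages"] = tuple(tuple(s) for s in doc["stages"])
        doc["decoder_channels"] = tuple(doc["decoder_channels"])
        doc["input_size"] = tuple(doc["input_size"])
        net = build_network(NetworkConfig(**doc))
        n_state = len(net.params()) + len(net.buffers())
        state = [data[f"p{i:04d}"] for i in range(n_state)]
    net.load_state(state)
    return net
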