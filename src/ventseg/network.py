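"""Encoder–decoder segmentation model with a sub-pixel convolution decoder.

The encoder is a residual convolutional pyramid; each decoder stage is a
convolution expanding to ``C * r^2`` channels followed by a depth-to-space
rearrangement (sub-pixel convolution), which upsamples by ``r`` without
transposed convolutions or interpolation.  Skip connections concatenate
encoder features at matching resolutions (can be disabled).

Two encoders are available: ``small`` — a 4-level residual encoder with total
downsampling 4, sized for CPU training on 64x64 slices — and ``resnet34``,
the classic 34-layer residual topology with downsampling 32.  ImageNet
weights cannot be loaded here, so ``pretrained=True`` raises with an explicit
instruction to fall back to random initialization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import (Adam, BatchNorm2d, Conv2d, MaxPool2d, PixelShuffle, ReLU,
                 softmax, softmax_backward)


@dataclass
class ModelConfig:
    encoder: str = "small"
    pretrained: bool = False
    num_classes: int = 2
    upscale_factor: int = 2
    decoder_channels: list[int] | None = None
    skip_connections: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder not in ("small", "resnet34"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        down = {"small": 4, "resnet34": 32}[self.encoder]
        r, n = self.upscale_factor, 0
        total = 1
        while total < down:
            total *= r
            n += 1
        if total != down:
            raise ValueError(
                f"upscale_factor {r} cannot compose to the encoder's total "
                f"downsampling {down}"
            )
        self.n_decoder_stages = n
        self.downsample = down
        if self.decoder_channels is None:
            self.decoder_channels = (
                [16, 8] if self.encoder == "small" else [256, 128, 64, 32, 16]
            )
        if len(self.decoder_channels) != n:
            raise ValueError(
                f"decoder_channels must list {n} widths, got {self.decoder_channels}"
            )


@dataclass
class FeatureMap:
    """A feature tensor (H, W, channels) at one pyramid level."""

    tensor: np.ndarray
    level: int = 0

    def __post_init__(self) -> None:
        if self.tensor.ndim != 3 or min(self.tensor.shape[:2]) < 1:
            raise ValueError(f"feature tensor must be HxWxC, got {self.tensor.shape}")


# ---------------------------------------------------------------------------
# The sub-pixel operator


def subpixel_rearrange(x: np.ndarray, r: int) -> np.ndarray:
    """Rearrange (H, W, C*r^2) into (rH, rW, C); pure permutation.

    Output pixel (i, j) of class channel c reads input
    ``x[i // r, j // r, c*r*r + (i % r)*r + (j % r)]`` — the r^2 channels of
    each input pixel tile its r x r output block in row-major order.
    """
    if x.ndim != 3:
        raise ValueError(f"expected HxWxC input, got shape {x.shape}")
    h, w, crr = x.shape
    if r < 1:
        raise ValueError("r must be a positive integer")
    if crr % (r * r):
        raise ValueError(f"channel count {crr} not divisible by r^2 = {r * r}")
    c = crr // (r * r)
    y = x.reshape(h, w, c, r, r).transpose(0, 3, 1, 4, 2)
    return np.ascontiguousarray(y).reshape(h * r, w * r, c)


def subpixel_inverse(y: np.ndarray, r: int) -> np.ndarray:
    """Exact inverse of :func:`subpixel_rearrange`."""
    rh, rw, c = y.shape
    h, w = rh // r, rw // r
    x = y.reshape(h, r, w, r, c).transpose(0, 2, 4, 1, 3)
    return np.ascontiguousarray(x).reshape(h, w, c * r * r)


def subpixel_stage(feature: FeatureMap, weights: np.ndarray, bias: np.ndarray,
                   r: int) -> FeatureMap:
    """One decoder stage: same-padding convolution, then sub-pixel rearrange.

    ``weights`` has shape (out_ch, in_ch, k, k) with out_ch divisible by r^2;
    output spatial dims are exactly r times the input's.
    """
    x = feature.tensor
    if weights.shape[1] != x.shape[2]:
        raise ValueError(
            f"stage expects {weights.shape[1]} channels, feature has {x.shape[2]}"
        )
    conv = Conv2d.__new__(Conv2d)
    conv.stride, conv.pad = 1, weights.shape[2] // 2
    conv.params = {"w": weights, "b": bias}
    conv.grads = {k: np.zeros_like(v) for k, v in conv.params.items()}
    y = conv.forward(x.transpose(2, 0, 1)[None].astype(weights.dtype))
    y = y[0].transpose(1, 2, 0)
    return FeatureMap(subpixel_rearrange(y, r), level=feature.level + 1)


# ---------------------------------------------------------------------------
# Building blocks (NCHW internally)


class _Sequential:
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m.forward(x)
        return x

    def backward(self, dy):
        for m in reversed(self.mods):
            dy = m.backward(dy)
        return dy

    def layers(self):
        out = []
        for m in self.mods:
            out.extend(m.layers() if hasattr(m, "layers") else [m])
        return out


class _ResidualBlock:
    """conv-BN-relu-conv-BN with identity (or projected) shortcut, final ReLU."""

    def __init__(self, rng, in_ch, out_ch, stride=1):
        self.conv1 = Conv2d(rng, in_ch, out_ch, 3, stride=stride)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(rng, out_ch, out_ch, 3)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(rng, in_ch, out_ch, 1, stride=stride, pad=0)
            self.bnp = BatchNorm2d(out_ch)
        else:
            self.proj = None
            self.bnp = None
        self.relu_out = ReLU()

    def forward(self, x):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        h = self.bn2.forward(self.conv2.forward(h))
        s = self.bnp.forward(self.proj.forward(x)) if self.proj else x
        return self.relu_out.forward(h + s)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dh = self.conv2.backward(self.bn2.backward(d))
        dx = self.conv1.backward(self.bn1.backward(self.relu1.backward(dh)))
        dx = dx + (self.proj.backward(self.bnp.backward(d)) if self.proj else d)
        return dx

    def layers(self):
        out = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj:
            out.extend([self.proj, self.bnp])
        return out


class _UpStage:
    """Sub-pixel upsampling stage with optional skip concatenation."""

    def __init__(self, rng, in_ch, out_ch, r, skip_ch):
        self.r = r
        self.conv = Conv2d(rng, in_ch, out_ch * r * r, 3)
        self.shuffle = PixelShuffle(r)
        self.skip_ch = skip_ch
        fuse_in = out_ch + skip_ch
        self.fuse = Conv2d(rng, fuse_in, out_ch, 3)
        self.bn = BatchNorm2d(out_ch)
        self.relu = ReLU()

    def forward(self, x, skip):
        y = self.shuffle.forward(self.conv.forward(x))
        if self.skip_ch:
            y = np.concatenate([y, skip], axis=1)
        self._split = y.shape[1] - (skip.shape[1] if self.skip_ch else 0)
        return self.relu.forward(self.bn.forward(self.fuse.forward(y)))

    def backward(self, dy):
        d = self.fuse.backward(self.bn.backward(self.relu.backward(dy)))
        if self.skip_ch:
            d, dskip = d[:, : self._split], d[:, self._split:]
        else:
            dskip = None
        dx = self.conv.backward(self.shuffle.backward(d))
        return dx, dskip

    def layers(self):
        return [self.conv, self.fuse, self.bn]


class SegModel:
    """Residual encoder + sub-pixel decoder mapping HxWx3 -> HxWxC probabilities."""

    def __init__(self, config: ModelConfig):
        if config.pretrained:
            raise RuntimeError(
                "ImageNet-pretrained encoder weights are not bundled and cannot "
                "be downloaded here; rebuild with pretrained=False to use random "
                "initialization."
            )
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E9]))
        C = config.num_classes
        r = config.upscale_factor
        skip = config.skip_connections

        if config.encoder == "small":
            widths = [8, 16, 32]
            self.stem = _Sequential(Conv2d(rng, 3, widths[0], 3),
                                    BatchNorm2d(widths[0]), ReLU())
            self.enc_stages = [
                _ResidualBlock(rng, widths[0], widths[1], stride=2),
                _ResidualBlock(rng, widths[1], widths[2], stride=2),
            ]
            skip_feats = [widths[1], widths[0]]  # per decoder stage, coarse->fine
            in_ch = widths[2]
        else:  # resnet34
            self.stem = _Sequential(Conv2d(rng, 3, 64, 7, stride=2, pad=3),
                                    BatchNorm2d(64), ReLU())
            self.pool = MaxPool2d(3, 2, 1)
            blocks = []
            chans = [(64, 64, 3), (64, 128, 4), (128, 256, 6), (256, 512, 3)]
            self.enc_stages = []
            for i, (cin, cout, n) in enumerate(chans):
                stage = [_ResidualBlock(rng, cin, cout, stride=1 if i == 0 else 2)]
                stage += [_ResidualBlock(rng, cout, cout) for _ in range(n - 1)]
                self.enc_stages.append(_Sequential(*stage))
            skip_feats = [256, 128, 64, 64, 0]
            in_ch = 512

        self.dec_stages = []
        for out_ch, sk in zip(config.decoder_channels, skip_feats):
            self.dec_stages.append(
                _UpStage(rng, in_ch, out_ch, r, sk if skip else 0))
            in_ch = out_ch
        self.head = Conv2d(rng, in_ch, C, 1, pad=0)
        self._float32()

    def _float32(self):
        for layer in self.layers():
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(np.float32)
                layer.grads[k] = np.zeros_like(layer.params[k])
            for k in getattr(layer, "buffers", {}):
                layer.buffers[k] = layer.buffers[k].astype(np.float32)

    def set_training(self, flag: bool) -> None:
        for layer in self.layers():
            if hasattr(layer, "training"):
                layer.training = flag

    def layers(self):
        out = self.stem.layers()
        for s in self.enc_stages:
            out.extend(s.layers())
        for s in self.dec_stages:
            out.extend(s.layers())
        out.append(self.head)
        return out

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 3, H, W) with H, W multiples of the downsampling factor."""
        f = self.stem.forward(x.astype(np.float32))
        feats = [f]
        if self.config.encoder == "resnet34":
            f = self.pool.forward(f)
            for i, stage in enumerate(self.enc_stages):
                f = stage.forward(f)
                feats.append(f)
            skips = [feats[3], feats[2], feats[1], feats[0], None]
        else:
            for stage in self.enc_stages:
                f = stage.forward(f)
                feats.append(f)
            skips = [feats[1], feats[0]]
        self._skips = skips
        y = feats[-1]
        for stage, sk in zip(self.dec_stages, skips):
            y = stage.forward(y, sk)
        return self.head.forward(y)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for stage in reversed(self.dec_stages):
            d, dsk = stage.backward(d)
            dskips.append(dsk)
        dskips.reverse()
        if self.config.encoder == "resnet34":
            g3 = self.enc_stages[3].backward(d)
            if dskips[0] is not None:
                g3 = g3 + dskips[0]
            g2 = self.enc_stages[2].backward(g3)
            if dskips[1] is not None:
                g2 = g2 + dskips[1]
            g1 = self.enc_stages[1].backward(g2)
            if dskips[2] is not None:
                g1 = g1 + dskips[2]
            g0 = self.enc_stages[0].backward(g1)
            gp = self.pool.backward(g0)
            if dskips[3] is not None:
                gp = gp + dskips[3]
            self.stem.backward(gp)
        else:
            g = self.enc_stages[1].backward(d)
            if dskips[0] is not None:
                g = g + dskips[0]
            g = self.enc_stages[0].backward(g)
            if dskips[1] is not None:
                g = g + dskips[1]
            self.stem.backward(g)

    # -- inference ----------------------------------------------------------

    def forward_proba_batch(self, x: np.ndarray) -> np.ndarray:
        """(N, 3, H, W) -> (N, C, H, W) probabilities, padding if needed."""
        self.set_training(False)
        n, _, h, w = x.shape
        d = self.config.downsample
        ph, pw = (-h) % d, (-w) % d
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        p = softmax(self.forward_logits(x), axis=1)
        return p[:, :, :h, :w]

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """HxWx3 image -> HxWxC probability map (rows sum to 1)."""
        p = self.forward_proba_batch(image.transpose(2, 0, 1)[None])
        return p[0].transpose(1, 2, 0)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers()):
            for k, v in layer.params.items():
                arrays[f"layer{i:03d}_{k}"] = v
            for k, v in getattr(layer, "buffers", {}).items():
                arrays[f"layer{i:03d}_buf_{k}"] = v
        cfg = asdict(self.config)
        cfg.pop("n_decoder_stages", None)
        cfg.pop("downsample", None)
        arrays["config_json"] = np.frombuffer(
            json.dumps(cfg, sort_keys=True).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["config_json"].tobytes()).decode())
            model = cls(ModelConfig(**cfg))
            for i, layer in enumerate(model.layers()):
                for k in layer.params:
                    layer.params[k] = data[f"layer{i:03d}_{k}"].copy()
                    layer.grads[k] = np.zeros_like(layer.params[k])
                for k in getattr(layer, "buffers", {}):
                    layer.buffers[k] = data[f"layer{i:03d}_buf_{k}"].copy()
        return model


def build_model(config: ModelConfig) -> SegModel:
    """Construct a :class:`SegModel`; initialization is determined by config.seed."""
    return SegModel(config)
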