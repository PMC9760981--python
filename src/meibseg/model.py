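"""U-Net-style segmentation network with a residual encoder and a
multi-scale dilated bottleneck.

Architecture
------------
* **Encoder**: the 34-layer residual design with the classifier head
  removed — a 7×7/stride-2 stem with batch norm, ReLU and 3×3/stride-2
  max-pooling, followed by four stages of basic residual blocks
  (3, 4, 6, 3 blocks; 64/128/256/512 channels at ``width_scale`` 1), total
  downsampling ×32.
* **MSP bottleneck**: parallel 3×3 convolutions with dilation rates 1, 2
  and 3 (effective receptive fields 3×3, 5×5 and 7×7), each followed by
  ReLU, fused by a 1×1 convolution with ReLU.
* **Decoder**: repeated (bilinear ×2 upsample → concatenate the matching
  encoder feature map → two conv-BN-ReLU blocks) steps back to full
  resolution, then a 1×1 convolution to 3 class channels (background,
  eyelid, gland).

``width_scale`` multiplies every channel count so the same architecture
trains at desk scale on a CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .preprocessing import to_uint8

__all__ = ["NetworkConfig", "MeibNet", "MSPBlock", "build_network",
           "predict_mask", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    n_classes: int = 3
    base_width: int = 64
    encoder_blocks: tuple = (3, 4, 6, 3)
    msp_dilations: tuple = (1, 2, 3)
    width_scale: float = 1.0
    input_size: int = 256
    decoder_upsample: int = 2  # ×4-per-step reading available as 4
    seed: int = 0

    def __post_init__(self):
        if self.n_classes != 3:
            raise ValueError("the segmentation head is defined for 3 classes")
        if not self.msp_dilations or any(d < 1 for d in self.msp_dilations):
            raise ValueError("msp_dilations must be positive integers")
        if not 0 < self.width_scale <= 1:
            raise ValueError("width_scale must lie in (0, 1]")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by the total "
                             "encoder stride (32)")
        if self.decoder_upsample not in (2, 4):
            raise ValueError("decoder_upsample must be 2 or 4")

    def widths(self) -> list[int]:
        return [max(4, int(round(self.base_width * self.width_scale * m)))
                for m in (1, 1, 2, 4, 8)]  # stem + 4 stages


class BasicBlock(nn.Module):
    """Two 3×3 conv-BN layers with an identity (or projected) shortcut."""

    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1,
                               bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = nn.Conv2d(cin, cout, 1, stride=stride, bias=False,
                                       rng=rng)
            self.down_bn = nn.BatchNorm2d(cout)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x):
        out = nn.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return nn.relu(out + shortcut)


class MSPBlock(nn.Module):
    """Multi-scale perception: parallel 3×3 dilated convolutions (rates
    ``dilations``) + ReLU, fused by a 1×1 convolution + ReLU."""

    def __init__(self, channels, dilations=(1, 2, 3), rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.dilations = tuple(dilations)
        self.branches = [nn.Conv2d(channels, channels, 3, padding=d, dilation=d,
                                   rng=rng) for d in self.dilations]
        self.fuse = nn.Conv2d(channels * len(self.branches), channels, 1,
                              rng=rng)

    def forward(self, x):
        feats = [nn.relu(b(x)) for b in self.branches]
        return nn.relu(self.fuse(nn.concat(feats, axis=1)))


class _DoubleConv(nn.Module):
    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)

    def forward(self, x):
        x = nn.relu(self.bn1(self.conv1(x)))
        return nn.relu(self.bn2(self.conv2(x)))


class MeibNet(nn.Module):
    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w_stem, w1, w2, w3, w4 = config.widths()

        self.stem_conv = nn.Conv2d(config.in_channels, w_stem, 7, stride=2,
                                   padding=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(w_stem)
        self.pool = nn.MaxPool2d(3, 2, 1)

        def stage(cin, cout, n_blocks, stride):
            blocks = [BasicBlock(cin, cout, stride, rng)]
            blocks += [BasicBlock(cout, cout, 1, rng) for _ in range(n_blocks - 1)]
            return nn.Sequential(*blocks)

        b1, b2, b3, b4 = config.encoder_blocks
        self.stage1 = stage(w_stem, w1, b1, 1)   # /4
        self.stage2 = stage(w1, w2, b2, 2)       # /8
        self.stage3 = stage(w2, w3, b3, 2)       # /16
        self.stage4 = stage(w3, w4, b4, 2)       # /32

        self.msp = MSPBlock(w4, config.msp_dilations, rng)

        # decoder: skip channel counts at each ×2 resolution step
        self.skip_channels = {16: w3, 8: w2, 4: w1, 2: w_stem}
        self.decoder_steps = []
        cur = w4
        stride = 32
        step = config.decoder_upsample
        out_widths = {16: w3, 8: w2, 4: w1, 2: w_stem, 1: max(4, w_stem // 2)}
        while stride > 1:
            factor = step if stride >= step else stride  # final partial step
            stride //= factor
            skip = self.skip_channels.get(stride, 0)
            cout = out_widths.get(stride, max(4, cur // 2))
            self.decoder_steps.append(
                (stride, factor, _DoubleConv(cur + skip, cout, rng)))
            cur = cout
        self.decoder_modules = [m for _, _, m in self.decoder_steps]  # discovery
        self.head = nn.Conv2d(cur, config.n_classes, 1, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        c = self.config
        stem = nn.relu(self.stem_bn(self.stem_conv(x)))   # /2
        p = self.pool(stem)                               # /4
        s1 = self.stage1(p)                               # /4
        s2 = self.stage2(s1)                              # /8
        s3 = self.stage3(s2)                              # /16
        s4 = self.stage4(s3)                              # /32
        skips = {16: s3, 8: s2, 4: s1, 2: stem}
        y = self.msp(s4)
        for stride, factor, block in self.decoder_steps:
            y = nn.upsample_bilinear2d(y, factor)
            if stride in skips:
                y = nn.concat([y, skips[stride]], axis=1)
            y = block(y)
        return self.head(y)


def build_network(config: NetworkConfig = NetworkConfig()) -> MeibNet:
    """Construct the segmentation network (He-initialized, seeded)."""
    return MeibNet(config)


def _resize_nearest(arr: np.ndarray, shape) -> np.ndarray:
    ys = (np.arange(shape[0]) + 0.5) * arr.shape[0] / shape[0]
    xs = (np.arange(shape[1]) + 0.5) * arr.shape[1] / shape[1]
    ys = np.clip(ys.astype(int), 0, arr.shape[0] - 1)
    xs = np.clip(xs.astype(int), 0, arr.shape[1] - 1)
    return arr[np.ix_(ys, xs)]


def _resize_bilinear(arr: np.ndarray, shape) -> np.ndarray:
    from .nn.tensor import _bilinear_matrix
    my = _bilinear_matrix(arr.shape[0], shape[0], float)
    mx = _bilinear_matrix(arr.shape[1], shape[1], float)
    return my @ arr.astype(float) @ mx.T


def image_to_input(image: np.ndarray, input_size: int) -> np.ndarray:
    """Resize an 8-bit image to the network input and scale to [0, 1]."""
    img = to_uint8(image).astype(float)
    if img.shape != (input_size, input_size):
        img = _resize_bilinear(img, (input_size, input_size))
    return (img / 255.0).astype(np.float32)[None, None]


def predict_mask(network: MeibNet, image: np.ndarray) -> np.ndarray:
    """Segment one grayscale image into a {0,1,2} label mask.

    The image is resized to the network's input size, scored, argmaxed per
    pixel, and the label map resized back to the original dimensions with
    nearest-neighbor interpolation.
    """
    image = to_uint8(image)
    original = image.shape
    network.eval()
    x = nn.Tensor(image_to_input(image, network.config.input_size))
    scores = network(x).data[0]
    labels = scores.argmax(axis=0).astype(np.uint8)
    if labels.shape != original:
        labels = _resize_nearest(labels, original)
    return labels


def save_checkpoint(network: MeibNet, path) -> None:
    """Persist weights (.npz) with a sidecar JSON of the NetworkConfig."""
    path = Path(path)
    np.savez(path, **network.state_dict())
    cfg = asdict(network.config)
    Path(str(path) + ".json").write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path) -> MeibNet:
    path = Path(path)
    cfg = json.loads(Path(str(path) + ".json").read_text())
    for key in ("encoder_blocks", "msp_dilations"):
        cfg[key] = tuple(cfg[key])
    net = MeibNet(NetworkConfig(**cfg))
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        net.load_state_dict(dict(data))
    return net
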