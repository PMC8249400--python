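"""A U-Net variant for per-pixel two-class prediction.

Encoder blocks are (conv3x3 -> batch-norm -> ReLU) x2 followed by 2x2 max
pooling; the symmetric decoder upsamples (nearest-neighbour x2), concatenates
the matching encoder feature map (skip connection) and applies the same double
convolution; dropout acts only at the bottleneck; a final 1x1 convolution
produces the two class scores.  Because the network is fully convolutional it
accepts any input whose spatial dimensions are divisible by ``2**depth``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BatchNorm2d, Conv2d, Dropout, MaxPool2, ReLU, UpsampleNearest2


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4
    base_filters: int = 64
    dropout_rate: float = 0.5
    in_channels: int = 1
    out_classes: int = 2

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")


class _DoubleConv:
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()
        self._layers = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self._layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self._layers):
            dout = layer.backward(dout)
        return dout

    def param_items(self, prefix: str):
        for name, sub in (("conv1", self.conv1), ("bn1", self.bn1),
                          ("conv2", self.conv2), ("bn2", self.bn2)):
            yield from sub.param_items(f"{prefix}.{name}")

    def state_items(self, prefix: str):
        for name, sub in (("conv1", self.conv1), ("bn1", self.bn1),
                          ("conv2", self.conv2), ("bn2", self.bn2)):
            yield from sub.state_items(f"{prefix}.{name}")


class UNet:
    """Untrained model; see :func:`build_unet`."""

    def __init__(self, cfg: UNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        f = cfg.base_filters
        self.enc: list[_DoubleConv] = []
        self.pools: list[MaxPool2] = []
        in_ch = cfg.in_channels
        for i in range(cfg.depth):
            self.enc.append(_DoubleConv(in_ch, f * 2**i, rng))
            self.pools.append(MaxPool2())
            in_ch = f * 2**i
        self.bottleneck = _DoubleConv(in_ch, f * 2**cfg.depth, rng)
        self.dropout = Dropout(cfg.dropout_rate)
        self.ups: list[UpsampleNearest2] = []
        self.dec: list[_DoubleConv] = []
        for i in reversed(range(cfg.depth)):
            self.ups.append(UpsampleNearest2())
            self.dec.append(_DoubleConv(f * 2 ** (i + 1) + f * 2**i, f * 2**i, rng))
        self.head = Conv2d(f, cfg.out_classes, 1, rng)
        self._skip_channels = [f * 2**i for i in range(cfg.depth)]

    # -- shape contract ---------------------------------------------------
    def check_input_shape(self, shape: tuple[int, int]) -> None:
        div = 2**self.cfg.depth
        h, w = shape
        if h % div or w % div:
            raise ValueError(
                f"input spatial dims {shape} must both be divisible by 2**depth = {div}"
            )

    # -- forward / backward ----------------------------------------------
    def forward(
        self, x: np.ndarray, train: bool = True, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """``x``: (N, H, W, in_channels) -> logits (N, H, W, out_classes)."""
        self.check_input_shape(x.shape[1:3])
        x = np.ascontiguousarray(x, np.float32)
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        if rng is None:
            rng = np.random.default_rng(0)
        x = self.dropout.forward(x, rng, train)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=-1)
            x = dec.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        # decoder stages were applied in order self.dec[0..depth-1] (deep -> shallow),
        # so backprop visits them shallow -> deep
        for stage in reversed(range(self.cfg.depth)):
            d = self.dec[stage].backward(d)
            n_skip = self._skip_channels[self.cfg.depth - 1 - stage]
            dskip, dup = d[..., :n_skip], d[..., n_skip:]
            dskips.append(np.ascontiguousarray(dskip))
            d = self.ups[stage].backward(np.ascontiguousarray(dup))
        d = self.dropout.backward(d)
        d = self.bottleneck.backward(d)
        # dskips collected deepest-decoder-last; dskips[i] pairs with enc stage i
        for stage in reversed(range(self.cfg.depth)):
            d = self.pools[stage].backward(d)
            d = d + dskips[stage]
            d = self.enc[stage].backward(d)

    # -- parameter access -------------------------------------------------
    def param_items(self):
        for i, enc in enumerate(self.enc):
            yield from enc.param_items(f"enc{i}")
        yield from self.bottleneck.param_items("bottleneck")
        for i, dec in enumerate(self.dec):
            yield from dec.param_items(f"dec{i}")
        yield from self.head.param_items("head")

    def state_items(self):
        for i, enc in enumerate(self.enc):
            yield from enc.state_items(f"enc{i}")
        yield from self.bottleneck.state_items("bottleneck")
        for i, dec in enumerate(self.dec):
            yield from dec.state_items(f"dec{i}")
        yield from self.head.state_items("head")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: arr.copy() for name, arr in self.state_items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, arr in self.state_items():
            arr[...] = state[name]


def build_unet(cfg: UNetConfig, seed: int = 0) -> UNet:
    """Construct an untrained U-Net with seeded He-normal initialization."""
    return UNet(cfg, np.random.default_rng(seed))
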