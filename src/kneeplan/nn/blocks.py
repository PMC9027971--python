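"""Residual pre-activation bottleneck blocks and hourglass building parts."""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2d, MaxPool2, Module, ReLU, Sequential, Upsample2


class Bottleneck(Module):
    """Pre-activation residual bottleneck: BN-ReLU-1x1 (compress), BN-ReLU-3x3,
    BN-ReLU-1x1 (expand), with an identity shortcut. Channel count is
    preserved; the mid width is ``channels * compression``."""

    def __init__(self, channels: int, rng: np.random.Generator, compression: float = 0.5) -> None:
        mid = max(1, int(round(channels * compression)))
        self.body = Sequential(
            BatchNorm2d(channels),
            ReLU(),
            Conv2d(channels, mid, 1, rng),
            BatchNorm2d(mid),
            ReLU(),
            Conv2d(mid, mid, 3, rng),
            BatchNorm2d(mid),
            ReLU(),
            Conv2d(mid, channels, 1, rng),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.body.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy + self.body.backward(dy)


class Encoder(Module):
    """Contracting hourglass half: stem conv, then per level a bottleneck and
    2x2 max pooling, closed by a bottom bottleneck. Pre-pool features are kept
    for the (parameterized) skip connections. The channel count is constant
    across all levels."""

    def __init__(self, in_channels: int, n_features: int, depth: int, rng: np.random.Generator) -> None:
        self.stem = Conv2d(in_channels, n_features, 3, rng)
        self.blocks = [Bottleneck(n_features, rng) for _ in range(depth)]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottom = Bottleneck(n_features, rng)
        self.depth = depth

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        h = self.stem.forward(x)
        skips = []
        for block, pool in zip(self.blocks, self.pools):
            h = block.forward(h)
            skips.append(h)
            h = pool.forward(h)
        return self.bottom.forward(h), skips

    def backward(self, dbottom: np.ndarray, dskips: list[np.ndarray]) -> np.ndarray:
        dh = self.bottom.backward(dbottom)
        for block, pool, dskip in zip(reversed(self.blocks), reversed(self.pools), reversed(dskips)):
            dh = pool.backward(dh)
            dh = dh + dskip
            dh = block.backward(dh)
        return self.stem.backward(dh)


class Decoder(Module):
    """Expanding hourglass half: per level nearest-neighbour upsampling plus a
    1x1-convolved skip from the encoder, then a bottleneck; closed by a final
    bottleneck at full resolution."""

    def __init__(self, n_features: int, depth: int, rng: np.random.Generator) -> None:
        self.skip_convs = [Conv2d(n_features, n_features, 1, rng) for _ in range(depth)]
        self.ups = [Upsample2() for _ in range(depth)]
        self.blocks = [Bottleneck(n_features, rng) for _ in range(depth)]
        self.final = Bottleneck(n_features, rng)
        self.depth = depth

    def forward(self, bottom: np.ndarray, skips: list[np.ndarray]) -> np.ndarray:
        h = bottom
        for up, sconv, block, skip in zip(
            reversed(self.ups), reversed(self.skip_convs), reversed(self.blocks), reversed(skips)
        ):
            h = up.forward(h) + sconv.forward(skip)
            h = block.forward(h)
        return self.final.forward(h)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        dh = self.final.backward(dy)
        dskips: list[np.ndarray] = []
        for up, sconv, block in zip(self.ups, self.skip_convs, self.blocks):
            dh = block.backward(dh)
            dskips.append(sconv.backward(dh))
            dh = up.backward(dh)
        # blocks[0] pairs with skips[0] (full resolution) and is unwound first,
        # so dskips is already in encoder order
        return dh, dskips
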