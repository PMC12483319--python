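"""2D/3D UNet for foreground + boundary probability prediction.

Encoder feature widths grow as ``initial_features * growth**level`` with
max-pool downsampling; the decoder mirrors it with nearest-neighbour
upsampling and skip connections; each output channel is sigmoid-bounded.
For 3D data the first downsampling step can be restricted to the image
plane to account for the smaller (and missing-wedge-affected) depth axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv, MaxPool, ReLU, Sigmoid, Upsample

__all__ = ["UNetConfig", "UNet", "build_unet"]


@dataclass
class UNetConfig:
    dimensionality: int = 3
    levels: int = 4
    initial_features: int = 32
    feature_growth: int = 2
    anisotropic_first_downsample: bool = False
    in_channels: int = 1
    out_channels: tuple[str, ...] = ("foreground", "boundary")
    convs_per_block: int = 2

    def __post_init__(self) -> None:
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.initial_features < 1 or self.feature_growth < 1:
            raise ValueError("features must be positive")
        if self.anisotropic_first_downsample and self.dimensionality != 3:
            raise ValueError("anisotropic first downsample only applies to 3D")

    @property
    def feature_widths(self) -> list[int]:
        return [self.initial_features * self.feature_growth**i for i in range(self.levels)]

    @property
    def downsample_factors(self) -> list[tuple[int, ...]]:
        nd = self.dimensionality
        factors = [(2,) * nd for _ in range(self.levels - 1)]
        if self.anisotropic_first_downsample:
            factors[0] = (1,) + (2,) * (nd - 1)
        return factors

    @property
    def divisor(self) -> tuple[int, ...]:
        div = np.ones(self.dimensionality, dtype=int)
        for f in self.downsample_factors:
            div *= np.asarray(f)
        return tuple(int(d) for d in div)


class _Block:
    """convs_per_block x (Conv -> ReLU)."""

    def __init__(self, cin, cout, ndim, n_convs, rng):
        self.layers = []
        for i in range(n_convs):
            self.layers.append(Conv(cin if i == 0 else cout, cout, ndim, rng=rng))
            self.layers.append(ReLU())

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def convs(self):
        return [l for l in self.layers if isinstance(l, Conv)]


class UNet:
    """UNet assembled from NumPy layers; see :class:`UNetConfig`."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        nd = cfg.dimensionality
        widths = cfg.feature_widths
        factors = cfg.downsample_factors
        n = cfg.convs_per_block

        self.encoder = []
        cin = cfg.in_channels
        for w in widths[:-1]:
            self.encoder.append(_Block(cin, w, nd, n, rng))
            cin = w
        self.pools = [MaxPool(f) for f in factors]
        self.bottleneck = _Block(widths[-2], widths[-1], nd, n, rng)
        self.ups = [Upsample(f) for f in reversed(factors)]
        self.decoder = []
        up_in = widths[-1]
        for w in reversed(widths[:-1]):
            self.decoder.append(_Block(up_in + w, w, nd, n, rng))
            up_in = w
        self.head = Conv(widths[0], len(cfg.out_channels), nd, kernel_size=1, rng=rng, scale=0.01)
        self.out_act = Sigmoid()

    # ---- parameter access -------------------------------------------------
    def _conv_layers(self):
        out = []
        for i, block in enumerate(self.encoder):
            out += [(f"enc{i}.{j}", c) for j, c in enumerate(block.convs())]
        out += [(f"bottleneck.{j}", c) for j, c in enumerate(self.bottleneck.convs())]
        for i, block in enumerate(self.decoder):
            out += [(f"dec{i}.{j}", c) for j, c in enumerate(block.convs())]
        out += [("head.0", self.head)]
        return out

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{p}": arr
            for name, conv in self._conv_layers()
            for p, arr in conv.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{p}": arr
            for name, conv in self._conv_layers()
            for p, arr in conv.grads.items()
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(params) != set(state):
            raise ValueError("checkpoint does not match model architecture")
        for k, v in params.items():
            if v.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            v[...] = state[k]

    # ---- forward / backward ----------------------------------------------
    def _check_shape(self, spatial):
        for s, d in zip(spatial, self.cfg.divisor):
            if s % d:
                raise ValueError(
                    f"spatial shape {tuple(spatial)} not divisible by {self.cfg.divisor}"
                )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (batch, *spatial, in_channels) -> probabilities, same layout."""
        self._check_shape(x.shape[1:-1])
        skips = []
        h = x.astype(np.float32, copy=False)
        for block, pool in zip(self.encoder, self.pools):
            h = block.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_widths = []
        for up, block, skip in zip(self.ups, self.decoder, reversed(skips)):
            h = up.forward(h)
            self._skip_widths.append(skip.shape[-1])
            h = block.forward(np.concatenate([skip, h], axis=-1))
        h = self.head.forward(h)
        return self.out_act.forward(h)

    def backward(self, grad: np.ndarray) -> None:
        g = self.out_act.backward(grad)
        g = self.head.backward(g)
        skip_grads = []
        for block, up, w in zip(
            reversed(self.decoder), reversed(self.ups), reversed(self._skip_widths)
        ):
            g = block.backward(g)
            skip_grads.append(g[..., :w])
            g = up.backward(g[..., w:])
        g = self.bottleneck.backward(g)
        for block, pool, gs in zip(
            reversed(self.encoder), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g) + gs
            g = block.backward(g)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Single image/volume (*spatial,) -> channels-first maps (C, *spatial)."""
        x = image[None, ..., None].astype(np.float32)
        out = self.forward(x)[0]
        return np.moveaxis(out, -1, 0)


def build_unet(cfg: UNetConfig, seed: int = 0) -> UNet:
    return UNet(cfg, seed=seed)
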