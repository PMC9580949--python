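"""Residual 3D U-Net with instance normalization.

The encoder ("context pathway") has `depth` levels; each level applies a
channel-setting convolution (stride 2 from level 1 downward, doubling the
filter count) followed by a residual context block of two 3x3x3
convolutions with instance normalization, leaky ReLU and dropout, around an
identity shortcut.  The decoder ("localization pathway") upsamples 2x
(nearest-neighbour repeat + convolution, which avoids checkerboard
artifacts), concatenates the matching encoder features and reduces filters
with a 3x3x3 + 1x1x1 localization pair.  A final 1x1x1 convolution and
channel softmax produce per-voxel class probabilities on the input grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["NetworkConfig", "ResidualUNet3D", "build_model"]

LEAKY_SLOPE = 0.01


@dataclass
class NetworkConfig:
    depth: int = 3
    base_filters: int = 8
    dropout_rate: float = 0.1
    in_channels: int = 1
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 1 or self.in_channels < 1 or self.n_classes < 2:
            raise ValueError("base_filters/in_channels >= 1 and n_classes >= 2 required")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")

    def level_filters(self) -> list[int]:
        return [self.base_filters * 2**level for level in range(self.depth)]

    def check_input_shape(self, shape) -> None:
        div = 2 ** (self.depth - 1)
        if any(int(n) % div for n in shape):
            raise ValueError(
                f"input spatial dims {tuple(shape)} must each be divisible by "
                f"{div} for depth {self.depth}"
            )


def _he_init(rng: np.random.Generator, co: int, ci: int, k: int) -> np.ndarray:
    fan_in = ci * k**3
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(co, ci, k, k, k)).astype(np.float32)


class _Conv:
    def __init__(self, rng, ci, co, k=3, stride=1, name=""):
        self.w = ad.parameter(_he_init(rng, co, ci, k), name=f"{name}.w")
        self.b = ad.parameter(np.zeros(co, dtype=np.float32), name=f"{name}.b")
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.w, self.b, stride=self.stride)

    def params(self):
        return [self.w, self.b]


class _Norm:
    def __init__(self, channels, name=""):
        self.gamma = ad.parameter(np.ones((channels, 1, 1, 1), dtype=np.float32), name=f"{name}.g")
        self.beta = ad.parameter(np.zeros((channels, 1, 1, 1), dtype=np.float32), name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return ad.instance_norm(x, self.gamma, self.beta)

    def params(self):
        return [self.gamma, self.beta]


class _ContextBlock:
    """Pre-activation residual unit: two (IN -> lReLU -> conv) with dropout."""

    def __init__(self, rng, channels, dropout_rate, name=""):
        self.norm1 = _Norm(channels, f"{name}.n1")
        self.conv1 = _Conv(rng, channels, channels, name=f"{name}.c1")
        self.norm2 = _Norm(channels, f"{name}.n2")
        self.conv2 = _Conv(rng, channels, channels, name=f"{name}.c2")
        self.dropout_rate = dropout_rate

    def __call__(self, x: Tensor, rng, training: bool) -> Tensor:
        h = self.conv1(ad.leaky_relu(self.norm1(x), LEAKY_SLOPE))
        h = ad.dropout(h, self.dropout_rate, rng, training)
        h = self.conv2(ad.leaky_relu(self.norm2(h), LEAKY_SLOPE))
        return ad.add(x, h)

    def params(self):
        return self.norm1.params() + self.conv1.params() + self.norm2.params() + self.conv2.params()


class ResidualUNet3D:
    """Encoder-decoder segmentation network on (C, X, Y, Z) float32 arrays."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        filters = cfg.level_filters()
        self.in_convs: list[_Conv] = []
        self.context: list[_ContextBlock] = []
        for level, f in enumerate(filters):
            ci = cfg.in_channels if level == 0 else filters[level - 1]
            stride = 1 if level == 0 else 2
            self.in_convs.append(_Conv(rng, ci, f, stride=stride, name=f"enc{level}.in"))
            self.context.append(_ContextBlock(rng, f, cfg.dropout_rate, name=f"enc{level}.ctx"))
        self.up_convs: list[_Conv] = []
        self.loc_convs: list[tuple[_Conv, _Conv]] = []
        self.loc_norms: list[_Norm] = []
        for level in range(cfg.depth - 2, -1, -1):
            f = filters[level]
            self.up_convs.append(_Conv(rng, filters[level + 1], f, name=f"dec{level}.up"))
            self.loc_convs.append(
                (_Conv(rng, 2 * f, f, name=f"dec{level}.loc3"), _Conv(rng, f, f, k=1, name=f"dec{level}.loc1"))
            )
            self.loc_norms.append(_Norm(f, f"dec{level}.n"))
        self.head = _Conv(rng, filters[0], cfg.n_classes, k=1, name="head")
        self._drop_rng = np.random.default_rng(cfg.seed + 1)

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for conv, block in zip(self.in_convs, self.context):
            params += conv.params() + block.params()
        for conv in self.up_convs:
            params += conv.params()
        for (c3, c1), n in zip(self.loc_convs, self.loc_norms):
            params += c3.params() + c1.params() + n.params()
        params += self.head.params()
        return params

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{idx:03d}": p.data.copy() for idx, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for idx, p in enumerate(params):
            arr = np.asarray(state[f"p{idx:03d}"], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {idx}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def reseed_dropout(self, seed: int) -> None:
        self._drop_rng = np.random.default_rng(seed)

    # -- forward ------------------------------------------------------------
    def forward(self, x: np.ndarray | Tensor, training: bool = False) -> Tensor:
        """Per-voxel class probabilities, shape (n_classes, X, Y, Z)."""
        if isinstance(x, np.ndarray):
            if x.ndim == 3:
                x = x[None]
            x = ad.constant(x.astype(np.float32))
        self.cfg.check_input_shape(x.data.shape[1:])
        rng = self._drop_rng
        skips: list[Tensor] = []
        h = x
        for level in range(self.cfg.depth):
            h = self.in_convs[level](h)
            h = self.context[level](h, rng, training)
            skips.append(h)
        for i, level in enumerate(range(self.cfg.depth - 2, -1, -1)):
            h = self.up_convs[i](ad.upsample2(h))
            h = ad.concat(h, skips[level])
            c3, c1 = self.loc_convs[i]
            h = ad.leaky_relu(self.loc_norms[i](c3(h)), LEAKY_SLOPE)
            h = c1(h)
        logits = self.head(h)
        return ad.softmax_channels(logits)

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        with ad.no_grad():
            return self.forward(x, training=False).data


def build_model(cfg: NetworkConfig) -> ResidualUNet3D:
    return ResidualUNet3D(cfg)
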