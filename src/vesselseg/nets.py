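"""Modified 3D U-Net with multi-scale supervision (U-Net MSS).

Encoder: four levels of two (conv3x3x3 -> batch-norm -> ReLU) blocks followed
by 2x max-pooling, channels doubling per level.  Decoder: trilinear 2x
upsampling, skip concatenation, two conv blocks.  The last three decoder
levels carry 1x1x1 sigmoid heads; the two deeper heads are resampled to label
resolution with nearest-neighbour interpolation, giving three full-resolution
probability maps for multi-scale supervision.  With ``supervision_taps=1``
the model degrades to a plain U-Net comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from .autodiff import (
    Tensor,
    batchnorm3d,
    concat_channels,
    conv3d,
    maxpool3d,
    resize3d,
)


@dataclass
class NetworkConfig:
    in_channels: int = 1
    base_channels: int = 64
    depth: int = 4
    supervision_taps: int = 3
    upsample_mode: str = "trilinear"
    norm: str = "batch"
    activation: str = "relu"
    final_activation: str = "sigmoid"

    def validate(self):
        problems = []
        if self.in_channels < 1:
            problems.append("in_channels must be >= 1")
        if self.base_channels < 2:
            problems.append("base_channels must be >= 2")
        if self.depth < 1:
            problems.append("depth must be >= 1")
        if not (1 <= self.supervision_taps <= self.depth):
            problems.append("supervision_taps must be in [1, depth]")
        if self.upsample_mode != "trilinear":
            problems.append("upsample_mode must be 'trilinear'")
        if self.norm != "batch":
            problems.append("norm must be 'batch'")
        if self.activation != "relu":
            problems.append("activation must be 'relu'")
        if self.final_activation != "sigmoid":
            problems.append("final_activation must be 'sigmoid'")
        if problems:
            raise ValueError("invalid NetworkConfig: " + "; ".join(problems))

    def to_dict(self):
        return dict(self.__dict__)


@dataclass
class MultiScaleOutput:
    """Probability maps from the supervision taps, all at label resolution.

    ``maps[0]`` is the full-resolution head; deeper heads follow in order of
    decreasing native resolution.
    """

    maps: List[Tensor]

    def __len__(self):
        return len(self.maps)

    @property
    def full_res(self) -> Tensor:
        return self.maps[0]

    def sample(self, i: int) -> "MultiScaleOutput":
        """Per-sample view of a batched output (keeps the batch axis)."""
        from .autodiff import slice_batch

        return MultiScaleOutput([slice_batch(m, i) for m in self.maps])


class _Conv3d:
    def __init__(self, c_in, c_out, k, rng, dtype=np.float32):
        fan_in = c_in * k**3
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(
            rng.normal(0.0, std, size=(c_out, c_in, k, k, k)).astype(dtype),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        return conv3d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class _BatchNorm3d:
    def __init__(self, c, dtype=np.float32):
        self.gamma = Tensor(np.ones(c, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.training = True

    def __call__(self, x):
        return batchnorm3d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training,
        )

    def parameters(self):
        return [self.gamma, self.beta]


class _DoubleConv:
    """Two (conv -> batch-norm -> ReLU) blocks."""

    def __init__(self, c_in, c_out, rng):
        self.conv1 = _Conv3d(c_in, c_out, 3, rng)
        self.bn1 = _BatchNorm3d(c_out)
        self.conv2 = _Conv3d(c_out, c_out, 3, rng)
        self.bn2 = _BatchNorm3d(c_out)

    def __call__(self, x):
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()

    def parameters(self):
        return (
            self.conv1.parameters() + self.bn1.parameters()
            + self.conv2.parameters() + self.bn2.parameters()
        )

    def bns(self):
        return [self.bn1, self.bn2]


class UNetMSS:
    """The backbone network; build with :func:`build_network`."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        b = cfg.base_channels
        enc_ch = [b * 2**i for i in range(cfg.depth)]
        self.encoders = []
        c_in = cfg.in_channels
        for c in enc_ch:
            self.encoders.append(_DoubleConv(c_in, c, rng))
            c_in = c
        self.bottleneck = _DoubleConv(enc_ch[-1], enc_ch[-1] * 2, rng)
        self.decoders = []
        c_up = enc_ch[-1] * 2
        for c_skip in reversed(enc_ch):
            self.decoders.append(_DoubleConv(c_up + c_skip, c_skip, rng))
            c_up = c_skip
        # 1x1x1 sigmoid heads on the last `supervision_taps` decoder levels,
        # ordered from full resolution downward.
        self.heads = [
            _Conv3d(enc_ch[i], 1, 1, rng) for i in range(cfg.supervision_taps)
        ]
        self._training = True

    # -- mode / parameter bookkeeping ----------------------------------------
    def train(self):
        self._training = True
        for bn in self._bns():
            bn.training = True
        return self

    def eval(self):
        self._training = False
        for bn in self._bns():
            bn.training = False
        return self

    def _bns(self):
        blocks = self.encoders + [self.bottleneck] + self.decoders
        return [bn for blk in blocks for bn in blk.bns()]

    def parameters(self):
        params = []
        for blk in self.encoders + [self.bottleneck] + self.decoders:
            params.extend(blk.parameters())
        for h in self.heads:
            params.extend(h.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self):
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.data.copy()
        for i, bn in enumerate(self._bns()):
            state[f"bn_{i}_mean"] = bn.running_mean.copy()
            state[f"bn_{i}_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state):
        for i, p in enumerate(self.parameters()):
            p.data = np.array(state[f"param_{i}"])
        for i, bn in enumerate(self._bns()):
            bn.running_mean = np.array(state[f"bn_{i}_mean"])
            bn.running_var = np.array(state[f"bn_{i}_var"])

    # -- forward --------------------------------------------------------------
    def forward(self, patch) -> MultiScaleOutput:
        """Run a (N, 1, X, Y, Z) batch (3D arrays are auto-batched).

        Spatial dims must be divisible by 2**depth (16 for the default
        four-level network).
        """
        if isinstance(patch, Tensor):
            x = patch
        else:
            arr = np.asarray(patch, dtype=np.float32)
            if arr.ndim == 3:
                arr = arr[None, None]
            elif arr.ndim == 4:
                arr = arr[:, None]
            x = Tensor(arr)
        div = 2**self.cfg.depth
        spatial = x.shape[2:]
        if any(s % div for s in spatial):
            raise ValueError(
                f"spatial dims {tuple(spatial)} must be divisible by {div}"
            )
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = maxpool3d(x)
        x = self.bottleneck(x)
        dec_feats = []
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = resize3d(x, skip.shape[2:], mode="linear")
            x = dec(concat_channels(x, skip))
            dec_feats.append(x)
        # dec_feats is ordered deepest -> full resolution
        full_shape = dec_feats[-1].shape[2:]
        maps = []
        for tap in range(self.cfg.supervision_taps):
            feat = dec_feats[-1 - tap]
            logits = self.heads[tap](feat)
            prob = logits.sigmoid()
            if tap > 0:
                prob = resize3d(prob, full_shape, mode="nearest")
            maps.append(prob)
        return MultiScaleOutput(maps)

    __call__ = forward


def build_network(cfg: NetworkConfig, rng: np.random.Generator) -> UNetMSS:
    """Construct a seeded U-Net MSS; same seed yields identical weights."""
    return UNetMSS(cfg, rng)


def tiny_config(base_channels: int = 8, supervision_taps: int = 3) -> NetworkConfig:
    """CPU-friendly preset used for desk-scale experiments and tests."""
    return NetworkConfig(base_channels=base_channels, supervision_taps=supervision_taps)
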