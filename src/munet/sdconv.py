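"""SD-Conv: redundancy-reducing convolution unit.

SD-Conv chains a spatial/channel reconstruction convolution (SCConv) with a
depthwise-separable convolution:

* SRU (Spatial Reconstruction Unit) ranks channels by the magnitude of their
  group-norm scale, gates the feature map into an informative and a
  less-informative stream with a sigmoid gate thresholded at 0.5, and
  cross-adds the two streams before re-concatenation ("separate and
  reconstruct").
* CRU (Channel Reconstruction Unit) splits channels into a rich branch
  (group conv + pointwise conv) and a cheap branch (pointwise conv +
  passthrough) and merges them with pooling-guided soft attention
  ("split-transform-merge").
* The depthwise-separable convolution (per-channel k x k followed by a 1 x 1
  pointwise mix) supplies spatial context at a parameter cost of
  C_in*k^2 + C_in*C_out instead of C_in*C_out*k^2.

All convolutions inside the unit are bias-free; every stage preserves the
batch and spatial dimensions and the unit preserves the channel count.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor, concatenate, stack

__all__ = ["SRU", "CRU", "DepthwiseSeparableConv", "SDConv"]


class SRU(nn.Module):
    """Spatial Reconstruction Unit (separate-and-reconstruct gating)."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 groups: int = 4, gate_threshold: float = 0.5):
        super().__init__()
        if channels < 2:
            raise ValueError("SRU needs at least 2 channels to separate")
        if channels % 2:
            raise ValueError("SRU channel count must be even (two streams)")
        groups = min(groups, channels)
        while channels % groups:
            groups -= 1
        self.norm = nn.GroupNorm(groups, channels)
        self.gate_threshold = gate_threshold

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        B, C, H, W = x.shape
        xn = self.norm(x)
        gamma = self.norm.gamma
        # informativeness weight per channel from the learned norm scales
        w = (gamma * gamma) / ((gamma * gamma).sum() + 1e-8)
        gate = (xn * w.reshape(1, -1, 1, 1)).sigmoid()
        informative = (gate.data >= self.gate_threshold).astype(np.float64)
        w1 = gate * Tensor(informative)
        w2 = gate * Tensor(1.0 - informative)
        x1 = x * w1
        x2 = x * w2
        half = C // 2
        x11, x12 = x1[:, :half], x1[:, half:]
        x21, x22 = x2[:, :half], x2[:, half:]
        return concatenate([x11 + x22, x12 + x21], axis=1)


class CRU(nn.Module):
    """Channel Reconstruction Unit (split-transform-merge with soft attention)."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 split_ratio: float = 0.5, squeeze: int = 2, groups: int = 2):
        super().__init__()
        if channels < 2:
            raise ValueError("CRU needs at least 2 channels")
        if not 0.0 < split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")
        c_up = max(1, round(channels * split_ratio))
        c_low = channels - c_up
        if c_low < 1:
            raise ValueError("split leaves no lower channels")
        sq_up = max(1, c_up // squeeze)
        sq_low = max(1, c_low // squeeze)
        g = math.gcd(groups, math.gcd(sq_up, channels))
        self.c_up, self.c_low = c_up, c_low
        self.squeeze_up = nn.Conv2d(c_up, sq_up, 1, rng, bias=False)
        self.squeeze_low = nn.Conv2d(c_low, sq_low, 1, rng, bias=False)
        self.gwc = nn.Conv2d(sq_up, channels, 3, rng, padding=1, groups=g, bias=False)
        self.pwc_up = nn.Conv2d(sq_up, channels, 1, rng, bias=False)
        self.pwc_low = nn.Conv2d(sq_low, channels - sq_low, 1, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        up = self.squeeze_up(x[:, : self.c_up])
        low = self.squeeze_low(x[:, self.c_up :])
        y1 = self.gwc(up) + self.pwc_up(up)
        y2 = concatenate([self.pwc_low(low), low], axis=1)
        # pooling-guided soft attention over the two branches
        pooled = stack([y1.mean(axis=(2, 3)), y2.mean(axis=(2, 3))], axis=0)
        beta = pooled.softmax(axis=0)  # (2, B, C)
        b1 = beta[0].reshape(*beta.shape[1:], 1, 1)
        b2 = beta[1].reshape(*beta.shape[1:], 1, 1)
        return y1 * b1 + y2 * b2

    def branch_attention(self, x: Tensor) -> np.ndarray:
        """The two branch weights (2, B, C); they sum to 1 over the first axis."""
        x = as_tensor(x)
        up = self.squeeze_up(x[:, : self.c_up])
        low = self.squeeze_low(x[:, self.c_up :])
        y1 = self.gwc(up) + self.pwc_up(up)
        y2 = concatenate([self.pwc_low(low), low], axis=1)
        pooled = stack([y1.mean(axis=(2, 3)), y2.mean(axis=(2, 3))], axis=0)
        return pooled.softmax(axis=0).data


class DepthwiseSeparableConv(nn.Module):
    """Per-channel k x k convolution followed by a 1 x 1 pointwise mix."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd to preserve spatial size")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        pad = dilation * (kernel_size - 1) // 2
        self.depthwise = nn.Conv2d(in_channels, in_channels, kernel_size, rng,
                                   padding=pad, dilation=dilation,
                                   groups=in_channels, bias=False)
        self.pointwise = nn.Conv2d(in_channels, out_channels, 1, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class SDConv(nn.Module):
    """SRU -> CRU -> depthwise-separable convolution, shape preserving."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 kernel_size: int = 3, dilation: int = 1,
                 split_ratio: float = 0.5):
        super().__init__()
        self.sru = SRU(channels, rng)
        self.cru = CRU(channels, rng, split_ratio=split_ratio)
        self.dwconv = DepthwiseSeparableConv(channels, channels, kernel_size, rng,
                                             dilation=dilation)

    def forward(self, x: Tensor) -> Tensor:
        return self.dwconv(self.cru(self.sru(x)))
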