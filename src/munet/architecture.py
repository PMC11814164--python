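"""MUNet: a UNet-shaped encoder-decoder whose stages are SD-SSM blocks.

The network partitions the multimodal input into non-overlapping patches,
embeds them linearly, and processes them through a hierarchy of SD-SSM
blocks.  Each SD-SSM block runs two branches over the stage feature map:

* X1: batch normalisation followed by stacked SD-Conv units at increasing
  dilation rates (multi-scale local context);
* X2: channel layer-norm -> linear mix -> SiLU -> SD-Conv -> SS2D, where
  SS2D expands the map into four directional sequences, runs the selective
  scan along each and merges the results (global context).

The two branch outputs are scaled by learnable scalars (initialised to zero,
so a freshly built block is exactly the identity) and added to the block
input as a residual.  Patch merging halves the spatial size and doubles the
channels; patch expanding is its shape inverse; encoder features reach the
decoder through additive skip fusion.  A final expansion restores full
resolution and a 1x1 convolution produces per-class logits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor, concatenate
from .ssm_core import S6, ss2d_expand, ss2d_merge

__all__ = [
    "ModelConfig",
    "PatchEmbed",
    "PatchMerge",
    "PatchExpand",
    "SS2DLayer",
    "SDSSMBlock",
    "SkipFusion",
    "MUNet",
    "build_munet",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    Input height/width must be divisible by ``patch_size * 2**(num_stages-1)``.
    Channel width doubles at every patch merge: stage s has
    ``embed_dim * 2**s`` channels at 1/(patch_size * 2**s) resolution.
    """

    in_channels: int = 4
    num_classes: int = 4
    patch_size: int = 4
    embed_dim: int = 32
    depths: int = 2
    num_stages: int = 3
    n_state: int = 8
    dilation_rates: tuple[int, ...] = (1, 2, 4)

    def __post_init__(self):
        if self.in_channels < 1 or self.num_classes < 1:
            raise ValueError("in_channels and num_classes must be positive")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if self.embed_dim < 2 or self.embed_dim % 2:
            raise ValueError("embed_dim must be an even integer >= 2")
        if self.depths < 1:
            raise ValueError("depths must be >= 1 per stage")
        if self.num_stages < 1:
            raise ValueError("num_stages must be >= 1")
        if self.n_state < 1:
            raise ValueError("n_state must be >= 1")
        self.dilation_rates = tuple(int(d) for d in self.dilation_rates)
        if not self.dilation_rates or any(d < 1 for d in self.dilation_rates):
            raise ValueError("dilation_rates must be non-empty positive integers")

    @property
    def divisor(self) -> int:
        return self.patch_size * 2 ** (self.num_stages - 1)

    def validate_input_size(self, H: int, W: int) -> None:
        d = self.divisor
        if H % d or W % d:
            raise ValueError(
                f"input size {H}x{W} must be divisible by patch_size * "
                f"2**(num_stages-1) = {d}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dilation_rates"] = list(self.dilation_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{**d, "dilation_rates": tuple(d.get("dilation_rates", (1, 2, 4)))})


class PatchEmbed(nn.Module):
    """Non-overlapping patch partition + linear projection (a strided conv)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.patch_size = cfg.patch_size
        self.proj = nn.Conv2d(cfg.in_channels, cfg.embed_dim, cfg.patch_size, rng,
                              stride=cfg.patch_size)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        H, W = x.shape[-2:]
        if H % self.patch_size or W % self.patch_size:
            raise ValueError(
                f"spatial size {H}x{W} not divisible by patch_size {self.patch_size}"
            )
        return self.proj(x)


class PatchMerge(nn.Module):
    """2x2 neighbourhood concatenation (4C) + linear reduction to 2C."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.reduce = nn.Conv2d(4 * channels, 2 * channels, 1, rng, bias=False)

    @staticmethod
    def rearrange(x: Tensor) -> Tensor:
        H, W = x.shape[-2:]
        if H < 2 or W < 2 or H % 2 or W % 2:
            raise ValueError(f"spatial size {H}x{W} must be even and >= 2 to merge")
        quads = [x[:, :, 0::2, 0::2], x[:, :, 0::2, 1::2],
                 x[:, :, 1::2, 0::2], x[:, :, 1::2, 1::2]]
        return concatenate(quads, axis=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.reduce(self.rearrange(as_tensor(x)))


def _pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """(B, r*r*C, H, W) -> (B, C, r*H, r*W)."""
    B, C2, H, W = x.shape
    C = C2 // (r * r)
    x = x.reshape(B, r, r, C, H, W)
    x = x.transpose(0, 3, 4, 1, 5, 2)  # B, C, H, r, W, r
    return x.reshape(B, C, H * r, W * r)


class PatchExpand(nn.Module):
    """Linear expansion + pixel rearrangement: doubles H, W, halves channels."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        if channels % 2:
            raise ValueError("channel count must be even to expand")
        self.expand = nn.Conv2d(channels, 2 * channels, 1, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        return _pixel_shuffle(self.expand(as_tensor(x)), 2)


class FinalExpand(nn.Module):
    """Expand by the patch size back to full image resolution, keeping C."""

    def __init__(self, channels: int, patch_size: int, rng: np.random.Generator):
        super().__init__()
        self.patch_size = patch_size
        self.expand = nn.Conv2d(channels, channels * patch_size**2, 1, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        return _pixel_shuffle(self.expand(as_tensor(x)), self.patch_size)


class SS2DLayer(nn.Module):
    """Four-direction selective scan over a 2-D feature map.

    The four directional sequences are stacked into the batch axis and run
    through one shared S6 scan, then realigned and summed; a 1x1 projection
    follows the merge.
    """

    def __init__(self, channels: int, n_state: int, rng: np.random.Generator):
        super().__init__()
        self.s6 = S6(channels, n_state, rng)
        self.proj = nn.Conv2d(channels, channels, 1, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        B, C, H, W = x.shape
        seqs = ss2d_expand(x)  # four (B, C, L)
        stacked = concatenate(seqs, axis=0)            # (4B, C, L)
        scanned = self.s6(stacked.transpose(0, 2, 1))  # (4B, L, C)
        scanned = scanned.transpose(0, 2, 1)           # (4B, C, L)
        parts = [scanned[i * B : (i + 1) * B] for i in range(4)]
        merged = ss2d_merge(parts, H, W)
        return self.proj(merged)


class SDSSMBlock(nn.Module):
    """Two-branch selective-scan block with zero-initialised residual scales."""

    def __init__(self, channels: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        from .sdconv import SDConv  # local import to keep module load order simple

        self.bn = nn.BatchNorm2d(channels)
        self.x1_convs = [
            SDConv(channels, rng, dilation=d) for d in cfg.dilation_rates
        ]
        self.ln = nn.LayerNorm2d(channels)
        self.linear = nn.Conv2d(channels, channels, 1, rng)
        self.x2_conv = SDConv(channels, rng, dilation=1)
        self.ss2d = SS2DLayer(channels, cfg.n_state, rng)
        self.scale1 = nn.Parameter(np.zeros(1))
        self.scale2 = nn.Parameter(np.zeros(1))

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        b1 = self.bn(x)
        for conv in self.x1_convs:
            b1 = conv(b1)
        b2 = self.ss2d(self.x2_conv(self.linear(self.ln(x)).silu()))
        return x + b1 * self.scale1.reshape(1, 1, 1, 1) + b2 * self.scale2.reshape(1, 1, 1, 1)


class SkipFusion(nn.Module):
    """Elementwise addition of decoder and encoder features + 1x1 projection."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Conv2d(channels, channels, 1, rng)

    def forward(self, decoder_f: Tensor, encoder_f: Tensor) -> Tensor:
        decoder_f = as_tensor(decoder_f)
        encoder_f = as_tensor(encoder_f)
        if decoder_f.shape != encoder_f.shape:
            raise ValueError(
                f"skip fusion shape mismatch: {decoder_f.shape} vs {encoder_f.shape}"
            )
        return self.proj(decoder_f + encoder_f)


class MUNet(nn.Module):
    """Encoder-decoder segmentation network of SD-SSM stages."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        S = cfg.num_stages
        widths = [cfg.embed_dim * 2**s for s in range(S)]
        self.patch_embed = PatchEmbed(cfg, rng)
        self.encoder_blocks = []
        self.merges = []
        for s in range(S - 1):
            self.encoder_blocks.append(
                _BlockStack([SDSSMBlock(widths[s], cfg, rng) for _ in range(cfg.depths)])
            )
            self.merges.append(PatchMerge(widths[s], rng))
        self.bottleneck = _BlockStack(
            [SDSSMBlock(widths[S - 1], cfg, rng) for _ in range(cfg.depths)]
        )
        self.expands = []
        self.skips = []
        self.decoder_blocks = []
        for s in range(S - 2, -1, -1):
            self.expands.append(PatchExpand(widths[s + 1], rng))
            self.skips.append(SkipFusion(widths[s], rng))
            self.decoder_blocks.append(
                _BlockStack([SDSSMBlock(widths[s], cfg, rng) for _ in range(cfg.depths)])
            )
        self.final_expand = FinalExpand(cfg.embed_dim, cfg.patch_size, rng)
        self.head = nn.Conv2d(cfg.embed_dim, cfg.num_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (B, {self.cfg.in_channels}, H, W) input, got {x.shape}"
            )
        self.cfg.validate_input_size(x.shape[2], x.shape[3])
        f = self.patch_embed(x)
        skips = []
        for blocks, merge in zip(self.encoder_blocks, self.merges):
            f = blocks(f)
            skips.append(f)
            f = merge(f)
        f = self.bottleneck(f)
        for expand, fuse, blocks, enc in zip(
            self.expands, self.skips, self.decoder_blocks, reversed(skips)
        ):
            f = fuse(expand(f), enc)
            f = blocks(f)
        return self.head(self.final_expand(f))

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        """Inference helper on a plain array; respects train/eval mode."""
        return self.forward(Tensor(np.asarray(x, dtype=np.float64))).data


class _BlockStack(nn.Module):
    def __init__(self, blocks):
        super().__init__()
        self.blocks = blocks

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


def build_munet(cfg: ModelConfig, seed: int = 0) -> MUNet:
    """Construct a MUNet with all parameters drawn from a seeded generator."""
    rng = np.random.default_rng(seed)
    return MUNet(cfg, rng)


# ---------------------------------------------------------------------------
# Checkpoints: .npz weights + JSON sidecar with config and version
# ---------------------------------------------------------------------------


def save_checkpoint(model: MUNet, path: str | Path, step: int = 0,
                    extra: dict | None = None) -> None:
    from . import __version__

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {
        "config": model.cfg.to_dict(),
        "version": __version__,
        "step": int(step),
    }
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[MUNet, dict]:
    """Rebuild the model from its sidecar config and load the weights.

    Raises if the stored weights are inconsistent with the stored config.
    """
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig.from_dict(sidecar["config"])
    model = build_munet(cfg, seed=0)
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    model.load_state_dict(state)
    model.eval()
    return model, sidecar
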