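"""Pyramid vision Transformer branch.

Four stages, each: overlapping patch embedding (a strided convolution whose
kernel exceeds its stride, so neighboring patches overlap) → a stack of
attention blocks → one closing layer normalization, after which tokens are
reshaped back to a spatial map. Every block is pre-norm residual:

    x = x + MHA(LN(x));   x = x + CFF(LN(x))

where the multi-head attention takes queries from the full-resolution token
sequence but keys/values from a spatially reduced copy (strided convolution
with kernel = stride = Rs, then a linear projection and layer normalization),
cutting the quadratic attention cost by Rs² per stage. The feed-forward block
inserts a depthwise 3×3 convolution between its two linear layers to restore
local continuity; no explicit positional embedding is used (the zero-padded
patch embedding and depthwise convolution carry positional information).

Stage geometry with the default plan and a 224×224 input:
56×56/64ch → 28×28/128ch → 14×14/320ch → 7×7/512ch, matching the CNN branch
resolution-for-resolution so the two can be fused stage-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor

__all__ = [
    "PvTStageConfig",
    "TokenGrid",
    "default_pvt_configs",
    "tiny_pvt_configs",
    "OverlapPatchEmbed",
    "SpatialReduction",
    "SRAttention",
    "ConvFeedForward",
    "PvTBlock",
    "PvTStage",
    "PvTBranch",
]


@dataclass(frozen=True)
class PvTStageConfig:
    """Architecture hyperparameters of one Transformer stage."""

    stage_index: int
    embed_dim: int          # d_i
    num_heads: int          # h_i
    sr_ratio: int           # Rs_i, key/value spatial reduction
    mlp_ratio: int          # Rm_i, feed-forward expansion
    depth: int              # number of blocks
    patch_kernel: int
    patch_stride: int
    patch_padding: int

    def __post_init__(self):
        if self.embed_dim % self.num_heads != 0:
            raise ValueError(
                f"stage {self.stage_index}: embed_dim {self.embed_dim} not divisible "
                f"by num_heads {self.num_heads}"
            )
        if self.sr_ratio < 1 or self.depth < 1:
            raise ValueError(f"stage {self.stage_index}: sr_ratio and depth must be >= 1")
        if self.patch_kernel <= self.patch_stride:
            raise ValueError(
                f"stage {self.stage_index}: patch kernel ({self.patch_kernel}) must "
                f"exceed stride ({self.patch_stride}) for overlapping embedding"
            )


def default_pvt_configs() -> list[PvTStageConfig]:
    """The published stage plan: d=[64,128,320,512], h=[1,2,5,8],
    Rs=[8,4,2,1], Rm=[8,8,4,4], depths=[3,8,27,3].

    Stage 1 embeds with kernel 7 / stride 4 / padding 3; stages 2–4 with
    kernel 3 / stride 2 / padding 1 (exact halving).
    """
    dims, heads = [64, 128, 320, 512], [1, 2, 5, 8]
    srs, mlps, depths = [8, 4, 2, 1], [8, 8, 4, 4], [3, 8, 27, 3]
    return _make_configs(dims, heads, srs, mlps, depths)


def tiny_pvt_configs() -> list[PvTStageConfig]:
    """Desk-scale plan for 64×64 inputs: d=[16,32,64,128], one block per stage."""
    return _make_configs([16, 32, 64, 128], [1, 2, 4, 8], [4, 2, 2, 1],
                         [2, 2, 2, 2], [1, 1, 1, 1])


def _make_configs(dims, heads, srs, mlps, depths, stage1_stride=4):
    cfgs = []
    for i in range(4):
        k, s, p = (7, stage1_stride, 3) if i == 0 else (3, 2, 1)
        cfgs.append(
            PvTStageConfig(
                stage_index=i + 1, embed_dim=dims[i], num_heads=heads[i],
                sr_ratio=srs[i], mlp_ratio=mlps[i], depth=depths[i],
                patch_kernel=k, patch_stride=s, patch_padding=p,
            )
        )
    return cfgs


@dataclass
class TokenGrid:
    """Flattened token sequence [batch, H·W, d] plus its grid geometry."""

    tokens: Tensor
    grid_h: int
    grid_w: int

    def __post_init__(self):
        if self.tokens.shape[-2] != self.grid_h * self.grid_w:
            raise ValueError(
                f"token count {self.tokens.shape[-2]} != grid "
                f"{self.grid_h}x{self.grid_w}"
            )

    def to_map(self) -> Tensor:
        """Lossless reshape to a [batch, d, H, W] spatial map."""
        b, n, d = self.tokens.shape
        return self.tokens.transpose(0, 2, 1).reshape(b, d, self.grid_h, self.grid_w)

    @classmethod
    def from_map(cls, fmap: Tensor) -> "TokenGrid":
        b, d, h, w = fmap.shape
        return cls(fmap.reshape(b, d, h * w).transpose(0, 2, 1), h, w)


class OverlapPatchEmbed(nn.Module):
    """Strided convolution tokenizer (kernel > stride) + token layer norm."""

    def __init__(self, in_ch: int, cfg: PvTStageConfig, *, rng):
        super().__init__()
        self.cfg = cfg
        self.proj = nn.Conv2d(in_ch, cfg.embed_dim, cfg.patch_kernel,
                              stride=cfg.patch_stride, padding=cfg.patch_padding,
                              rng=rng)
        self.norm = nn.LayerNorm(cfg.embed_dim)

    def forward(self, fmap: Tensor) -> TokenGrid:
        _, _, h, w = fmap.shape
        c = self.cfg
        gh = (h + 2 * c.patch_padding - c.patch_kernel) // c.patch_stride + 1
        gw = (w + 2 * c.patch_padding - c.patch_kernel) // c.patch_stride + 1
        if gh <= 0 or gw <= 0:
            raise ValueError(
                f"stage {c.stage_index}: input {h}x{w} too small for patch "
                f"embedding (kernel {c.patch_kernel}, stride {c.patch_stride})"
            )
        grid = TokenGrid.from_map(self.proj(fmap))
        grid.tokens = self.norm(grid.tokens)
        return grid


class SpatialReduction(nn.Module):
    """SR(x) = LN(flatten(Conv(reshape(x), kernel=stride=Rs)) · W_S).

    Reduces an H×W token grid to (H/Rs)×(W/Rs); applied to keys and values
    only. Rs must divide both grid dimensions.
    """

    def __init__(self, dim: int, sr_ratio: int, *, rng):
        super().__init__()
        self.sr_ratio = sr_ratio
        self.conv = nn.Conv2d(dim, dim, sr_ratio, stride=sr_ratio, padding=0, rng=rng)
        self.proj = nn.Linear(dim, dim, rng=rng)
        self.norm = nn.LayerNorm(dim)

    def forward(self, grid: TokenGrid) -> TokenGrid:
        rs = self.sr_ratio
        if grid.grid_h % rs or grid.grid_w % rs:
            raise ValueError(
                f"grid {grid.grid_h}x{grid.grid_w} not divisible by sr_ratio {rs}"
            )
        reduced = TokenGrid.from_map(self.conv(grid.to_map()))
        reduced.tokens = self.norm(self.proj(reduced.tokens))
        return reduced


class SRAttention(nn.Module):
    """Multi-head attention with spatially reduced keys/values.

    Per head: Attention(q, k, v) = Softmax(q·kᵀ / √(d/h))·v; heads are
    concatenated and projected by W_O. Queries keep full resolution.
    """

    def __init__(self, cfg: PvTStageConfig, *, rng):
        super().__init__()
        d = cfg.embed_dim
        self.num_heads = cfg.num_heads
        self.head_dim = d // cfg.num_heads
        self.q = nn.Linear(d, d, rng=rng)
        self.k = nn.Linear(d, d, rng=rng)
        self.v = nn.Linear(d, d, rng=rng)
        self.out_proj = nn.Linear(d, d, rng=rng)
        self.sr = SpatialReduction(d, cfg.sr_ratio, rng=rng)

    def _split_heads(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        return x.reshape(b, n, self.num_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, grid: TokenGrid, return_attention: bool = False):
        b, n, d = grid.tokens.shape
        reduced = self.sr(grid)
        q = self._split_heads(self.q(grid.tokens))          # [B,h,N,dh]
        k = self._split_heads(self.k(reduced.tokens))       # [B,h,M,dh]
        v = self._split_heads(self.v(reduced.tokens))
        scale = 1.0 / math.sqrt(self.head_dim)
        attn = ((q @ k.transpose(0, 1, 3, 2)) * scale).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        out = self.out_proj(out)
        result = TokenGrid(out, grid.grid_h, grid.grid_w)
        if return_attention:
            return result, attn
        return result


class ConvFeedForward(nn.Module):
    """Expand d → d·Rm, depthwise 3×3 convolution on the token map, GELU,
    project back to d. Shape-preserving."""

    def __init__(self, cfg: PvTStageConfig, *, rng):
        super().__init__()
        d, hidden = cfg.embed_dim, cfg.embed_dim * cfg.mlp_ratio
        self.fc1 = nn.Linear(d, hidden, rng=rng)
        self.dwconv = nn.Conv2d(hidden, hidden, 3, stride=1, padding=1,
                                groups=hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, d, rng=rng)

    def forward(self, grid: TokenGrid) -> TokenGrid:
        h = self.fc1(grid.tokens)
        hmap = TokenGrid(h, grid.grid_h, grid.grid_w).to_map()
        h = TokenGrid.from_map(self.dwconv(hmap)).tokens
        h = self.fc2(h.gelu())
        return TokenGrid(h, grid.grid_h, grid.grid_w)


class PvTBlock(nn.Module):
    """Pre-norm residual block: x + MHA(LN(x)); then x + CFF(LN(x))."""

    def __init__(self, cfg: PvTStageConfig, *, rng):
        super().__init__()
        d = cfg.embed_dim
        self.norm1 = nn.LayerNorm(d)
        self.attn = SRAttention(cfg, rng=rng)
        self.norm2 = nn.LayerNorm(d)
        self.mlp = ConvFeedForward(cfg, rng=rng)

    def forward(self, grid: TokenGrid) -> TokenGrid:
        normed = TokenGrid(self.norm1(grid.tokens), grid.grid_h, grid.grid_w)
        x = grid.tokens + self.attn(normed).tokens
        normed2 = TokenGrid(self.norm2(x), grid.grid_h, grid.grid_w)
        x = x + self.mlp(normed2).tokens
        return TokenGrid(x, grid.grid_h, grid.grid_w)


class PvTStage(nn.Module):
    """One stage: patch embedding → depth× blocks → closing layer norm."""

    def __init__(self, in_ch: int, cfg: PvTStageConfig, *, rng):
        super().__init__()
        self.cfg = cfg
        self.embed = OverlapPatchEmbed(in_ch, cfg, rng=rng)
        self.blocks = nn.ModuleList(
            [PvTBlock(cfg, rng=rng) for _ in range(cfg.depth)]
        )
        self.norm = nn.LayerNorm(cfg.embed_dim)

    def forward(self, fmap: Tensor) -> Tensor:
        grid = self.embed(fmap)
        for blk in self.blocks:
            grid = blk(grid)
        grid.tokens = self.norm(grid.tokens)
        return grid.to_map()


class PvTBranch(nn.Module):
    """Four-stage pyramid; each stage accepts the previous stage's spatial map
    (possibly replaced by a fused map from the feature-fusion module)."""

    def __init__(self, configs: list[PvTStageConfig] | None = None,
                 in_channels: int = 3, *, rng=None):
        super().__init__()
        if configs is None:
            configs = default_pvt_configs()
        if rng is None:
            rng = np.random.default_rng(0)
        self.configs = configs
        chans = [in_channels] + [c.embed_dim for c in configs[:-1]]
        self.stages = nn.ModuleList(
            [PvTStage(chans[i], configs[i], rng=rng) for i in range(len(configs))]
        )

    def stage_forward(self, index: int, fmap: Tensor) -> Tensor:
        """Run stage ``index`` (0-based) on a spatial map; used for stage-wise
        interleaving with the fusion module."""
        return self.stages[index](fmap)

    def forward(self, image: Tensor) -> list[Tensor]:
        maps = []
        x = image
        for stage in self.stages:
            x = stage(x)
            maps.append(x)
        return maps
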