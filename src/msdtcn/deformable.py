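"""Deformable-attention branch: channel alignment, multi-scale encoder,
and per-level output projections.

The five ResNet taps are mapped to a common width of 256 by per-level 1x1
convolutions, flattened into one token sequence with sinusoidal position
codes plus a learned per-level embedding, and refined by a stack of
deformable self-attention encoder layers.  Each query attends at a small set
of predicted offsets around its own normalized location on every pyramid
level, so the cost stays linear in the token count.  The refined tokens are
folded back into maps and projected by 3x3 convolutions to the pyramid
widths (48, 96, 192, 384, 768).
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Dropout, LayerNorm, Linear, Module, ModuleList
from .nn.deform import ms_deform_sample
from .nn.tensor import Tensor, concat, relu, softmax

T_WIDTHS = (48, 96, 192, 384, 768)
R_WIDTHS = (64, 64, 128, 256, 512)


def sinusoidal_position_embedding(h: int, w: int, dim: int = 256,
                                  temperature: float = 10000.0) -> np.ndarray:
    """(h*w, dim) sine/cosine codes of the normalized (row, col) centers."""
    if dim % 4:
        raise ValueError("embedding dim must be divisible by 4")
    half = dim // 2
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    y = (ys.astype(np.float64) + 0.5) / h * (2 * np.pi)
    x = (xs.astype(np.float64) + 0.5) / w * (2 * np.pi)
    dim_t = temperature ** (2 * (np.arange(half) // 2) / half)
    py = y[..., None] / dim_t
    px = x[..., None] / dim_t
    py = np.stack([np.sin(py[..., 0::2]), np.cos(py[..., 1::2])],
                  axis=-1).reshape(h, w, half)
    px = np.stack([np.sin(px[..., 0::2]), np.cos(px[..., 1::2])],
                  axis=-1).reshape(h, w, half)
    return np.concatenate([py, px], axis=-1).reshape(h * w, dim).astype(np.float32)


def reference_points(shapes) -> np.ndarray:
    """Normalized (x, y) center of every token in its own level; (S, 2)."""
    pts = []
    for h, w in shapes:
        ys, xs = np.meshgrid((np.arange(h) + 0.5) / h,
                             (np.arange(w) + 0.5) / w, indexing="ij")
        pts.append(np.stack([xs, ys], axis=-1).reshape(-1, 2))
    return np.concatenate(pts, axis=0).astype(np.float32)


class MSDeformAttn(Module):
    """Multi-scale deformable self-attention.

    Offset predictors start at zero weights with biases spread over the unit
    directions (scaled by sampling-point index) and the weight head starts
    uniform, the standard stabilizing initialization for this mechanism.
    """

    def __init__(self, rng: np.random.Generator, d_model: int = 256,
                 n_levels: int = 5, n_heads: int = 8, n_points: int = 4):
        super().__init__()
        self.d_model, self.n_levels = d_model, n_levels
        self.n_heads, self.n_points = n_heads, n_points
        self.head_dim = d_model // n_heads
        self.sampling_offsets = Linear(
            d_model, n_heads * n_levels * n_points * 2, rng, init="zero")
        thetas = 2 * np.pi * np.arange(n_heads) / n_heads
        grid = np.stack([np.cos(thetas), np.sin(thetas)], axis=-1)
        grid = grid / np.abs(grid).max(axis=-1, keepdims=True)
        bias = np.tile(grid[:, None, None, :], (1, n_levels, n_points, 1))
        bias *= (np.arange(n_points) + 1)[None, None, :, None]
        self.sampling_offsets.bias.data[...] = bias.reshape(-1)
        self.attention_weights = Linear(
            d_model, n_heads * n_levels * n_points, rng, init="zero")
        self.value_proj = Linear(d_model, d_model, rng)
        self.output_proj = Linear(d_model, d_model, rng)

    def forward(self, query: Tensor, src: Tensor, ref: np.ndarray,
                shapes: np.ndarray, starts: np.ndarray) -> Tensor:
        """query/src: (N, S, C); ref: (S, 2) normalized (x, y) points."""
        n, s, _ = query.shape
        m, l, p = self.n_heads, self.n_levels, self.n_points
        offsets = self.sampling_offsets(query).reshape(n, s, m, l, p, 2)
        weights = softmax(
            self.attention_weights(query).reshape(n, s, m, l * p), axis=-1)
        weights = weights.reshape(n, s, m, l, p)
        value = self.value_proj(src).reshape(n, s, m, self.head_dim)
        # offsets are expressed in texels of each level: normalize by (W, H)
        wh = shapes[:, ::-1].astype(np.float32)  # (L, 2) as (W, H)
        inv_wh = Tensor((1.0 / wh).reshape(1, 1, 1, l, 1, 2))
        loc = Tensor(ref.reshape(1, s, 1, 1, 1, 2)) + offsets * inv_wh
        out = ms_deform_sample(value, loc, weights, shapes, starts)
        return self.output_proj(out.reshape(n, s, self.d_model))


class DeformableEncoderLayer(Module):
    """Deformable self-attention + feed-forward, residual, post-LayerNorm."""

    def __init__(self, rng: np.random.Generator, d_model: int = 256,
                 n_levels: int = 5, n_heads: int = 8, n_points: int = 4,
                 ffn_dim: int = 1024, dropout: float = 0.1):
        super().__init__()
        self.self_attn = MSDeformAttn(rng, d_model, n_levels, n_heads, n_points)
        self.norm1 = LayerNorm(d_model, axis=-1)
        self.linear1 = Linear(d_model, ffn_dim, rng)
        self.linear2 = Linear(ffn_dim, d_model, rng)
        self.norm2 = LayerNorm(d_model, axis=-1)
        self.drop = Dropout(dropout, rng)

    def forward(self, src, pos, ref, shapes, starts):
        attn = self.self_attn(src + pos, src, ref, shapes, starts)
        src = self.norm1(src + self.drop(attn))
        ffn = self.linear2(self.drop(relu(self.linear1(src))))
        return self.norm2(src + self.drop(ffn))


class DeformableBranch(Module):
    """ResNet pyramid -> aligned tokens -> encoder -> projected T pyramid."""

    def __init__(self, rng: np.random.Generator, depth: int = 12,
                 d_model: int = 256, n_heads: int = 8, n_points: int = 4,
                 ffn_dim: int = 1024, dropout: float = 0.1):
        super().__init__()
        self.d_model = d_model
        self.align = ModuleList([Conv2d(c, d_model, 1, rng) for c in R_WIDTHS])
        self.level_embed = Tensor(
            (rng.standard_normal((len(R_WIDTHS), d_model)) * 0.02
             ).astype(np.float32), requires_grad=True)
        self.layers = ModuleList([
            DeformableEncoderLayer(rng, d_model, len(R_WIDTHS), n_heads,
                                   n_points, ffn_dim, dropout)
            for _ in range(depth)])
        self.out_projs = ModuleList(
            [Conv2d(d_model, c, 3, rng, padding=1) for c in T_WIDTHS])

    # ---- pieces (also used directly by tests) ---------------------------
    def align_channels(self, pyramid: list) -> list:
        """Per-level 1x1 convolutions to the common width."""
        return [conv(x) for conv, x in zip(self.align, pyramid)]

    @staticmethod
    def level_shapes(aligned: list) -> np.ndarray:
        return np.array([x.shape[-2:] for x in aligned], dtype=np.int64)

    @staticmethod
    def level_starts(shapes: np.ndarray) -> np.ndarray:
        sizes = shapes[:, 0] * shapes[:, 1]
        return np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.int64)

    def positional_embeddings(self, shapes) -> Tensor:
        """Sinusoidal position codes plus the learned level embedding, (S, C)."""
        parts = []
        for i, (h, w) in enumerate(shapes):
            sine = Tensor(sinusoidal_position_embedding(int(h), int(w),
                                                        self.d_model))
            parts.append(sine + self.level_embed[i: i + 1])
        return concat(parts, axis=0)

    def tokenize(self, aligned: list) -> Tensor:
        """Flatten an aligned pyramid into (N, S, C) token memory."""
        n = aligned[0].shape[0]
        toks = [x.reshape(n, self.d_model, -1).transpose(0, 2, 1)
                for x in aligned]
        return concat(toks, axis=1)

    def encode(self, tokens: Tensor, pos: Tensor, shapes: np.ndarray) -> Tensor:
        """Run the encoder stack; token count and width are preserved."""
        starts = self.level_starts(shapes)
        ref = reference_points(shapes)
        src = tokens
        for layer in self.layers:
            src = layer(src, pos, ref, shapes, starts)
        return src

    def split_project(self, memory: Tensor, shapes: np.ndarray) -> list:
        """Split token memory by level and project each map to its T width."""
        n = memory.shape[0]
        starts = self.level_starts(shapes)
        sizes = shapes[:, 0] * shapes[:, 1]
        outs = []
        for i, ((h, w), s0, sz) in enumerate(zip(shapes, starts, sizes)):
            level = memory[:, int(s0): int(s0 + sz)]
            level = level.transpose(0, 2, 1).reshape(n, self.d_model,
                                                     int(h), int(w))
            outs.append(self.out_projs[i](level))
        return outs

    # ---- full branch ----------------------------------------------------
    def forward(self, resnet_pyramid: list) -> list:
        aligned = self.align_channels(resnet_pyramid)
        shapes = self.level_shapes(aligned)
        tokens = self.tokenize(aligned)
        pos = self.positional_embeddings(shapes)
        memory = self.encode(tokens, pos, shapes)
        return self.split_project(memory, shapes)
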