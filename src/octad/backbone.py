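"""Convolutional backbones and local-region / image-level feature extraction.

Two representations feed the downstream density models:

* **local-region embeddings** — feature grids of two intermediate
  backbone stages are locally average-pooled (3x3, stride 1), the
  coarser grid is upsampled to the finer one by nearest neighbor, and
  the two are concatenated channel-wise, yielding one embedding vector
  per spatial cell of the finer grid;
* **image-level embedding** — the global average pool of the final
  stage's feature grid.

The backbone is pluggable.  ``toy_cnn`` is a small, fully seeded CNN
implemented directly in NumPy (forward and backward passes), mirroring
the stride schedule of a standard residual network: a stride-2 stem
followed by four stages of 3x3 convolution -> leaky ReLU -> 2x2 average
pooling, with 8/16/32/64 channels.  On a 224 input its stages produce
56/28/14/7 grids, so the default stage pair (2, 3) yields a 28x28
region grid on a stride-8 pixel lattice.  Pretrained residual-network
kinds are selectable through :class:`BackboneSpec` but require weight
files that are not bundled; requesting them without such assets raises
a :class:`ResourceError`.

The backward pass exists so the one-class adaptation stage
(:mod:`octad.adapt`) can fine-tune the backbone with a center loss; no
deep-learning framework is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from octad.errors import ConfigurationError, InputError, ResourceError
from octad.prep import PreparedScan

__all__ = [
    "BackboneKind",
    "BackboneSpec",
    "FeatureHierarchy",
    "RegionGrid",
    "ToyCNN",
    "make_backbone",
    "extract_feature_hierarchy",
    "local_embeddings",
    "image_embedding",
]


class BackboneKind(str, Enum):
    pretrained_resnet152 = "pretrained_resnet152"
    pretrained_resnet_small = "pretrained_resnet_small"
    toy_cnn = "toy_cnn"


@dataclass(frozen=True)
class BackboneSpec:
    kind: BackboneKind = BackboneKind.toy_cnn
    seed: int = 0
    blocks_for_regions: tuple[int, int] = (2, 3)
    local_pool_kernel: int = 3

    def __post_init__(self) -> None:
        a, b = self.blocks_for_regions
        if a == b or not ({a, b} <= {1, 2, 3, 4}):
            raise ConfigurationError(
                f"blocks_for_regions must be two distinct stages in 1..4, got {(a, b)}"
            )
        if self.local_pool_kernel < 1 or self.local_pool_kernel % 2 == 0:
            raise ConfigurationError("local_pool_kernel must be odd and positive")


@dataclass
class FeatureHierarchy:
    """Per-stage feature grids plus the global-average-pooled vector."""

    blocks: dict[int, np.ndarray]  # stage index -> (C, H, W)
    pooled_vector: np.ndarray  # (C_final,)
    source_id: str = ""


@dataclass
class RegionGrid:
    """An (H, W) lattice of D-dimensional local-region embeddings."""

    grid: np.ndarray  # (H, W, D)
    source_id: str = ""
    grid_stride: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape[0], self.grid.shape[1]

    @property
    def dim(self) -> int:
        return self.grid.shape[2]

    def vectors(self) -> np.ndarray:
        """Row-major (H*W, D) view of the cell embeddings."""
        return self.grid.reshape(-1, self.grid.shape[2])


# ---------------------------------------------------------------------------
# toy CNN: seeded NumPy forward/backward
# ---------------------------------------------------------------------------

_TOY_CHANNELS = (8, 16, 32, 64)
_LEAK = 0.1


def _conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3x3 'same' convolution via im2col; returns (output, column matrix)."""
    c_in, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    # columns: (H*W, C_in*9)
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    cols = win.transpose(1, 2, 0, 3, 4).reshape(h * wd, c_in * 9)
    out = cols @ w.reshape(w.shape[0], -1).T + b
    return out.T.reshape(w.shape[0], h, wd), cols


def _avgpool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _avgpool2_backward(g: np.ndarray) -> np.ndarray:
    """Distribute pooled gradients back onto the 2x2 source cells."""
    return np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) / 4.0


class ToyCNN:
    """Seeded 4-stage NumPy CNN with explicit gradients for the center loss.

    Weights are a pure function of the seed (He-style normal init).
    Inference is deterministic; there is no normalization state.
    """

    n_stages = 4

    def __init__(self, seed: int = 0, channels: tuple[int, ...] = _TOY_CHANNELS):
        self.seed = int(seed)
        self.channels = tuple(channels)
        rng = np.random.default_rng(np.random.SeedSequence([0x0C7AD, self.seed]))
        self.params: dict[str, np.ndarray] = {}
        c_in = 3
        for i, c_out in enumerate(self.channels, start=1):
            fan_in = c_in * 9
            self.params[f"w{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3)
            )
            self.params[f"b{i}"] = np.zeros(c_out)
            c_in = c_out

    @property
    def final_dim(self) -> int:
        return self.channels[-1]

    def block_channels(self, block: int) -> int:
        return self.channels[block - 1]

    def copy(self) -> "ToyCNN":
        dup = ToyCNN.__new__(ToyCNN)
        dup.seed = self.seed
        dup.channels = self.channels
        dup.params = {k: v.copy() for k, v in self.params.items()}
        return dup

    def forward(self, tensor: np.ndarray, *, want_cache: bool = False):
        """Run the net; returns (blocks, pooled[, cache]).

        ``blocks`` maps stage index (1-based) to the (C, H, W) grid after
        that stage's pooling; ``pooled`` is the spatial mean of stage 4.
        """
        x = np.asarray(tensor, dtype=np.float64)
        if x.ndim != 3 or x.shape[0] != 3:
            raise InputError(f"expected a (3, S, S) tensor, got shape {x.shape}")
        if x.shape[1] % 32 or x.shape[2] % 32:
            raise InputError(
                f"spatial size {x.shape[1:]} must be divisible by 32 "
                "for the toy backbone's stride schedule"
            )
        cache: dict[str, np.ndarray] = {}
        x = _avgpool2(x)  # stem: stride-2 average pool
        blocks: dict[int, np.ndarray] = {}
        for i in range(1, self.n_stages + 1):
            if want_cache:
                cache[f"in{i}"] = x
            pre, cols = _conv2d_same(x, self.params[f"w{i}"], self.params[f"b{i}"])
            act = np.where(pre > 0, pre, _LEAK * pre)
            x = _avgpool2(act)
            blocks[i] = x
            if want_cache:
                cache[f"cols{i}"] = cols
                cache[f"pre{i}"] = pre
        pooled = blocks[self.n_stages].mean(axis=(1, 2))
        if want_cache:
            return blocks, pooled, cache
        return blocks, pooled

    def center_loss_and_grads(
        self, tensor: np.ndarray, center: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Loss ||GAP(f(x)) - c||^2 and its gradient per parameter."""
        blocks, pooled, cache = self.forward(tensor, want_cache=True)
        diff = pooled - np.asarray(center, dtype=np.float64)
        loss = float(diff @ diff)
        top = blocks[self.n_stages]
        c, h, w = top.shape
        g = np.broadcast_to((2.0 * diff / (h * w))[:, None, None], top.shape)
        grads: dict[str, np.ndarray] = {}
        for i in range(self.n_stages, 0, -1):
            g = _avgpool2_backward(g)  # through the stage's pooling
            pre = cache[f"pre{i}"]
            g = g * np.where(pre > 0, 1.0, _LEAK)
            cols = cache[f"cols{i}"]
            c_out = g.shape[0]
            g_mat = g.reshape(c_out, -1)  # (C_out, H*W)
            grads[f"w{i}"] = (g_mat @ cols).reshape(self.params[f"w{i}"].shape)
            grads[f"b{i}"] = g_mat.sum(axis=1)
            if i > 1:
                w_mat = self.params[f"w{i}"].reshape(c_out, -1)  # (C_out, C_in*9)
                g_cols = g_mat.T @ w_mat  # (H*W, C_in*9)
                g = _col2im_same(g_cols, cache[f"in{i}"].shape)
        return loss, grads


def _col2im_same(g_cols: np.ndarray, in_shape: tuple[int, int, int]) -> np.ndarray:
    """Adjoint of the im2col used by :func:`_conv2d_same`."""
    c_in, h, w = in_shape
    gp = np.zeros((c_in, h + 2, w + 2))
    g5 = g_cols.reshape(h, w, c_in, 3, 3)
    for dr in range(3):
        for dc in range(3):
            gp[:, dr : dr + h, dc : dc + w] += g5[:, :, :, dr, dc].transpose(2, 0, 1)
    return gp[:, 1 : 1 + h, 1 : 1 + w]


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def make_backbone(spec: BackboneSpec) -> ToyCNN:
    """Instantiate the backbone described by ``spec``.

    Only ``toy_cnn`` is self-contained; the pretrained kinds need weight
    assets that are not bundled with the package.
    """
    kind = BackboneKind(spec.kind)
    if kind is BackboneKind.toy_cnn:
        return ToyCNN(seed=spec.seed)
    raise ResourceError(
        f"pretrained weights for {kind.value!r} are not available in this "
        "environment; use kind='toy_cnn' for a self-contained seeded backbone"
    )


def extract_feature_hierarchy(backbone: ToyCNN, scan: PreparedScan) -> FeatureHierarchy:
    """Deterministic inference pass producing all stage grids and the GAP vector."""
    blocks, pooled = backbone.forward(scan.tensor)
    return FeatureHierarchy(blocks=blocks, pooled_vector=pooled, source_id=scan.source_id)


def local_embeddings(h: FeatureHierarchy, spec: BackboneSpec) -> RegionGrid:
    """Combine two stage grids into one local-region embedding lattice.

    Each stage grid is average-pooled over a ``local_pool_kernel`` square
    neighborhood (stride 1, edge padding) so every cell summarizes its
    surroundings; the coarser grid is then copied up to the finer grid's
    resolution by nearest neighbor and the channels are concatenated.
    """
    a, b = spec.blocks_for_regions
    for blk in (a, b):
        if blk not in h.blocks:
            raise ConfigurationError(f"stage {blk} not present in the feature hierarchy")
    fa, fb = h.blocks[a], h.blocks[b]
    if fa.shape[1] < fb.shape[1]:
        fa, fb = fb, fa  # fa = finer grid
    k = spec.local_pool_kernel
    if k > 1:
        fa = ndimage.uniform_filter(fa, size=(1, k, k), mode="nearest")
        fb = ndimage.uniform_filter(fb, size=(1, k, k), mode="nearest")
    hf, wf = fa.shape[1], fa.shape[2]
    rows = (np.arange(hf) * fb.shape[1]) // hf
    cols = (np.arange(wf) * fb.shape[2]) // wf
    fb_up = fb[:, rows[:, None], cols[None, :]]
    grid = np.concatenate([fa, fb_up], axis=0).transpose(1, 2, 0)
    # infer the prepared-image size from the stem+pool stride schedule
    return RegionGrid(grid=np.ascontiguousarray(grid), source_id=h.source_id,
                      grid_stride=_infer_stride(h, hf))


def _infer_stride(h: FeatureHierarchy, grid_h: int) -> float:
    final = max(h.blocks)
    prepared = h.blocks[final].shape[1] * (2 ** (final + 1))
    return prepared / grid_h


def image_embedding(h: FeatureHierarchy) -> np.ndarray:
    """The image-level representation: the global-average-pooled vector."""
    return np.asarray(h.pooled_vector)
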