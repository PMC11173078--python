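"""Alternative density backends: per-position Gaussian fields and
gallery-retrieval pixel scoring.

The Gaussian backend fits one multivariate normal per grid position
from the healthy training grids and scores test cells by Mahalanobis
distance to the distribution at their own position — fast, but it bakes
in an alignment assumption.  The gallery backend first retrieves the K
most similar healthy scans by image-level embedding and then scores each
test cell by kNN distance against the pooled cells of just those scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from octad.backbone import RegionGrid
from octad.bank import KnnConfig, ScoreGrid, _knn_mean_dists
from octad.errors import ConfigurationError, InputError

__all__ = [
    "GaussianField",
    "GalleryRetrieval",
    "fit_gaussian_field",
    "mahalanobis_scores",
    "retrieve_knn_images",
    "spade_pixel_scores",
]


@dataclass
class GaussianField:
    """Per-position mean and regularized covariance of healthy embeddings.

    Covariances carry a ridge ``epsilon * I`` so every matrix is
    symmetric positive definite even where the sample covariance is
    rank-deficient.
    """

    mean: np.ndarray  # (H, W, D)
    covariance: np.ndarray  # (H, W, D, D), already regularized
    epsilon: float
    n_train: int

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.mean.shape[0], self.mean.shape[1]

    @property
    def dim(self) -> int:
        return self.mean.shape[2]


def fit_gaussian_field(
    train_grids: list[RegionGrid], epsilon: float = 0.01
) -> GaussianField:
    """Sample mean and (n-1)-denominator covariance at each grid cell."""
    if len(train_grids) < 2:
        raise InputError(
            "Gaussian field estimation needs at least two training grids"
        )
    if epsilon < 0:
        raise ConfigurationError("epsilon must be non-negative")
    shape, dim = train_grids[0].shape, train_grids[0].dim
    for g in train_grids:
        if g.shape != shape or g.dim != dim:
            raise InputError("training grids must share (H, W, D)")
    stack = np.stack([g.grid for g in train_grids], axis=0)  # (n, H, W, D)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    centered = stack - mean
    cov = np.einsum("nhwi,nhwj->hwij", centered, centered) / (n - 1)
    cov += epsilon * np.eye(dim)
    return GaussianField(mean=mean, covariance=cov, epsilon=float(epsilon), n_train=n)


def mahalanobis_scores(grid: RegionGrid, field: GaussianField) -> ScoreGrid:
    """sqrt((x-mu)^T Sigma^{-1} (x-mu)) at each cell's own position."""
    if grid.shape != field.grid_shape or grid.dim != field.dim:
        raise InputError(
            f"grid {grid.shape}x{grid.dim} does not match field "
            f"{field.grid_shape}x{field.dim}"
        )
    h, w = grid.shape
    diff = grid.grid - field.mean
    # batched Cholesky + triangular solve, one factor per position
    chol = np.linalg.cholesky(field.covariance.reshape(h * w, field.dim, field.dim))
    y = np.linalg.solve(chol, diff.reshape(h * w, field.dim, 1)).reshape(h * w, field.dim)
    out = np.sqrt((y * y).sum(axis=1)).reshape(h, w)
    return ScoreGrid(grid=out, source_id=grid.source_id, grid_stride=grid.grid_stride)


@dataclass
class GalleryRetrieval:
    """The K healthy scans most similar to a query, by image embedding."""

    query_id: str
    neighbor_ids: list[str]
    K: int


def retrieve_knn_images(
    query_embedding: np.ndarray,
    train_embeddings: list[np.ndarray],
    K: int = 5,
    train_ids: list[str] | None = None,
    query_id: str = "",
) -> GalleryRetrieval:
    """K nearest training scans by Euclidean distance on image embeddings."""
    n = len(train_embeddings)
    if K > n:
        raise ConfigurationError(f"K={K} exceeds the {n} training scans")
    mat = np.asarray(train_embeddings, dtype=np.float64)
    d = np.linalg.norm(mat - np.asarray(query_embedding, dtype=np.float64), axis=1)
    order = np.argsort(d, kind="stable")[:K]  # stable: ties by training index
    ids = train_ids if train_ids is not None else [str(i) for i in range(n)]
    return GalleryRetrieval(query_id=query_id, neighbor_ids=[ids[i] for i in order], K=K)


def spade_pixel_scores(
    query_grid: RegionGrid,
    gallery_grids: list[RegionGrid],
    cfg: KnnConfig | None = None,
) -> ScoreGrid:
    """Score each query cell against the pooled cells of the retrieved gallery."""
    cfg = cfg or KnnConfig()
    if not gallery_grids:
        raise InputError("gallery is empty")
    for g in gallery_grids:
        if g.shape != query_grid.shape or g.dim != query_grid.dim:
            raise InputError("gallery grids must share (H, W, D) with the query")
    pool = np.concatenate([g.vectors() for g in gallery_grids], axis=0)
    if len(pool) < cfg.k:
        raise ConfigurationError(
            f"pooled gallery of {len(pool)} cells is smaller than k={cfg.k}"
        )
    scores = _knn_mean_dists(query_grid.vectors(), pool, cfg.k)
    h, w = query_grid.shape
    return ScoreGrid(grid=scores.reshape(h, w), source_id=query_grid.source_id,
                     grid_stride=query_grid.grid_stride)
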