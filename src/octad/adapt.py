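"""One-class feature adaptation: center loss with elastic weight consolidation.

The backbone is fine-tuned on healthy scans only.  The target is the
*center* — the mean image-level embedding of the training set under the
initial weights, frozen thereafter (a moving center would admit the
trivial solution of shifting the center instead of the features).  The
loss per scan is ``||f(x) - c||^2``; to keep the generic pretrained
representation from collapsing (catastrophic forgetting), parameter
drift is penalized by an elastic-weight-consolidation (EWC) term
``lambda * sum_i F_i (theta_i - theta_i^0)^2`` with a diagonal Fisher
estimate ``F``.

Numerics: the center-loss gradient is applied with Adam-style
per-parameter step sizes ``alpha_i`` (curvature across the conv stack
varies by orders of magnitude, making fixed-step gradient descent
either inert or divergent on this loss), while the quadratic EWC
penalty is applied *implicitly* (a proximal step, exact for a
quadratic):

    theta <- theta0 + (theta - alpha * m_hat - theta0) / (1 + 2 * alpha * lambda * F).

This reduces to a plain adaptive step at ``lambda = 0`` and remains
stable for arbitrarily large ``lambda``, where it pins parameters at
``theta0`` exactly — an explicit step on the penalty would oscillate
and diverge there for any fixed step size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from octad.backbone import ToyCNN
from octad.errors import InputError, TrainingError
from octad.prep import PreparedScan

__all__ = [
    "CenterState",
    "AdaptConfig",
    "FisherDiag",
    "compute_center",
    "estimate_fisher_diag",
    "adapt_backbone",
    "mean_center_loss",
]


@dataclass
class CenterState:
    """The frozen center of the healthy image-embedding cloud."""

    center: np.ndarray

    @property
    def dim(self) -> int:
        return len(self.center)


@dataclass(frozen=True)
class AdaptConfig:
    epochs: int = 40
    learning_rate: float = 1e-4
    ewc_lambda: float = 1e4
    fisher_samples: int = 32
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0 or self.ewc_lambda < 0:
            raise ValueError("learning_rate must be > 0 and ewc_lambda >= 0")
        if self.fisher_samples < 1 or self.batch_size < 1:
            raise ValueError("fisher_samples and batch_size must be positive")


@dataclass
class FisherDiag:
    """Diagonal Fisher-information weights, one array per parameter."""

    weights: dict[str, np.ndarray]


def compute_center(embeddings: list[np.ndarray]) -> CenterState:
    """Arithmetic mean of the image-level embeddings."""
    if len(embeddings) == 0:
        raise InputError("cannot compute a center from zero embeddings")
    return CenterState(center=np.mean(np.asarray(embeddings, dtype=np.float64), axis=0))


def estimate_fisher_diag(
    backbone: ToyCNN,
    train_scans: list[PreparedScan],
    state: CenterState,
    cfg: AdaptConfig,
) -> FisherDiag:
    """Average squared center-loss gradients over ``fisher_samples`` scans.

    The Fisher diagonal is anchored at the *initial* weights, on the
    in-distribution healthy scans, so the EWC penalty protects exactly
    the directions the center loss is sensitive to at the start.
    """
    n = len(train_scans)
    samples = cfg.fisher_samples
    if samples > n:
        warnings.warn(
            f"fisher_samples={samples} exceeds the {n} available scans; clipping",
            stacklevel=2,
        )
        samples = n
    rng = np.random.default_rng(np.random.SeedSequence([0xF15, cfg.seed]))
    order = rng.permutation(n)[:samples]
    acc = {k: np.zeros_like(v) for k, v in backbone.params.items()}
    for i in order:
        _, grads = backbone.center_loss_and_grads(train_scans[i].tensor, state.center)
        for k, g in grads.items():
            acc[k] += g * g
    return FisherDiag(weights={k: v / samples for k, v in acc.items()})


def mean_center_loss(
    backbone: ToyCNN, scans: list[PreparedScan], state: CenterState
) -> float:
    """Mean ||f(x) - c||^2 over the scans (no EWC term)."""
    total = 0.0
    for s in scans:
        _, pooled = backbone.forward(s.tensor)
        diff = pooled - state.center
        total += float(diff @ diff)
    return total / len(scans)


def adapt_backbone(
    backbone: ToyCNN,
    train_scans: list[PreparedScan],
    cfg: AdaptConfig | None = None,
    state: CenterState | None = None,
    fisher: FisherDiag | None = None,
) -> tuple[ToyCNN, list[float]]:
    """Fine-tune a copy of the backbone with center loss + EWC.

    Returns the adapted backbone and the per-epoch mean center loss
    (evaluated on the pre-update weights within each epoch).  The input
    backbone is left untouched.  The center and Fisher diagonal are
    computed from the initial weights when not supplied.
    """
    cfg = cfg or AdaptConfig()
    if not train_scans:
        raise InputError("no training scans provided")
    if state is None:
        embs = [backbone.forward(s.tensor)[1] for s in train_scans]
        state = compute_center(embs)
    if fisher is None and cfg.ewc_lambda > 0:
        fisher = estimate_fisher_diag(backbone, train_scans, state, cfg)

    net = backbone.copy()
    theta0 = {k: v.copy() for k, v in net.params.items()}
    rng = np.random.default_rng(np.random.SeedSequence([0xADA, cfg.seed]))
    n = len(train_scans)
    history: list[float] = []
    lr = cfg.learning_rate
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m1 = {k: np.zeros_like(v) for k, v in net.params.items()}
    m2 = {k: np.zeros_like(v) for k, v in net.params.items()}
    t = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            grads = {k: np.zeros_like(v) for k, v in net.params.items()}
            for i in batch:
                loss, g = net.center_loss_and_grads(
                    train_scans[i].tensor, state.center
                )
                epoch_loss += loss
                for k in grads:
                    grads[k] += g[k]
            t += 1
            for k, p in net.params.items():
                g = grads[k] / len(batch)
                m1[k] = beta1 * m1[k] + (1 - beta1) * g
                m2[k] = beta2 * m2[k] + (1 - beta2) * g * g
                mh = m1[k] / (1 - beta1**t)
                vh = m2[k] / (1 - beta2**t)
                alpha = lr / (np.sqrt(vh) + eps)  # per-parameter step size
                step = p - alpha * mh
                if cfg.ewc_lambda > 0:
                    denom = 1.0 + 2.0 * alpha * cfg.ewc_lambda * fisher.weights[k]
                    p[...] = theta0[k] + (step - theta0[k]) / denom
                else:
                    p[...] = step
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise TrainingError(f"center loss diverged at epoch {epoch}")
        history.append(epoch_loss)
    return net, history
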