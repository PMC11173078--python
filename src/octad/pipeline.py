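"""End-to-end orchestration: fit on healthy scans, score, evaluate.

Backends
--------
``global_knn``
    Local-region bank (optionally coreset-compressed), each test region
    scored against the whole bank regardless of position.
``aligned_knn``
    Same bank, uncompressed, scored only against same-position members.
``gaussian``
    Per-position Gaussian field, Mahalanobis scoring.
``spade``
    Image-embedding retrieval of K similar healthy scans, then pooled
    region kNN against that gallery only.
``image_level_knn``
    kNN distance on the global-average-pooled image embedding — no
    region grid and hence no localization map.

Every stage is deterministic given the run seed: backbone weights,
coreset selection, and adaptation batching all derive their streams
from it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from octad import adapt as _adapt
from octad import bank as _bank
from octad import density as _density
from octad import evaluate as _eval
from octad.backbone import (
    BackboneSpec,
    RegionGrid,
    extract_feature_hierarchy,
    image_embedding,
    local_embeddings,
    make_backbone,
)
from octad.errors import ConfigurationError, InputError
from octad.prep import MarginConfig, PrepConfig, PreparedScan, RawScan, load_scan, prepare, remove_margins

__all__ = ["BACKENDS", "RunConfig", "FittedModel", "ScanResult", "fit", "score", "evaluate", "run_experiment"]

BACKENDS = ("global_knn", "aligned_knn", "gaussian", "spade", "image_level_knn")


@dataclass
class RunConfig:
    backend: str = "global_knn"
    prep: PrepConfig = field(default_factory=PrepConfig)
    margins: MarginConfig = field(default_factory=MarginConfig)
    remove_margins: bool = True
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    knn: _bank.KnnConfig = field(default_factory=_bank.KnnConfig)
    coreset_fraction: float = 0.10  # clinical-scale profile; 1.0 disables
    coreset_projection: int | None = 24  # selection-time random projection
    gallery_k: int = 5  # retrieved scans for the spade backend
    gaussian_epsilon: float = 0.01
    adapt_enabled: bool = False
    adapt: _adapt.AdaptConfig = field(default_factory=_adapt.AdaptConfig)
    seeds: tuple[int, ...] = (0, 1, 2)
    heatmap_sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ConfigurationError(
                f"backend must be one of {BACKENDS}, got {self.backend!r}"
            )
        if not self.seeds:
            raise ConfigurationError("seeds must be non-empty")

    def with_seed(self, seed: int) -> "RunConfig":
        """Rebind every stochastic stage to streams derived from ``seed``."""
        return dataclasses.replace(
            self,
            backbone=dataclasses.replace(self.backbone, seed=seed),
            adapt=dataclasses.replace(self.adapt, seed=seed),
            seeds=(seed,),
        )


@dataclass
class FittedModel:
    config: RunConfig
    backbone: object
    bank: _bank.NominalBank | None = None
    gaussian: _density.GaussianField | None = None
    image_embeddings: np.ndarray | None = None
    image_ids: list[str] = field(default_factory=list)
    gallery_grids: list[RegionGrid] | None = None
    center: _adapt.CenterState | None = None
    adapt_history: list[float] | None = None
    n_train: int = 0


@dataclass
class ScanResult:
    source_id: str
    image_score: float
    score_grid: _bank.ScoreGrid | None
    anomaly_map: _eval.AnomalyMap | None
    crop_box: tuple[int, int, int, int]


def _load_dir(path) -> list[RawScan]:
    files = sorted(
        p for p in Path(path).rglob("*")
        if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
    )
    return [load_scan(p) for p in files]


def _prepare_all(scans: list[RawScan], cfg: RunConfig) -> list[PreparedScan]:
    out = []
    for s in scans:
        if cfg.remove_margins:
            s = remove_margins(s, cfg.margins)
        out.append(prepare(s, cfg.prep))
    return out


def _region_grid(model_backbone, spec: BackboneSpec, prepped: PreparedScan) -> RegionGrid:
    h = extract_feature_hierarchy(model_backbone, prepped)
    return local_embeddings(h, spec)


def fit(config: RunConfig, train, seed: int | None = None) -> FittedModel:
    """Fit the configured backend on normal-only training scans.

    ``train`` is a directory or a list of :class:`RawScan`.  A single
    run seed drives backbone init, adaptation, and coreset selection.
    """
    if seed is None:
        seed = config.seeds[0]
    cfg = config.with_seed(seed)
    scans = _load_dir(train) if isinstance(train, (str, Path)) else list(train)
    if not scans:
        raise InputError("training set is empty")
    prepped = _prepare_all(scans, cfg)
    backbone = make_backbone(cfg.backbone)

    center = None
    history = None
    if cfg.adapt_enabled:
        # center frozen at the pre-adaptation embeddings
        embs0 = [backbone.forward(s.tensor)[1] for s in prepped]
        center = _adapt.compute_center(embs0)
        backbone, history = _adapt.adapt_backbone(
            backbone, prepped, cfg.adapt, state=center
        )

    model = FittedModel(config=cfg, backbone=backbone, center=center,
                        adapt_history=history, n_train=len(prepped))
    backend = cfg.backend
    if backend in ("global_knn", "aligned_knn"):
        grids = [_region_grid(backbone, cfg.backbone, p) for p in prepped]
        nominal = _bank.build_bank(grids)
        if backend == "global_knn" and cfg.coreset_fraction < 1.0:
            nominal = _bank.greedy_coreset(
                nominal,
                _bank.CoresetConfig(fraction=cfg.coreset_fraction, seed=seed,
                                    projection_dim=cfg.coreset_projection),
            )
        model.bank = nominal
    elif backend == "gaussian":
        grids = [_region_grid(backbone, cfg.backbone, p) for p in prepped]
        model.gaussian = _density.fit_gaussian_field(grids, cfg.gaussian_epsilon)
    elif backend == "spade":
        model.gallery_grids = [_region_grid(backbone, cfg.backbone, p) for p in prepped]
        hs = [extract_feature_hierarchy(backbone, p) for p in prepped]
        model.image_embeddings = np.asarray([image_embedding(h) for h in hs])
        model.image_ids = [p.source_id for p in prepped]
    elif backend == "image_level_knn":
        hs = [extract_feature_hierarchy(backbone, p) for p in prepped]
        model.image_embeddings = np.asarray([image_embedding(h) for h in hs])
        model.image_ids = [p.source_id for p in prepped]
    return model


def _score_one(model: FittedModel, prepped: PreparedScan) -> ScanResult:
    cfg = model.config
    backend = cfg.backend
    if backend == "image_level_knn":
        h = extract_feature_hierarchy(model.backbone, prepped)
        emb = image_embedding(h)
        nn_bank = _bank.NominalBank(
            vectors=model.image_embeddings,
            positions=np.zeros((len(model.image_embeddings), 2), dtype=np.int64),
            grid_shape=(1, 1),
        )
        s = _bank.knn_avg_distance(emb, nn_bank, cfg.knn)
        return ScanResult(prepped.source_id, s, None, None, prepped.crop_box)

    grid = _region_grid(model.backbone, cfg.backbone, prepped)
    if backend == "global_knn":
        sg = _bank.score_regions_global(grid, model.bank, cfg.knn)
    elif backend == "aligned_knn":
        sg = _bank.score_regions_aligned(grid, model.bank, cfg.knn)
    elif backend == "gaussian":
        sg = _density.mahalanobis_scores(grid, model.gaussian)
    elif backend == "spade":
        h = extract_feature_hierarchy(model.backbone, prepped)
        ret = _density.retrieve_knn_images(
            image_embedding(h), list(model.image_embeddings),
            K=min(cfg.gallery_k, len(model.image_ids)), train_ids=model.image_ids,
            query_id=prepped.source_id,
        )
        by_id = {i: g for i, g in zip(model.image_ids, model.gallery_grids)}
        sg = _density.spade_pixel_scores(grid, [by_id[i] for i in ret.neighbor_ids], cfg.knn)
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown backend {backend!r}")
    amap = _eval.anomaly_heatmap(sg, cfg.prep.target_size, cfg.heatmap_sigma)
    return ScanResult(prepped.source_id, _eval.image_score(sg), sg, amap, prepped.crop_box)


def score(model: FittedModel, scans) -> list[ScanResult]:
    """Score a directory or list of :class:`RawScan` against the model."""
    raw = _load_dir(scans) if isinstance(scans, (str, Path)) else list(scans)
    prepped = _prepare_all(raw, model.config)
    return [_score_one(model, p) for p in prepped]


def evaluate(model: FittedModel, test_scans, labels) -> dict:
    """Pooled metrics plus per-pathology one-vs-normal AUC.

    ``labels`` are strings aligned with ``test_scans``; any label other
    than ``"normal"`` counts as anomalous.
    """
    results = score(model, test_scans)
    labels = list(labels)
    if len(labels) != len(results):
        raise InputError("labels must align with the test scans")
    s = np.asarray([r.image_score for r in results])
    y = np.asarray([0 if l == "normal" else 1 for l in labels])
    if y.min() == y.max():
        raise InputError("test set must contain both normal and anomalous scans")
    thr = _eval.select_threshold_max_f1(s, y)
    pooled = _eval.classification_metrics(s, y, thr)
    per_path = {}
    for kind in sorted(set(labels) - {"normal"}):
        sel = (y == 0) | (np.asarray(labels) == kind)
        per_path[kind] = _eval.roc_auc(s[sel], y[sel])
    return {
        "pooled": pooled,
        "per_pathology_auc": per_path,
        "scores": pd.DataFrame(
            {"source_id": [r.source_id for r in results], "label": labels, "score": s}
        ),
        "results": results,
    }


def run_experiment(config: RunConfig, train, test_scans, labels) -> dict:
    """Run fit+evaluate for every configured seed; report mean and sd.

    Mirrors the protocol of repeating every experiment with three random
    seeds and reporting averaged metrics.
    """
    per_seed = []
    for sd in config.seeds:
        model = fit(config, train, seed=sd)
        per_seed.append(evaluate(model, test_scans, labels))
    aucs = np.asarray([r["pooled"].roc_auc for r in per_seed])
    per_path = {}
    for kind in per_seed[0]["per_pathology_auc"]:
        vals = np.asarray([r["per_pathology_auc"][kind] for r in per_seed])
        per_path[kind] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    return {
        "pooled_auc": {"mean": float(aucs.mean()), "sd": float(aucs.std(ddof=0))},
        "per_pathology_auc": per_path,
        "per_seed": per_seed,
    }


# ---------------------------------------------------------------------------
# config and model (de)serialization
# ---------------------------------------------------------------------------


def config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["backbone"]["kind"] = str(
        getattr(cfg.backbone.kind, "value", cfg.backbone.kind)
    )
    return d


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d or {})
    kw: dict = {}
    if "prep" in d:
        kw["prep"] = PrepConfig(**d.pop("prep"))
    if "margins" in d:
        kw["margins"] = MarginConfig(**d.pop("margins"))
    if "backbone" in d:
        b = dict(d.pop("backbone"))
        if "blocks_for_regions" in b:
            b["blocks_for_regions"] = tuple(b["blocks_for_regions"])
        kw["backbone"] = BackboneSpec(**b)
    if "knn" in d:
        kw["knn"] = _bank.KnnConfig(**d.pop("knn"))
    if "adapt" in d:
        kw["adapt"] = _adapt.AdaptConfig(**d.pop("adapt"))
    if "seeds" in d:
        kw["seeds"] = tuple(d.pop("seeds"))
    kw.update(d)
    return RunConfig(**kw)


def save_model(model: FittedModel, out_dir) -> Path:
    """Persist a fitted model as one .npz tensor container + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for k, v in model.backbone.params.items():
        arrays[f"backbone.{k}"] = v
    if model.bank is not None:
        arrays["bank.vectors"] = model.bank.vectors
        arrays["bank.positions"] = model.bank.positions
    if model.gaussian is not None:
        arrays["gauss.mean"] = model.gaussian.mean
        arrays["gauss.cov"] = model.gaussian.covariance
    if model.image_embeddings is not None:
        arrays["image_embeddings"] = model.image_embeddings
    if model.gallery_grids is not None:
        arrays["gallery.stack"] = np.stack([g.grid for g in model.gallery_grids])
        arrays["gallery.stride"] = np.asarray(
            [g.grid_stride for g in model.gallery_grids]
        )
    if model.center is not None:
        arrays["center"] = model.center.center
    np.savez_compressed(out / "model.npz", **arrays)
    meta = {
        "config": config_to_dict(model.config),
        "n_train": model.n_train,
        "image_ids": model.image_ids,
        "adapt_history": model.adapt_history,
        "bank": None if model.bank is None else {
            "grid_shape": list(model.bank.grid_shape),
            "is_coreset": model.bank.is_coreset,
            "source_fraction": model.bank.source_fraction,
        },
        "gaussian": None if model.gaussian is None else {
            "epsilon": model.gaussian.epsilon, "n_train": model.gaussian.n_train,
        },
        "gallery_ids": None if model.gallery_grids is None else
            [g.source_id for g in model.gallery_grids],
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    return out


def load_model(model_dir) -> FittedModel:
    d = Path(model_dir)
    meta = json.loads((d / "model.json").read_text())
    data = np.load(d / "model.npz")
    cfg = config_from_dict(meta["config"])
    backbone = make_backbone(cfg.backbone)
    for k in backbone.params:
        backbone.params[k] = data[f"backbone.{k}"]
    model = FittedModel(config=cfg, backbone=backbone,
                        n_train=meta["n_train"], image_ids=meta["image_ids"] or [],
                        adapt_history=meta["adapt_history"])
    if meta["bank"] is not None:
        model.bank = _bank.NominalBank(
            vectors=data["bank.vectors"], positions=data["bank.positions"],
            grid_shape=tuple(meta["bank"]["grid_shape"]),
            is_coreset=meta["bank"]["is_coreset"],
            source_fraction=meta["bank"]["source_fraction"],
        )
    if meta["gaussian"] is not None:
        model.gaussian = _density.GaussianField(
            mean=data["gauss.mean"], covariance=data["gauss.cov"],
            epsilon=meta["gaussian"]["epsilon"], n_train=meta["gaussian"]["n_train"],
        )
    if "image_embeddings" in data:
        model.image_embeddings = data["image_embeddings"]
    if meta.get("gallery_ids"):
        stack = data["gallery.stack"]
        strides = data["gallery.stride"]
        model.gallery_grids = [
            RegionGrid(grid=stack[i], source_id=sid, grid_stride=float(strides[i]))
            for i, sid in enumerate(meta["gallery_ids"])
        ]
    if "center" in data:
        model.center = _adapt.CenterState(center=data["center"])
    return model
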