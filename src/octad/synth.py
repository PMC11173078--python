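"""Seeded synthetic OCT B-scan generator with ground-truth anomaly masks.

Scans are built as stacked horizontal retinal bands whose boundaries
carry a random vertical offset, tilt, sinusoidal curvature, and a
smoothed random walk — so scans are unaligned and uncentered, like real
B-scan exports.  Intensity is corrupted by multiplicative gamma speckle
(shape 4 by default), the standard OCT noise family.  Three anomaly
phenotypes are injected into an otherwise identical "normal twin":

* ``drusen`` — a localized Gaussian bump elevating a deep band boundary
  (focal elevation of the retinal pigment epithelium);
* ``dme_fluid`` — a dark elliptical cavity inside the band stack
  (intra-retinal fluid, intensity scaled to ~0.2 of the tissue value);
* ``cnv`` — local scrambling of several band boundaries plus a bright
  irregular blob (neovascular structural disruption).

Because the twin shares the geometry and the speckle field, the
ground-truth mask (pixels whose noiseless value changed by more than a
fixed tolerance) is exact: outside the mask the anomalous scan equals
its normal twin bit-for-bit.  Optional solid white/black margins
emulate scanner padding and exercise the margin-removal preprocessing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter1d

from octad.errors import InputError
from octad.prep import RawScan

__all__ = [
    "ANOMALY_KINDS",
    "SynthConfig",
    "SynthScan",
    "generate_normal",
    "generate_anomalous",
    "generate_dataset",
]

ANOMALY_KINDS = ("cnv", "dme_fluid", "drusen")

_MASK_TOL = 0.02  # noiseless intensity change that defines a mask pixel


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; defaults emulate a noisy, unaligned B-scan."""

    size: int = 224  # pre-margin image side
    n_layers: int = 6
    layer_contrast: float = 0.25  # intensity gap between alternating bands
    speckle_shape: float = 4.0  # gamma shape; larger = less noise
    curvature_amplitude: float = 6.0  # px of sinusoidal boundary curvature
    margin_prob: float = 0.0
    anomaly_size: tuple[int, int] = (8, 40)  # linear extent range, px

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise InputError("n_layers must be >= 2")
        if self.anomaly_size[0] >= self.anomaly_size[1]:
            raise InputError("anomaly_size range must be non-degenerate")

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class SynthScan:
    image: RawScan
    label: str  # normal | cnv | dme_fluid | drusen
    mask: np.ndarray | None  # bool (H, W); None for normal scans
    provenance: dict = field(default_factory=dict)


def _streams(seed: int):
    root = np.random.SeedSequence([0x0C75, int(seed)])
    geom, anom, speckle, margin = root.spawn(4)
    return (np.random.default_rng(geom), np.random.default_rng(anom),
            np.random.default_rng(speckle), np.random.default_rng(margin))


_BG_TOP = 0.12  # vitreous; kept above the black threshold even under speckle
_BG_BOTTOM = 0.20  # choroid


def _geometry(cfg: SynthConfig, rng: np.random.Generator):
    """Boundary curves (n_layers+1, size) and per-band intensities."""
    s = cfg.size
    x = np.arange(s)
    top = s * (0.28 + rng.uniform(-0.08, 0.08))
    thickness = s * 0.38
    tilt = rng.uniform(-0.12, 0.12)
    phase = rng.uniform(0, 2 * np.pi)
    freq = rng.uniform(0.8, 1.6)
    base = top + tilt * (x - s / 2) + cfg.curvature_amplitude * np.sin(
        2 * np.pi * freq * x / s + phase
    )
    bounds = []
    for j in range(cfg.n_layers + 1):
        walk = gaussian_filter1d(rng.normal(0.0, 0.6, s).cumsum(), sigma=12)
        walk -= walk.mean()
        bounds.append(base + thickness * j / cfg.n_layers + 0.4 * walk)
    bounds = np.asarray(bounds)
    bounds = np.sort(bounds, axis=0)  # keep bands ordered even after the walks
    lo, hi = 0.30, 0.30 + cfg.layer_contrast
    intens = np.empty(cfg.n_layers + 2)
    intens[0] = _BG_TOP
    for j in range(cfg.n_layers):
        intens[1 + j] = (hi if j % 2 == 0 else lo) + 0.015 * j
    intens[-1] = _BG_BOTTOM
    return bounds, intens


def _rasterize(bounds: np.ndarray, intens: np.ndarray, size: int) -> np.ndarray:
    rows = np.arange(size)[:, None]
    region = (rows >= bounds[:, None, :]).sum(axis=0)  # (size, size) in 0..n_layers+1
    return intens[region]


_DRUSEN_DEPOSIT = 0.48  # medium homogeneous reflectivity of sub-RPE material
_SHADOW_FACTOR = 0.65  # signal attenuation beneath the deposit


def _inject(cfg, kind, bounds, intens, rng):
    """Return (bounds, mul, add, override) describing one anomaly."""
    s = cfg.size
    lo, hi = cfg.anomaly_size
    extent = rng.uniform(lo, hi)
    x = np.arange(s)
    yy = np.arange(s)[:, None]
    bounds = bounds.copy()
    mul = np.ones((s, s))
    add = np.zeros((s, s))
    override = np.full((s, s), np.nan)
    cx = rng.uniform(0.2 * s, 0.8 * s)
    if kind == "drusen":
        j = cfg.n_layers - 1  # deep boundary: RPE-like elevation
        height = max(6.0, extent * rng.uniform(0.5, 0.9))
        bump = height * np.exp(-0.5 * ((x - cx) / (extent / 2.5)) ** 2)
        bruch = bounds[j].copy()  # the unmoved floor of the deposit
        # the deposit lifts the deep boundary most and the ones above it
        # progressively less, forming a draped dome without crossings
        for i in range(1, j + 1):
            bounds[i] -= bump * (i / j)
        bounds = np.sort(bounds, axis=0)
        col = bump > 1.0
        deposit = (yy >= bounds[j][None, :]) & (yy < bruch[None, :]) & col[None, :]
        override[deposit] = _DRUSEN_DEPOSIT
        shadow = (yy >= bruch[None, :]) & (bump > 0.3 * height)[None, :]
        mul[shadow] = _SHADOW_FACTOR
    elif kind == "dme_fluid":
        # cystoid edema: the retina swells around a cluster of
        # hyporeflective cysts separated by tissue septa
        h = max(6.0, 0.6 * extent)
        swell = h * np.exp(-0.5 * ((x - cx) / (extent / 1.5)) ** 2)
        jc = cfg.n_layers // 2
        for i in range(0, jc + 1):
            bounds[i] -= swell * (1.0 - i / (jc + 1))
        bounds = np.sort(bounds, axis=0)
        mid = 0.5 * (bounds[1] + bounds[-2])
        cy0 = float(mid[int(cx)]) + rng.uniform(-0.05, 0.05) * s
        n_cysts = int(rng.integers(2, 6))
        fluid = np.zeros((s, s), dtype=bool)
        for _ in range(n_cysts):
            ccx = cx + rng.uniform(-0.5, 0.5) * extent
            ccy = cy0 + rng.uniform(-0.35, 0.35) * extent
            a = max(3.0, extent * rng.uniform(0.15, 0.4))
            b = max(3.0, a * rng.uniform(0.5, 0.9))
            fluid |= ((x[None, :] - ccx) / a) ** 2 + ((yy - ccy) / b) ** 2 <= 1.0
        mul[fluid] = 0.2
    elif kind == "cnv":
        j0 = max(1, cfg.n_layers - 4)
        env = np.exp(-0.5 * ((x - cx) / (extent / 2.0)) ** 2)
        for j in range(j0, cfg.n_layers + 1):
            # jagged, steep local disruption — well outside the smooth
            # curvature family of healthy boundaries
            rough = gaussian_filter1d(rng.normal(0.0, 14.0, s), sigma=2)
            bounds[j] += env * rough
        bounds = np.sort(bounds, axis=0)
        cy = float(bounds[cfg.n_layers - 1][int(cx)])
        r = extent / 2.0
        blob = ((x[None, :] - cx) / r) ** 2 + ((yy - cy) / (0.7 * r)) ** 2
        wob = 1.0 + 0.3 * np.sin(3.0 * np.arctan2(yy - cy, x[None, :] - cx + 1e-9)
                                 + rng.uniform(0, 2 * np.pi))
        add[blob <= wob] = 0.35
        shadow = (yy >= cy) & (env > 0.5)[None, :]
        mul[shadow] = _SHADOW_FACTOR
    else:
        raise InputError(f"unknown anomaly kind {kind!r}")
    return bounds, mul, add, override


def _margins(cfg: SynthConfig, rng: np.random.Generator):
    """Draw margin widths/color; consumes the same draws whether or not applied."""
    u = rng.uniform()
    color = 1.0 if rng.uniform() < 0.5 else 0.0
    sides = rng.uniform(size=4) < 0.6  # top, bottom, left, right
    widths = rng.integers(8, 25, size=4)
    if u >= cfg.margin_prob or not sides.any():
        return {"top": 0, "bottom": 0, "left": 0, "right": 0}, color
    w = {name: int(widths[i]) if sides[i] else 0
         for i, name in enumerate(("top", "bottom", "left", "right"))}
    return w, color


def _apply_margins(img, mask, widths, color):
    t, b, l, r = widths["top"], widths["bottom"], widths["left"], widths["right"]
    if t + b + l + r == 0:
        return img, mask
    img = np.pad(img, ((t, b), (l, r)), constant_values=color)
    if mask is not None:
        mask = np.pad(mask, ((t, b), (l, r)), constant_values=False)
    return img, mask


def _generate(cfg: SynthConfig, seed: int, kind: str) -> SynthScan:
    geom_rng, anom_rng, speckle_rng, margin_rng = _streams(seed)
    bounds, intens = _geometry(cfg, geom_rng)
    base = _rasterize(bounds, intens, cfg.size)
    mask = None
    if kind != "normal":
        bounds2, mul, add, override = _inject(cfg, kind, bounds, intens, anom_rng)
        base2 = _rasterize(bounds2, intens, cfg.size)
        base2 = np.where(np.isnan(override), base2, override)
        base2 = np.clip(base2 * mul + add, 0.0, 1.0)
        mask = np.abs(base2 - base) > _MASK_TOL
        # snap sub-tolerance residue back to the twin's value so the
        # anomalous scan differs from its twin exactly on the mask
        base = np.where(mask, base2, base)
    speckle = speckle_rng.gamma(cfg.speckle_shape, 1.0 / cfg.speckle_shape,
                                size=(cfg.size, cfg.size))
    img = np.clip(base * speckle, 0.0, 1.0)
    widths, color = _margins(cfg, margin_rng)
    img, mask = _apply_margins(img, mask, widths, color)
    sid = f"synth-{kind}-{seed}"
    return SynthScan(
        image=RawScan(pixels=img, source_id=sid),
        label=kind,
        mask=mask,
        provenance={"seed": int(seed), "config": cfg.digest(),
                    "margins": widths, "margin_color": color},
    )


def generate_normal(cfg: SynthConfig, seed: int) -> SynthScan:
    """A healthy layered B-scan, fully determined by (cfg, seed)."""
    return _generate(cfg, seed, "normal")


def generate_anomalous(cfg: SynthConfig, kind: str, seed: int) -> SynthScan:
    """An anomalous scan sharing geometry and speckle with its normal twin."""
    if kind not in ANOMALY_KINDS:
        raise InputError(f"anomaly kind must be one of {ANOMALY_KINDS}, got {kind!r}")
    return _generate(cfg, seed, kind)


def _scan_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([int(master), int(index)]).generate_state(1)[0] % (2**31))


def generate_dataset(
    cfg: SynthConfig,
    out_dir,
    n_train: int,
    n_test_per_class: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Write train/normal and test/{normal,cnv,dme_fluid,drusen} PNGs + manifest.

    Per-scan seeds derive deterministically from the master seed, so the
    whole dataset is reproducible byte-for-byte.  Returns the manifest
    (also written to ``manifest.csv``): path, label, split, seed, mask
    path, and injected margin widths.
    """
    if n_train < 1 or n_test_per_class < 1:
        raise InputError("counts must be >= 1")
    out = Path(out_dir)
    rows = []
    idx = 0

    def _write(scan: SynthScan, split: str, label: str):
        nonlocal idx
        d = out / split / label
        d.mkdir(parents=True, exist_ok=True)
        p = d / f"{scan.image.source_id}.png"
        Image.fromarray(np.round(scan.image.pixels * 255).astype(np.uint8)).save(p)
        mask_path = ""
        if scan.mask is not None:
            md = out / "test_masks"
            md.mkdir(parents=True, exist_ok=True)
            mp = md / f"{scan.image.source_id}.png"
            Image.fromarray((scan.mask * 255).astype(np.uint8)).save(mp)
            mask_path = str(mp)
        m = scan.provenance["margins"]
        rows.append({
            "path": str(p), "label": label, "split": split,
            "seed": scan.provenance["seed"], "mask_path": mask_path,
            "margin_top": m["top"], "margin_bottom": m["bottom"],
            "margin_left": m["left"], "margin_right": m["right"],
        })
        idx += 1

    for i in range(n_train):
        _write(generate_normal(cfg, _scan_seed(seed, idx)), "train", "normal")
    for kind in ("normal",) + ANOMALY_KINDS:
        for i in range(n_test_per_class):
            s = _scan_seed(seed, idx)
            scan = (generate_normal(cfg, s) if kind == "normal"
                    else generate_anomalous(cfg, kind, s))
            _write(scan, "test", kind)
    manifest = pd.DataFrame(rows)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
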