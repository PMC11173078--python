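"""Scan loading, scanner-margin removal, and backbone input preparation.

OCT exports frequently carry solid white or black margins added by the
scanner software.  Margins are detected by thresholding the image into
white/black masks, labeling connected components, and — only when a
component touches an image corner — stripping contiguous boundary rows
and columns whose white-or-black pixel fraction exceeds ``line_fraction``
(more than a quarter of the line, by default).  Surviving pixels are
never altered: the output is always a contiguous crop of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from octad.errors import DegenerateInputError, InputError

__all__ = [
    "RawScan",
    "MarginConfig",
    "PrepConfig",
    "PreparedScan",
    "load_scan",
    "remove_margins",
    "prepare",
]


@dataclass
class RawScan:
    """A grayscale image with intensities in [0, 1]."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise InputError(
                f"scan {self.source_id!r}: expected a non-empty 2-D grid, "
                f"got shape {self.pixels.shape}"
            )
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise InputError(
                f"scan {self.source_id!r}: intensities outside [0, 1]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class MarginConfig:
    """Thresholds and stopping rules for white/black margin stripping.

    ``line_fraction=0.25`` encodes the "more than a quarter of white or
    black pixels" rule; ``max_passes`` bounds alternation between row and
    column stripping so the procedure always terminates.
    """

    white_threshold: float = 0.96
    black_threshold: float = 0.04
    line_fraction: float = 0.25
    max_passes: int = 4
    min_size: int = 32

    def __post_init__(self) -> None:
        if not (0.0 <= self.black_threshold < self.white_threshold <= 1.0):
            raise ValueError("need 0 <= black_threshold < white_threshold <= 1")
        if not (0.0 < self.line_fraction < 1.0):
            raise ValueError("line_fraction must lie in (0, 1)")
        if self.max_passes < 1 or self.min_size < 1:
            raise ValueError("max_passes and min_size must be positive")


@dataclass(frozen=True)
class PrepConfig:
    """Resize / normalization settings for backbone input tensors."""

    target_size: int = 224
    channel_means: tuple[float, float, float] = (0.485, 0.456, 0.406)
    channel_stds: tuple[float, float, float] = (0.229, 0.224, 0.225)
    replicate_channels: bool = True

    def __post_init__(self) -> None:
        if self.target_size < 1:
            raise ValueError("target_size must be positive")
        if any(s <= 0 for s in self.channel_stds):
            raise ValueError("channel_stds must be strictly positive")


@dataclass
class PreparedScan:
    """Normalized 3-channel tensor ready for the backbone.

    ``crop_box`` is (row0, row1, col0, col1), 0-based half-open, in the
    coordinates of the original (pre-crop) image.
    """

    tensor: np.ndarray  # (3, S, S)
    source_id: str
    crop_box: tuple[int, int, int, int]


def load_scan(path) -> RawScan:
    """Read a PNG/JPEG/TIFF file as a grayscale [0, 1] scan.

    Multi-channel images are converted to grayscale by averaging the
    channels; integer intensities are rescaled by the dtype's full range
    (255 for 8-bit, 65535 for 16-bit).
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # pragma: no cover - message path
        raise InputError(f"cannot read image file {path!s}: {exc}") from exc
    if arr.size == 0:
        raise InputError(f"image file {path!s} is empty")
    dtype = arr.dtype
    if arr.ndim == 3:
        arr = arr.astype(np.float64).mean(axis=2)
    if np.issubdtype(dtype, np.integer):
        arr = arr.astype(np.float64) / float(np.iinfo(dtype).max)
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return RawScan(pixels=arr, source_id=str(path))


_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


def _margin_mask(pixels: np.ndarray, cfg: MarginConfig) -> np.ndarray:
    return (pixels >= cfg.white_threshold) | (pixels <= cfg.black_threshold)


def _corner_component(mask: np.ndarray) -> bool:
    """True if a white/black connected component contains a corner pixel."""
    if not mask.any():
        return False
    labels, _ = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    h, w = mask.shape
    corners = labels[[0, 0, h - 1, h - 1], [0, w - 1, 0, w - 1]]
    return bool((corners > 0).any())


def _strip_run(fractions: np.ndarray, limit: float) -> tuple[int, int]:
    """Lengths of the maximal leading/trailing runs with fraction > limit."""
    over = fractions > limit
    n = len(over)
    lead = 0
    while lead < n and over[lead]:
        lead += 1
    trail = 0
    while trail < n - lead and over[n - 1 - trail]:
        trail += 1
    return lead, trail


def remove_margins(scan: RawScan, cfg: MarginConfig | None = None) -> RawScan:
    """Strip white/black scanner margins from the image borders.

    Each pass re-binarizes the current crop; stripping happens only when
    some white/black component touches a corner of the crop.  Rows are
    stripped before columns within a pass.  Raises
    :class:`DegenerateInputError` if the surviving region would fall
    below ``cfg.min_size`` in either dimension.
    """
    cfg = cfg or MarginConfig()
    px = scan.pixels
    r0, c0 = 0, 0
    r1, c1 = px.shape

    for _ in range(cfg.max_passes):
        crop = px[r0:r1, c0:c1]
        mask = _margin_mask(crop, cfg)
        if not _corner_component(mask):
            break
        top, bottom = _strip_run(mask.mean(axis=1), cfg.line_fraction)
        if top + bottom >= r1 - r0:
            raise DegenerateInputError(
                f"scan {scan.source_id!r}: the whole image is margin"
            )
        r0 += top
        r1 -= bottom
        mask = _margin_mask(px[r0:r1, c0:c1], cfg)
        left, right = _strip_run(mask.mean(axis=0), cfg.line_fraction)
        if left + right >= c1 - c0:
            raise DegenerateInputError(
                f"scan {scan.source_id!r}: the whole image is margin"
            )
        c0 += left
        c1 -= right
        if top == bottom == left == right == 0:
            break

    if r1 - r0 < cfg.min_size or c1 - c0 < cfg.min_size:
        raise DegenerateInputError(
            f"scan {scan.source_id!r}: {r1 - r0}x{c1 - c0} after margin "
            f"removal is below min_size={cfg.min_size}"
        )
    out = RawScan(pixels=px[r0:r1, c0:c1].copy(), source_id=scan.source_id)
    out.crop_box = (r0, r1, c0, c1)
    return out


def prepare(scan: RawScan, cfg: PrepConfig | None = None) -> PreparedScan:
    """Bilinear-resize to ``target_size``, replicate to 3 channels, standardize."""
    cfg = cfg or PrepConfig()
    s = cfg.target_size
    if scan.pixels.shape == (s, s):
        resized = scan.pixels.astype(np.float64)
    else:
        resized = _sk_resize(
            scan.pixels, (s, s), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    if cfg.replicate_channels:
        chans = np.stack([resized] * 3, axis=0)
    else:
        chans = resized[None]
    means = np.asarray(cfg.channel_means)[: chans.shape[0], None, None]
    stds = np.asarray(cfg.channel_stds)[: chans.shape[0], None, None]
    tensor = (chans - means) / stds
    crop_box = getattr(scan, "crop_box", (0, scan.height, 0, scan.width))
    return PreparedScan(tensor=tensor, source_id=scan.source_id, crop_box=crop_box)
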