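"""Wound photograph handling: loading, ROI statistics, quality screening, index maps.

Images are 8-bit RGB photographs taken during surgical debridement; all
computation happens on stored (gamma-encoded) values rescaled to [0, 1].
ROIs select the wound bed (and optionally margins) as boolean pixel masks,
either drawn as polygons or supplied as mask images.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.draw import polygon2mask

__all__ = [
    "RGBImage",
    "ROIMask",
    "ImageRecord",
    "QCThresholds",
    "QCReport",
    "ChannelStats",
    "ImageFormatError",
    "DegenerateROIError",
    "load_image",
    "save_image",
    "load_roi_masks",
    "roi_channel_means",
    "qc_screen",
    "render_index_map",
]

#: intensity (on the [0,1] scale) at or above which a pixel counts as glare
GLARE_LEVEL = 250.0 / 255.0

OUTCOMES = ("healed", "delayed", "dehisced")


class ImageFormatError(ValueError):
    """Raised when a file cannot be decoded as an 8-bit RGB image."""


class DegenerateROIError(ValueError):
    """Raised when a region of interest selects no pixels."""


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB photograph rescaled to float intensities in [0, 1].

    Channel order is always R, G, B along the last axis.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(
                f"expected an HxWx3 RGB array, got shape {px.shape}"
            )
        if px.size and (px.min() < 0.0 or px.max() > 1.0):
            raise ValueError("pixel intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[:, :, "rgb".index(name.lower())]


@dataclass(frozen=True)
class ROIMask:
    """Boolean inclusion mask over an image's pixel grid."""

    mask: np.ndarray
    source: str = "array"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("ROI mask must be a 2-D boolean array")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_polygon(cls, shape: tuple[int, int], polygon, source: str = "polygon") -> "ROIMask":
        """Rasterize an (x, y) vertex list; a pixel is included when its
        center falls inside the polygon (even-odd rule)."""
        poly = np.asarray(polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2:
            raise ValueError("polygon must be a sequence of (x, y) vertices")
        # polygon2mask expects (row, col) = (y, x)
        return cls(polygon2mask(shape, poly[:, ::-1]), source=source)


@dataclass(frozen=True)
class ImageRecord:
    """One debridement observation: image reference plus clinical metadata.

    Each debridement is treated as an independent measurement. ``delayed``
    denotes a wound that healed but whose surgical closure occurred more
    than 21 days post-injury.
    """

    image_id: str
    patient_id: str
    wound_id: str
    debridement_index: int
    hospital: str
    wound_area_cm2: float
    days_post_injury: float
    age: float
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}, got {self.outcome!r}")
        if self.debridement_index < 1:
            raise ValueError("debridement_index is ordinal and starts at 1")


@dataclass(frozen=True)
class QCThresholds:
    """Image-quality gates. Images failing any gate are disregarded.

    blur_min is a lower bound on the variance of a 3x3 Laplacian of the
    luminance over the ROI (in-focus texture raises it); the two fraction
    thresholds are upper bounds.
    """

    glare_max: float = 0.05
    blur_min: float = 1e-4
    blood_channel_margin: float = 0.25
    blood_max: float = 0.50


@dataclass(frozen=True)
class QCReport:
    glare_fraction: float
    blur_score: float
    blood_fraction: float
    reasons: tuple[str, ...] = field(default=())

    @property
    def passed(self) -> bool:
        return not self.reasons


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean and standard error over the union of ROI pixels."""

    mean: np.ndarray  # (3,) R, G, B
    sem: np.ndarray   # (3,)
    n_pixels: int


def load_image(path) -> RGBImage:
    """Load an 8-bit RGB PNG or JPEG, rescaling stored values to [0, 1]."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode in ("L", "I", "I;16", "LA"):
                raise ImageFormatError(
                    f"{path}: expected 3 color channels, got grayscale mode {mode!r}"
                )
            if mode != "RGB":
                raise ImageFormatError(
                    f"{path}: cannot decode as 8-bit RGB (mode {mode!r})"
                )
            arr = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageFormatError(f"{path}: unreadable image file ({exc})") from exc
    return RGBImage(arr.astype(float) / 255.0)


def save_image(image: RGBImage, path) -> None:
    """Write as an 8-bit PNG (values rounded back to 0..255)."""
    arr = np.rint(image.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(Path(path))


def load_roi_masks(path, shape: tuple[int, int]) -> list[ROIMask]:
    """Load ROIs from either a mask PNG (nonzero = included) or a JSON
    polygon file ``{"image_id": ..., "polygons": [[[x, y], ...], ...]}``."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        spec = json.loads(path.read_text())
        polys = spec["polygons"]
        # allow a single flat polygon [[x,y],...] as well
        if polys and isinstance(polys[0][0], (int, float)):
            polys = [polys]
        return [ROIMask.from_polygon(shape, p, source=str(path)) for p in polys]
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    if arr.shape != shape:
        raise ValueError(f"{path}: mask shape {arr.shape} does not match image {shape}")
    return [ROIMask(arr > 0, source=str(path))]


def _union_mask(image: RGBImage, rois) -> np.ndarray:
    if not rois:
        raise DegenerateROIError("at least one ROI is required")
    union = np.zeros((image.height, image.width), dtype=bool)
    for roi in rois:
        if roi.mask.shape != union.shape:
            raise ValueError("ROI mask shape does not match image")
        union |= roi.mask
    if not union.any():
        raise DegenerateROIError("union of ROIs selects no pixels")
    return union


def roi_channel_means(image: RGBImage, rois) -> ChannelStats:
    """Mean and SEM of each channel over the union of the ROIs.

    Overlapping ROIs count each pixel once, so multiple ROIs combine
    area-weighted into a single per-image statistic.
    """
    union = _union_mask(image, rois)
    vals = image.pixels[union]  # (n, 3)
    n = vals.shape[0]
    mean = vals.mean(axis=0)
    if n > 1:
        sem = vals.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.full(3, np.nan)
    return ChannelStats(mean=mean, sem=sem, n_pixels=n)


def qc_screen(image: RGBImage, roi: ROIMask, thresholds: QCThresholds | None = None) -> QCReport:
    """Screen one image+ROI for glare, blur, and blood in the field of view.

    glare_fraction: ROI pixels with any channel at or above 250/255.
    blur_score: variance of a 3x3 Laplacian of the mean-channel luminance
    over the ROI (flat or defocused fields score near zero).
    blood_fraction: ROI pixels whose red exceeds max(G, B) by more than the
    configured margin.
    """
    thr = thresholds or QCThresholds()
    union = _union_mask(image, [roi])
    px = image.pixels

    glare = float((px[union] >= GLARE_LEVEL).any(axis=1).mean())

    luminance = px.mean(axis=2)
    lap = ndimage.laplace(luminance)  # 3x3 kernel [[0,1,0],[1,-4,1],[0,1,0]]
    blur = float(lap[union].var())

    red_excess = px[:, :, 0] - np.maximum(px[:, :, 1], px[:, :, 2])
    blood = float((red_excess[union] > thr.blood_channel_margin).mean())

    reasons = []
    if glare > thr.glare_max:
        reasons.append("glare")
    if blur < thr.blur_min:
        reasons.append("blur")
    if blood > thr.blood_max:
        reasons.append("blood")
    return QCReport(glare_fraction=glare, blur_score=blur,
                    blood_fraction=blood, reasons=tuple(reasons))


def render_index_map(image: RGBImage, index: str) -> np.ndarray:
    """Contrast-enhanced grayscale map of one raw spectral index.

    The per-pixel index is linearly rescaled so its 1st/99th percentiles map
    to 0/1 (then clipped); brighter pixels carry a higher index value.
    Pixels where the index's denominator is zero render as 0.
    """
    from .features import RAW_INDEX_NAMES  # local import avoids a cycle

    if index not in RAW_INDEX_NAMES:
        raise ValueError(f"unknown index {index!r}; expected one of {RAW_INDEX_NAMES}")
    r = image.pixels[:, :, 0]
    g = image.pixels[:, :, 1]
    b = image.pixels[:, :, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = {
            "r": r,
            "g": g,
            "b": b,
            "r_minus_b": r - b,
            "r_minus_g": r - g,
            "rb_over_g": np.where(g > 0, (r - b) / np.where(g > 0, g, 1.0), np.nan),
            "rb_over_r2b2": np.where(
                r**2 + b**2 > 0, (r - b) / np.where(r**2 + b**2 > 0, r**2 + b**2, 1.0), np.nan
            ),
        }[index]
    valid = np.isfinite(values)
    out = np.zeros_like(r)
    if not valid.any():
        return out
    lo, hi = np.percentile(values[valid], [1.0, 99.0])
    if hi > lo:
        out[valid] = np.clip((values[valid] - lo) / (hi - lo), 0.0, 1.0)
    else:
        out[valid] = 0.5  # constant field renders mid-gray
    return out
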