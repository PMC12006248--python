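"""Chromogenic IHC and picrosirius-red quantification.

Brightfield H-DAB images are unmixed by optical-density color deconvolution
(Beer-Lambert model with the standard published hematoxylin/DAB stain
vectors), binarized with Kapur's maximum-entropy histogram threshold, and
summarized per region of interest as positive-area percent and vessel
density (cross-sectional vessels per mm^2).  Polarized picrosirius-red
images are split by hue into red-yellow (thick) versus green (thin) collagen
fibers.  Live/dead stained constructs yield the electroporation lesion area
used to invert the lethal field threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage.draw import polygon2mask

from .errors import (DegenerateHistogramError, DegenerateStainsError,
                     InvalidROIError)

__all__ = [
    "CalibratedImage",
    "StainVectors",
    "RegionOfInterest",
    "RegionMetrics",
    "AblationArea",
    "load_rois",
    "save_rois",
    "od_transform",
    "color_deconvolve",
    "max_entropy_threshold",
    "region_area_percent",
    "count_vessels",
    "psr_fiber_ratio",
    "ablation_area",
    "HDAB_VECTORS",
]

MAX_OD = 3.0  # cap for fully absorbing pixels (I/I0 = 1e-3)


@dataclass(frozen=True)
class CalibratedImage:
    """Pixel data plus physical calibration.

    ``pixels`` is (H, W, 3) for RGB brightfield or (H, W) per fluorescence
    channel; ``pixel_size_um`` is the side of one pixel in micrometres.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_semantics: str = "rgb"

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2


@dataclass(frozen=True)
class StainVectors:
    """Unit optical-density directions for (hematoxylin, DAB, residual)."""

    matrix: np.ndarray  # rows = stains, columns = RGB OD components

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise DegenerateStainsError("stain matrix must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise DegenerateStainsError("stain vectors must be unit norm")
        if np.linalg.cond(m) > 1e6:
            raise DegenerateStainsError("stain matrix is near-singular")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(np.asarray(self.matrix, dtype=float))


def _hdab_default() -> StainVectors:
    # standard published H-DAB optical-density vectors (rows: H, DAB,
    # residual), as shipped with scikit-image's stain-separation matrices
    m = skcolor.rgb_from_hdx
    m = m / np.linalg.norm(m, axis=1, keepdims=True)
    return StainVectors(m)


HDAB_VECTORS = _hdab_default()


@dataclass(frozen=True)
class RegionOfInterest:
    """Polygonal ROI in pixel coordinates (x right, y down, 0-based)."""

    polygon_xy: tuple[tuple[float, float], ...]
    label: str = "custom"

    def __post_init__(self):
        from shapely.geometry import Polygon
        if len(self.polygon_xy) < 3:
            raise InvalidROIError("polygon needs at least 3 vertices")
        p = Polygon(self.polygon_xy)
        if not p.is_valid:
            raise InvalidROIError("polygon is self-intersecting or degenerate")
        if p.area <= 0:
            raise InvalidROIError("polygon has zero area")

    def shapely(self):
        from shapely.geometry import Polygon
        return Polygon(self.polygon_xy)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize to a boolean pixel mask (pixel-center membership)."""
        # polygon2mask expects (row, col) = (y, x) vertex order
        verts = np.array([(y, x) for x, y in self.polygon_xy])
        m = polygon2mask(shape, verts)
        if not m.any():
            raise InvalidROIError("ROI does not overlap the image")
        return m


@dataclass(frozen=True)
class RegionMetrics:
    area_percent: float
    vessel_count: int
    roi_area_mm2: float
    vessel_density_per_mm2: float


@dataclass(frozen=True)
class AblationArea:
    area_mm2: float
    lesion_found: bool
    mask: np.ndarray = dc_field(repr=False, default=None)


def load_rois(path) -> list[RegionOfInterest]:
    """Read ROIs from a JSON file: a list of {"label", "polygon_xy"}."""
    import json

    with open(path) as fh:
        data = json.load(fh)
    return [RegionOfInterest(tuple(tuple(p) for p in r["polygon_xy"]),
                             r.get("label", "custom")) for r in data]


def save_rois(rois, path) -> None:
    import json

    data = [{"label": r.label, "polygon_xy": [list(p) for p in r.polygon_xy]}
            for r in rois]
    with open(path, "w") as fh:
        json.dump(data, fh)


# --------------------------------------------------------------------------
# optical density and stain separation
# --------------------------------------------------------------------------

def od_transform(image: np.ndarray, white_level: float | None = None,
                 max_od: float = MAX_OD) -> np.ndarray:
    """Per-channel optical density ``-log10((I + eps) / I0)``.

    ``white_level`` defaults to the dtype white point (255 / 65535) for
    integer images and to the per-channel maximum for float input.  Zeros
    are guarded so an all-black image saturates at ``max_od`` (with a
    warning) instead of diverging.
    """
    img = np.asarray(image, dtype=float)
    if white_level is None:
        if np.issubdtype(np.asarray(image).dtype, np.integer):
            white_level = float(np.iinfo(np.asarray(image).dtype).max)
        else:
            white_level = float(img.max()) if img.max() > 0 else 1.0
    floor = white_level * 10.0 ** (-max_od)
    if np.any(img < floor):
        warnings.warn("saturated (near-black) pixels capped at max OD",
                      stacklevel=2)
    od = -np.log10(np.maximum(img, floor) / white_level)
    return np.clip(od, 0.0, max_od)


def color_deconvolve(od_image: np.ndarray,
                     vectors: StainVectors = HDAB_VECTORS,
                     clip_negative: bool = True):
    """Unmix an OD image into per-stain concentration channels.

    Returns ``(concentrations, clamp_fraction)`` where concentrations has
    one channel per stain (H, DAB, residual) and ``clamp_fraction`` is the
    fraction of pixels with any negative component before clamping.
    """
    od = np.asarray(od_image, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise DegenerateStainsError("OD image must be (H, W, 3)")
    conc = od @ vectors.inverse
    neg = float(np.mean(np.any(conc < -1e-12, axis=-1)))
    if clip_negative:
        conc = np.clip(conc, 0.0, None)
    return conc, neg


# --------------------------------------------------------------------------
# maximum-entropy (Kapur) threshold
# --------------------------------------------------------------------------

def max_entropy_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Kapur's maximum-entropy threshold over the observed intensity range.

    The histogram is split at every candidate bin boundary; the boundary
    maximizing the sum of background and foreground Shannon entropies is
    returned as an intensity value (the upper edge of the background side).
    Deterministic for a fixed binning; depends on the image only through
    its histogram.
    """
    data = np.asarray(image, dtype=float).ravel()
    lo, hi = float(data.min()), float(data.max())
    if not hi > lo:
        raise DegenerateHistogramError("constant image has no threshold")
    hist, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    p = hist.astype(float) / hist.sum()
    c = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_plogp = np.cumsum(plogp)
    total_plogp = cum_plogp[-1]
    # candidate split after bin t: background = bins [0..t], fg = (t..end]
    w0 = c[:-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(w0) - cum_plogp[:-1] / w0
        h1 = np.log(w1) - (total_plogp - cum_plogp[:-1]) / w1
    crit = np.where(valid, h0 + h1, -np.inf)
    t = int(np.argmax(crit))
    return float(edges[t + 1])


# --------------------------------------------------------------------------
# region metrics
# --------------------------------------------------------------------------

def region_area_percent(mask: np.ndarray, roi: RegionOfInterest) -> float:
    """Percent of ROI pixels that are positive in ``mask``."""
    roi_mask = roi.mask(mask.shape)
    total = int(roi_mask.sum())
    return 100.0 * float(np.count_nonzero(mask & roi_mask)) / total


_STRUCT8 = np.ones((3, 3), dtype=bool)


def count_vessels(mask: np.ndarray, roi: RegionOfInterest,
                  pixel_size_um: float, min_area_um2: float = 15.0,
                  connectivity: int = 8) -> RegionMetrics:
    """Count cross-sectional vessels inside an ROI and derive density.

    Connected components (8-connectivity by default) with area at or above
    ``min_area_um2`` count as vessels; a component is attributed to the ROI
    if its centroid falls inside the polygon (boundary included).  Density
    is vessels per mm^2 of ROI; area percent is measured over ROI pixels.
    """
    if pixel_size_um <= 0:
        raise InvalidROIError("pixel size must be positive")
    struct = _STRUCT8 if connectivity == 8 else None
    labels, n = ndimage.label(mask, structure=struct)
    px_area = pixel_size_um ** 2
    roi_poly = roi.shapely()
    roi_mask = roi.mask(mask.shape)
    roi_area_mm2 = roi_poly.area * px_area / 1e6
    if roi_area_mm2 <= 0:
        raise InvalidROIError("ROI has zero area")
    count = 0
    if n:
        from shapely.geometry import Point
        areas = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        centroids = ndimage.center_of_mass(mask, labels, np.arange(1, n + 1))
        for area_px, (cy, cx) in zip(areas, centroids):
            if area_px * px_area < min_area_um2:
                continue
            pt = Point(cx, cy)
            if roi_poly.covers(pt):
                count += 1
    area_pct = 100.0 * float(np.count_nonzero(mask & roi_mask)) / int(roi_mask.sum())
    return RegionMetrics(area_pct, count, roi_area_mm2, count / roi_area_mm2)


# --------------------------------------------------------------------------
# picrosirius red
# --------------------------------------------------------------------------

def psr_fiber_ratio(rgb: np.ndarray,
                    red_yellow_deg: tuple = ((0.0, 70.0), (330.0, 360.0)),
                    green_deg: tuple = ((70.0, 170.0),),
                    saturation_floor: float = 0.2,
                    value_floor: float = 0.1):
    """Red-yellow to green birefringent fiber area ratio under polarized light.

    Pixels above the saturation/value floors are classified by hue; returns
    ``(ratio, red_yellow_px, green_px)``.  With no green fibers the ratio is
    the infinite sentinel (with a warning).
    """
    img = np.asarray(rgb, dtype=float)
    if np.issubdtype(np.asarray(rgb).dtype, np.integer):
        img = img / np.iinfo(np.asarray(rgb).dtype).max
    hsv = skcolor.rgb2hsv(img)
    hue = hsv[..., 0] * 360.0
    lit = (hsv[..., 1] >= saturation_floor) & (hsv[..., 2] >= value_floor)

    def in_bands(bands):
        m = np.zeros(hue.shape, dtype=bool)
        for lo, hi in bands:
            m |= (hue >= lo) & (hue < hi)
        return m

    ry = int(np.count_nonzero(in_bands(red_yellow_deg) & lit))
    gr = int(np.count_nonzero(in_bands(green_deg) & lit))
    if gr == 0:
        if ry > 0:
            warnings.warn("no green fibers detected; ratio is infinite",
                          stacklevel=2)
            return float("inf"), ry, gr
        return 0.0, ry, gr
    return ry / gr, ry, gr


# --------------------------------------------------------------------------
# live/dead lesion area
# --------------------------------------------------------------------------

def ablation_area(live: np.ndarray, dead: np.ndarray,
                  pixel_size_um: float,
                  dead_threshold: float | None = None,
                  live_threshold: float | None = None) -> AblationArea:
    """Electroporation lesion area from registered live/dead channels.

    Each channel is binarized (maximum-entropy threshold unless given);
    the lesion is the largest connected component of dead-positive AND
    live-negative pixels, returned in mm^2.  If no dead-positive pixels
    exist the result is zero with ``lesion_found=False``.
    """
    live = np.asarray(live, dtype=float)
    dead = np.asarray(dead, dtype=float)
    if live.shape != dead.shape:
        raise InvalidROIError("live and dead channels must be registered")

    def binarize(ch, thr):
        if thr is None:
            try:
                thr = max_entropy_threshold(ch)
            except DegenerateHistogramError:
                return np.zeros(ch.shape, dtype=bool)
        return ch > thr

    dead_pos = binarize(dead, dead_threshold)
    live_pos = binarize(live, live_threshold)
    lesion = dead_pos & ~live_pos
    if not lesion.any():
        return AblationArea(0.0, False, np.zeros_like(lesion))
    labels, n = ndimage.label(lesion, structure=_STRUCT8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    mask = labels == biggest
    area_mm2 = float(mask.sum()) * pixel_size_um ** 2 / 1e6
    return AblationArea(area_mm2, True, mask)
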