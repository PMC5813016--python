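"""TIRF membrane-puncta quantification chain.

The chain reproduces a grayscale-morphology spot-detection recipe for
beta-arrestin-GFP membrane recruitment imaged by TIRF microscopy:

1. 16-bit field -> 8-bit working range by square-root transform
   (variance-stabilizing; makes dim and bright puncta comparable).
2. Small Gaussian smoothing (half-width 2 px, sigma 1) to suppress noise.
3. White top-hat with a large disk (radius 30 px) to flatten the
   low-frequency background, then a second top-hat with a small disk
   (radius 5 px) to enhance puncta against local intensity variation.
4. Peak finding by non-maximal suppression (radius 3 px, threshold 20).
5. Marker-controlled watershed with the peaks as foreground markers to
   delineate per-punctum regions.
6. Per-region area / mean / integrated intensity measured on the
   *unprocessed* sqrt-transformed image.
7. Cell foreground by Otsu threshold + hole filling + largest connected
   component; per-field endpoints (puncta count, integrated intensity)
   normalized by foreground area relative to the experiment-wide median.

All coordinates are 0-based (row, col); connectivity is 8-connected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops
from skimage.morphology import disk, opening
from skimage.segmentation import watershed

from .synthetic import RawField, U16_MAX

__all__ = [
    "PipelineConfig",
    "PunctaRecord",
    "CellMask",
    "FieldResult",
    "NoForegroundError",
    "sqrt_to_8bit",
    "smooth",
    "tophat",
    "find_peaks_nms",
    "segment_puncta_watershed",
    "measure_puncta",
    "otsu_threshold",
    "segment_cells",
    "normalization_factors",
    "field_endpoints",
    "enhance",
    "process_field",
    "run_field_analysis",
]


class NoForegroundError(ValueError):
    """Otsu segmentation is undefined on a single-valued image."""


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the detection chain (defaults as published)."""

    gaussian_halfwidth_px: int = 2
    gaussian_sigma_px: float = 1.0
    tophat_large_radius_px: int = 30
    tophat_small_radius_px: int = 5
    nms_radius_px: int = 3
    nms_threshold: float = 20.0
    gate_min_area_px: int | None = None
    gate_min_mean_intensity: float | None = None

    def __post_init__(self) -> None:
        for r in (self.gaussian_halfwidth_px, self.tophat_large_radius_px,
                  self.tophat_small_radius_px, self.nms_radius_px):
            if r < 1:
                raise ValueError("all radii must be >= 1")
        if not (0 <= self.nms_threshold <= 255):
            raise ValueError("nms_threshold must lie in [0, 255]")
        if self.tophat_small_radius_px >= self.tophat_large_radius_px:
            raise ValueError("small top-hat radius must be < large radius")
        if self.gaussian_sigma_px <= 0:
            raise ValueError("gaussian_sigma_px must be positive")


@dataclass
class PunctaRecord:
    label: int
    centroid: tuple[float, float]
    area_px: int
    mean_intensity: float

    @property
    def integrated_intensity(self) -> float:
        return self.mean_intensity * self.area_px


@dataclass
class CellMask:
    foreground: np.ndarray

    @property
    def foreground_area_px(self) -> int:
        return int(np.count_nonzero(self.foreground))


@dataclass
class FieldResult:
    field_id: str
    n_puncta_raw: int
    puncta_count_norm: float
    integrated_intensity_norm: float
    normalization_factor: float


# ---------------------------------------------------------------------------
# elementary operators
# ---------------------------------------------------------------------------

def sqrt_to_8bit(field: RawField | np.ndarray) -> np.ndarray:
    """Map 16-bit counts onto [0, 255]: v8 = min(255, floor(sqrt(v16)))."""
    px = field.pixels if isinstance(field, RawField) else np.asarray(field)
    if px.ndim != 2 or px.size == 0:
        raise ValueError("expected a nonempty 2-D image")
    if px.min() < 0 or px.max() > U16_MAX:
        raise ValueError("pixel values must lie in [0, 65535]")
    return np.minimum(255, np.floor(np.sqrt(px.astype(np.float64)))).astype(np.uint8)


def _gaussian_kernel(halfwidth: int, sigma: float) -> np.ndarray:
    ax = np.arange(-halfwidth, halfwidth + 1, dtype=float)
    g1 = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g1, g1)
    return k / k.sum()


def smooth(img: np.ndarray, cfg: PipelineConfig = PipelineConfig()) -> np.ndarray:
    """Convolve with a normalized truncated Gaussian (reflect boundary)."""
    k = _gaussian_kernel(cfg.gaussian_halfwidth_px, cfg.gaussian_sigma_px)
    return ndimage.convolve(np.asarray(img, dtype=float), k, mode="reflect")


def tophat(img: np.ndarray, radius_px: int) -> np.ndarray:
    """White top-hat: img minus its grayscale opening with a disk.

    Removes (flat) features wider than the disk; exactly zero on constant
    images and invariant to additive offsets.
    """
    img = np.asarray(img, dtype=float)
    if radius_px < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius_px + 1 > min(img.shape):
        raise ValueError("structuring element larger than image")
    return img - opening(img, disk(radius_px))


def find_peaks_nms(enhanced: np.ndarray, cfg: PipelineConfig = PipelineConfig()
                   ) -> np.ndarray:
    """Non-maximal-suppression peak list, shape (n, 2), sorted by (row, col).

    A pixel is a peak iff its value is >= ``nms_threshold`` and >= every
    pixel within Chebyshev distance ``nms_radius_px``.  Equal-valued
    plateau candidates that touch (8-connectivity) are collapsed to the
    lexicographically smallest (row, col).
    """
    img = np.asarray(enhanced, dtype=float)
    size = 2 * cfg.nms_radius_px + 1
    local_max = ndimage.maximum_filter(img, size=size, mode="reflect")
    cand = (img >= cfg.nms_threshold) & (img >= local_max)
    if not cand.any():
        return np.empty((0, 2), dtype=int)
    # candidates adjacent within the NMS window are equal-valued, so each
    # 8-connected candidate component is one plateau
    labels, n = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    peaks = []
    rows, cols = np.nonzero(cand)
    order = np.lexsort((cols, rows))
    seen: set[int] = set()
    for i in order:
        lab = labels[rows[i], cols[i]]
        if lab not in seen:
            seen.add(lab)
            peaks.append((int(rows[i]), int(cols[i])))
    return np.array(sorted(peaks), dtype=int).reshape(-1, 2)


def segment_puncta_watershed(enhanced: np.ndarray, peaks: np.ndarray,
                             cfg: PipelineConfig = PipelineConfig()) -> np.ndarray:
    """Marker-controlled watershed on the negated enhanced image.

    Peaks are foreground markers 1..n; pixels below ``nms_threshold``
    form the background marker.  Returns an int label grid where 0 is
    background and label i is the region grown from peak i (1-based,
    peaks in their sorted order).
    """
    img = np.asarray(enhanced, dtype=float)
    peaks = np.asarray(peaks, dtype=int).reshape(-1, 2)
    if peaks.shape[0] == 0:
        return np.zeros(img.shape, dtype=np.int32)
    if (peaks[:, 0].min() < 0 or peaks[:, 1].min() < 0
            or peaks[:, 0].max() >= img.shape[0]
            or peaks[:, 1].max() >= img.shape[1]):
        raise ValueError("peaks must lie inside the image")
    n = peaks.shape[0]
    markers = np.zeros(img.shape, dtype=np.int32)
    bg_label = n + 1
    markers[img < cfg.nms_threshold] = bg_label
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-img, markers=markers, connectivity=2)
    labels[labels == bg_label] = 0
    return labels.astype(np.int32)


def measure_puncta(labels: np.ndarray, sqrt_image: np.ndarray
                   ) -> list[PunctaRecord]:
    """Area / mean / integrated intensity per region, on the sqrt image.

    ``sqrt_image`` must be the 8-bit transformed but otherwise
    unprocessed field (no smoothing or top-hat).
    """
    labels = np.asarray(labels)
    sqrt_image = np.asarray(sqrt_image, dtype=float)
    if labels.shape != sqrt_image.shape:
        raise ValueError("labels and sqrt_image must have the same shape")
    out: list[PunctaRecord] = []
    for rp in regionprops(labels.astype(np.int32), intensity_image=sqrt_image):
        out.append(PunctaRecord(
            label=int(rp.label),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            area_px=int(rp.area),
            mean_intensity=float(rp.intensity_mean),
        ))
    return out


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's threshold over the 256 candidate levels of an 8-bit image.

    Maximizes the between-class variance of the split (<= t) vs (> t);
    ties keep the lowest maximizing level.
    """
    img = np.asarray(img)
    hist = np.bincount(np.clip(np.rint(img).astype(int), 0, 255).ravel(),
                       minlength=256).astype(float)
    levels = np.arange(256, dtype=float)
    total = hist.sum()
    w0 = np.cumsum(hist)
    sum0 = np.cumsum(hist * levels)
    mu_total = sum0[-1] / total
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise NoForegroundError("single-valued image has no Otsu threshold")
    mu0 = np.where(w0 > 0, sum0 / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (sum0[-1] - sum0) / np.where(w1 > 0, w1, 1), 0.0)
    bcv = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    del mu_total
    return int(np.argmax(bcv))


def segment_cells(img: np.ndarray) -> CellMask:
    """Cell foreground: Otsu threshold, hole filling, largest component."""
    img = np.asarray(img)
    t = otsu_threshold(img)
    mask = img > t
    if not mask.any():
        raise NoForegroundError("no pixels above Otsu threshold")
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise NoForegroundError("no foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return CellMask(foreground=labels == keep)


def normalization_factors(areas: Sequence[float]) -> np.ndarray:
    """Per-field factor = area / median(pooled areas across the experiment)."""
    a = np.asarray(areas, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one area")
    if (a <= 0).any():
        raise ValueError("areas must be positive")
    return a / np.median(a)


def field_endpoints(records: Sequence[PunctaRecord], mask: CellMask,
                    factor: float, cfg: PipelineConfig = PipelineConfig(),
                    field_id: str = "") -> FieldResult:
    """Area-normalized per-field endpoints.

    Puncta whose centroid pixel falls outside the cell mask are dropped;
    optional area / mean-intensity gates are then applied.
    """
    if factor <= 0:
        raise ValueError("normalization factor must be positive")
    fg = mask.foreground
    kept: list[PunctaRecord] = []
    for rec in records:
        r = int(np.clip(round(rec.centroid[0]), 0, fg.shape[0] - 1))
        c = int(np.clip(round(rec.centroid[1]), 0, fg.shape[1] - 1))
        if not fg[r, c]:
            continue
        if cfg.gate_min_area_px is not None and rec.area_px < cfg.gate_min_area_px:
            continue
        if (cfg.gate_min_mean_intensity is not None
                and rec.mean_intensity < cfg.gate_min_mean_intensity):
            continue
        kept.append(rec)
    n = len(kept)
    integrated = float(sum(r.integrated_intensity for r in kept))
    return FieldResult(
        field_id=field_id,
        n_puncta_raw=n,
        puncta_count_norm=n / factor,
        integrated_intensity_norm=integrated / factor,
        normalization_factor=factor,
    )


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------

def enhance(field: RawField | np.ndarray,
            cfg: PipelineConfig = PipelineConfig()) -> dict[str, np.ndarray]:
    """Run the image-transform chain; returns all intermediate images."""
    sqrt8 = sqrt_to_8bit(field)
    smoothed = smooth(sqrt8, cfg)
    flat = tophat(smoothed, cfg.tophat_large_radius_px)
    enhanced = tophat(flat, cfg.tophat_small_radius_px)
    return {"sqrt8": sqrt8, "smoothed": smoothed, "flattened": flat,
            "enhanced": enhanced}


def process_field(field: RawField, cfg: PipelineConfig = PipelineConfig()
                  ) -> dict:
    """Detect, segment and measure one field (everything but normalization).

    Cell segmentation runs on the smoothed 8-bit image (configurable
    choice; the published chain does not state which image feeds Otsu).
    """
    imgs = enhance(field, cfg)
    peaks = find_peaks_nms(imgs["enhanced"], cfg)
    labels = segment_puncta_watershed(imgs["enhanced"], peaks, cfg)
    records = measure_puncta(labels, imgs["sqrt8"])
    mask = segment_cells(imgs["smoothed"])
    return {"images": imgs, "peaks": peaks, "labels": labels,
            "records": records, "cell_mask": mask}


def run_field_analysis(fields: Sequence[RawField],
                       cfg: PipelineConfig = PipelineConfig()
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process many fields with experiment-pooled area normalization.

    Returns (puncta_table, endpoint_table) as tidy DataFrames.
    """
    per_field = [process_field(f, cfg) for f in fields]
    areas = [res["cell_mask"].foreground_area_px for res in per_field]
    factors = normalization_factors(areas)

    puncta_rows = []
    endpoint_rows = []
    for f, res, factor in zip(fields, per_field, factors):
        fg = res["cell_mask"].foreground
        for rec in res["records"]:
            r = int(np.clip(round(rec.centroid[0]), 0, fg.shape[0] - 1))
            c = int(np.clip(round(rec.centroid[1]), 0, fg.shape[1] - 1))
            puncta_rows.append((f.field_id, f.treatment_label, f.batch_id,
                                rec.label, rec.centroid[0], rec.centroid[1],
                                rec.area_px, rec.mean_intensity,
                                rec.integrated_intensity, bool(fg[r, c])))
        ep = field_endpoints(res["records"], res["cell_mask"], float(factor),
                             cfg, field_id=f.field_id)
        endpoint_rows.append((f.field_id, f.treatment_label, f.batch_id,
                              ep.n_puncta_raw, ep.puncta_count_norm,
                              ep.integrated_intensity_norm,
                              ep.normalization_factor))
    puncta_table = pd.DataFrame(puncta_rows, columns=[
        "field_id", "treatment", "batch", "label", "row", "col", "area_px",
        "mean_intensity", "integrated_intensity", "inside_cell"])
    endpoint_table = pd.DataFrame(endpoint_rows, columns=[
        "field_id", "treatment", "batch", "n_puncta_raw", "puncta_count_norm",
        "integrated_intensity_norm", "normalization_factor"])
    return puncta_table, endpoint_table
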