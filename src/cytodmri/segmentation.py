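"""Nissl cell-body segmentation and its quality-control measures.

Pipeline, in order: morphological top-hat/bottom-hat contrast enhancement
(I + TH - BH), percentile contrast stretch, histogram-based global threshold
(Otsu by default) with dark-object polarity, hole filling, small-object
removal, connected-component labeling.  A Laplacian-of-Gaussian edge map is
available for QC overlays only — it never alters the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from cytodmri.errors import SchemaError


@dataclass
class SegmentationConfig:
    cell_radius_px: float = 3.0      # expected cell radius -> structuring element
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    threshold: str = "otsu"          # 'otsu' or 'quantile'
    threshold_quantile: float = 0.15  # used when threshold == 'quantile'
    dark_cells: bool = True          # cells below threshold
    min_area_px: float | None = None  # default pi*(radius/4)^2
    connectivity: int = 2            # 8-connectivity
    #: reject the thresholding when the two intensity classes are separated
    #: by less than this many pooled within-class standard deviations
    #: (a pure-noise image otherwise segments into spurious blobs)
    min_separation: float = 3.0

    @property
    def min_area(self) -> float:
        if self.min_area_px is not None:
            return self.min_area_px
        return np.pi * (0.25 * self.cell_radius_px) ** 2


@dataclass
class CellMask:
    binary: np.ndarray   # bool, True = cell body
    labels: np.ndarray   # int components, nonzero exactly where binary
    n_cells: int


def segment_cells(image: np.ndarray, config: SegmentationConfig | None = None) -> CellMask:
    cfg = config or SegmentationConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if img.max() == img.min():
        warnings.warn("constant image: returning empty segmentation")
        empty = np.zeros(img.shape, bool)
        return CellMask(empty, np.zeros(img.shape, np.int32), 0)

    se = morphology.disk(max(1, int(round(cfg.cell_radius_px))))
    enhanced = img + morphology.white_tophat(img, se) - morphology.black_tophat(img, se)

    p_lo, p_hi = np.percentile(enhanced, cfg.stretch_percentiles)
    if p_hi > p_lo:
        enhanced = np.clip((enhanced - p_lo) / (p_hi - p_lo), 0.0, 1.0)

    if cfg.threshold == "otsu":
        thr = filters.threshold_otsu(enhanced)
    elif cfg.threshold == "quantile":
        thr = np.quantile(enhanced, cfg.threshold_quantile)
    else:
        raise ValueError(f"unknown threshold rule {cfg.threshold!r}")

    binary = enhanced < thr if cfg.dark_cells else enhanced > thr
    if binary.any() and not binary.all():
        fg, bg = enhanced[binary], enhanced[~binary]
        pooled = np.sqrt((fg.var() * fg.size + bg.var() * bg.size) / enhanced.size)
        if abs(bg.mean() - fg.mean()) < cfg.min_separation * max(pooled, 1e-12):
            warnings.warn("no bimodal intensity separation: returning empty segmentation")
            empty = np.zeros(img.shape, bool)
            return CellMask(empty, np.zeros(img.shape, np.int32), 0)
    binary = ndimage.binary_fill_holes(binary)

    structure = ndimage.generate_binary_structure(2, cfg.connectivity)
    labels, n = ndimage.label(binary, structure=structure)
    if n and cfg.min_area > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < cfg.min_area)
        if small.size:
            binary &= ~np.isin(labels, small[small > 0])
            labels, n = ndimage.label(binary, structure=structure)
    return CellMask(binary, labels.astype(np.int32), int(n))


def log_edges(image: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Laplacian-of-Gaussian zero-crossing edge map for QC overlays."""
    log = ndimage.gaussian_laplace(np.asarray(image, dtype=float), sigma=sigma)
    signs = np.sign(log)
    edges = np.zeros(image.shape, bool)
    edges[:-1, :] |= signs[:-1, :] != signs[1:, :]
    edges[:, :-1] |= signs[:, :-1] != signs[:, 1:]
    return edges


def cell_area_density(mask: np.ndarray, roi: np.ndarray) -> float:
    """Fraction of ROI area covered by cell bodies."""
    mask = np.asarray(mask, bool)
    roi = np.asarray(roi, bool)
    if mask.shape != roi.shape:
        raise ValueError("mask/roi shape mismatch")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI: density undefined")
    return float((mask & roi).sum()) / n_roi


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b| / (|a|+|b|); two empty masks count as identical."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def density_error(auto_density: float, manual_density: float) -> float:
    """Absolute error between automated and reference cell area density."""
    for d in (auto_density, manual_density):
        if not 0.0 <= d <= 1.0:
            raise SchemaError(f"density {d} outside [0, 1]")
    return abs(auto_density - manual_density)
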