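"""Regional average and heterogeneity statistics.

Two distinct heterogeneity statistics are used deliberately:

* for diffusion maps, the inter-voxel statistic is the mean absolute
  pairwise difference (1/N^2) sum_i sum_j |x_i - x_j| — a Gini-type mean
  difference, including the zero i=j terms in the N^2 denominator;
* for histology, heterogeneity is the population variance of cell area
  density across diffusion-voxel-sized grid squares tiling the ROI.

The fast path for the pairwise statistic uses the sorted-order identity
h = (2/N^2) sum_i (2i - N - 1) x_(i) (1-based ranks), which is algebraically
equal to the double sum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cytodmri.io import SUMMARY_COLUMNS
from cytodmri.segmentation import cell_area_density


def regional_average(values: np.ndarray) -> float:
    """Mean over a region's valid (finite) voxel values; NaN if none."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    return float(v.mean())


def regional_heterogeneity(values: np.ndarray) -> float:
    """Mean absolute pairwise difference, (1/N^2) sum_ij |x_i - x_j|.

    Requires at least two finite values; returns NaN otherwise.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        return float("nan")
    x = np.sort(v)
    i = np.arange(1, n + 1)
    return float((2.0 / n**2) * np.sum((2 * i - n - 1) * x))


def grid_cell_area_density(
    cell_mask: np.ndarray,
    roi_mask: np.ndarray,
    pixel_size_um: float,
    grid_size_mm: float = 0.8,
    min_coverage: float = 0.5,
) -> tuple[float, float, np.ndarray]:
    """Average and heterogeneity of cell area density on a voxel-sized grid.

    The section is tiled with axis-aligned squares of side ``grid_size_mm``
    anchored at the ROI bounding-box origin.  A square qualifies when at
    least ``min_coverage`` of its pixels lie inside the ROI; its density is
    cell pixels / in-ROI pixels of the square.  The regional average is the
    whole-ROI area fraction (not the mean of square densities);
    heterogeneity is the population variance over qualifying squares.

    Returns (average, heterogeneity, per-square densities); heterogeneity is
    NaN with fewer than two qualifying squares.
    """
    cell = np.asarray(cell_mask, bool)
    roi = np.asarray(roi_mask, bool)
    if cell.shape != roi.shape:
        raise ValueError("cell/roi mask shape mismatch")
    side = int(round(grid_size_mm * 1000.0 / pixel_size_um))
    if side < 2:
        raise ValueError("grid square smaller than 2 pixels; use finer pixels")
    rows, cols = np.nonzero(roi)
    if rows.size == 0:
        raise ValueError("empty ROI")
    r0, c0 = rows.min(), cols.min()
    r1, c1 = rows.max() + 1, cols.max() + 1

    densities = []
    for ri in range(r0, r1, side):
        for ci in range(c0, c1, side):
            roi_sq = roi[ri : ri + side, ci : ci + side]
            in_roi = int(roi_sq.sum())
            if in_roi < min_coverage * side * side:
                continue
            cells_sq = int((cell[ri : ri + side, ci : ci + side] & roi_sq).sum())
            densities.append(cells_sq / in_roi)
    densities = np.array(densities)
    average = cell_area_density(cell, roi)
    het = float(np.var(densities)) if densities.size >= 2 else float("nan")
    return average, het, densities


def summarize_map(values: np.ndarray) -> tuple[float, float, int]:
    """(average, heterogeneity, n valid voxels) of one region's map values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return regional_average(v), regional_heterogeneity(v), int(v.size)


def build_summary(
    subject_maps: dict[str, dict[str, np.ndarray]],
    labels_by_subject: dict[str, "LabelVolume"],
    histology: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, float]],
    grid_size_mm: float = 0.8,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Assemble the tidy regional summary table.

    Parameters
    ----------
    subject_maps
        ``{subject: {measure: 3D scalar map}}`` with measures among
        FA/TR/MSD/RTOP; invalid voxels are NaN.
    labels_by_subject
        ``{subject: LabelVolume}`` on the same grids.
    histology
        ``{(subject, region): [(cell_mask, roi_mask, pixel_size_um), ...]}``
        feeding the CAD rows; qualifying grid squares from multiple sections
        of one region are pooled.  A bare tuple is accepted for a single
        section.  Missing entries produce flagged (NaN) rows.
    """
    rows = []
    for subject, measures in subject_maps.items():
        lab = labels_by_subject[subject]
        for label in sorted(lab.region_table):
            name, cls = lab.region_table[label]
            region_mask = lab.region_mask(label)
            present = bool(region_mask.any())
            for measure, scalar_map in measures.items():
                if present:
                    avg, het, n = summarize_map(scalar_map[region_mask])
                else:
                    avg, het, n = float("nan"), float("nan"), 0
                rows.append((subject, name, cls, measure, avg, het, n))
            key = (subject, name)
            if key in histology:
                entries = histology[key]
                if isinstance(entries, tuple):
                    entries = [entries]
                all_squares: list[np.ndarray] = []
                cell_px = roi_px = 0
                for cell, roi, px in entries:
                    _, _, squares = grid_cell_area_density(
                        cell, roi, px, grid_size_mm=grid_size_mm, min_coverage=min_coverage
                    )
                    all_squares.append(squares)
                    cell_px += int((np.asarray(cell, bool) & np.asarray(roi, bool)).sum())
                    roi_px += int(np.asarray(roi, bool).sum())
                pooled = np.concatenate(all_squares) if all_squares else np.empty(0)
                avg = cell_px / roi_px if roi_px else float("nan")
                het = float(np.var(pooled)) if pooled.size >= 2 else float("nan")
                rows.append((subject, name, cls, "CAD", avg, het, int(pooled.size)))
            else:
                rows.append((subject, name, cls, "CAD", float("nan"), float("nan"), 0))
    df = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    dup = df.duplicated(subset=["subject", "region", "measure"])
    if dup.any():
        raise ValueError("duplicate (subject, region, measure) rows")
    return df
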