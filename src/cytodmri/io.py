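"""Readers/writers for the standard formats the pipeline touches.

Covers FSL-style bval/bvec gradient tables, NIfTI diffusion and label
volumes, the tidy regional-summary CSV, and the synthetic-T2 contrast
transform (intensity reversal -> log enhancement -> histogram equalization)
used to give T1-weighted anatomy a b=0-like contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from skimage import exposure

from cytodmri.errors import FormatError, SchemaError

#: b-values at or below this (s/mm^2) are treated as b=0 for shell grouping;
#: scanners often report small non-zero values for nominally unweighted volumes.
B0_THRESHOLD = 50.0

REGION_CLASSES = ("cortical", "subcortical")

SUMMARY_COLUMNS = (
    "subject",
    "region",
    "class",
    "measure",
    "average",
    "heterogeneity",
    "n",
)


@dataclass
class GradientTable:
    """b-values (s/mm^2) and unit gradient directions for one acquisition."""

    bvals: np.ndarray  # (M,)
    bvecs: np.ndarray  # (M, 3), unit norm wherever bval > B0_THRESHOLD

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise FormatError(
                f"bvecs shape {self.bvecs.shape} does not match "
                f"{self.bvals.size} b-values"
            )
        if np.any(self.bvals < 0):
            raise FormatError("negative b-value")
        dw = self.bvals > B0_THRESHOLD
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(norms < 1e-12):
            raise FormatError("zero gradient direction for a diffusion-weighted volume")
        self.bvecs = self.bvecs.copy()
        self.bvecs[dw] /= norms[:, None]
        self.bvecs[~dw] = 0.0

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    def shells(self) -> np.ndarray:
        """Distinct nonzero shell b-values (after b0 thresholding)."""
        return np.unique(np.round(self.bvals[~self.b0_mask]))

    def subset(self, mask: np.ndarray) -> "GradientTable":
        return GradientTable(self.bvals[mask], self.bvecs[mask])


@dataclass
class DiffusionVolume:
    """4D diffusion signal on a regular grid with its gradient table."""

    signal: np.ndarray  # (X, Y, Z, M)
    affine: np.ndarray  # 4x4 grid-to-world (mm)
    gtab: GradientTable

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise FormatError("diffusion signal must be 4D (X,Y,Z,M)")
        if self.signal.shape[-1] != len(self.gtab):
            raise FormatError(
                f"signal has {self.signal.shape[-1]} volumes but gradient "
                f"table has {len(self.gtab)}"
            )
        if np.any(self.signal < 0):
            raise FormatError("negative signal intensity")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, recovered from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class LabelVolume:
    """Integer ROI labels on a diffusion grid; 0 is background."""

    labels: np.ndarray  # (X, Y, Z) int
    region_table: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("label volume must be integer-typed")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.region_table)
        if missing:
            raise SchemaError(f"labels {sorted(missing)} absent from region table")
        for lab, (name, cls) in self.region_table.items():
            if cls not in REGION_CLASSES:
                raise SchemaError(f"region {name!r}: class {cls!r} not in {REGION_CLASSES}")

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def region_labels(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})


def _read_numeric_table(path) -> np.ndarray:
    try:
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append([float(tok) for tok in line.split()])
    except ValueError as exc:
        raise FormatError(f"non-numeric token in {path}: {exc}") from exc
    if not rows:
        raise FormatError(f"empty gradient file {path}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"ragged rows in {path}")
    return np.array(rows)


def read_gradient_table(bval_path, bvec_path) -> GradientTable:
    """Read an FSL-dialect bval/bvec pair.

    Both the conventional 3xM layout and its M x 3 transpose are accepted;
    the axis of length 3 is taken as the coordinate axis (a genuinely
    ambiguous 3x3 file is read as FSL 3xM).  Directions for b > 0 are
    renormalized to unit length.
    """
    bvals = _read_numeric_table(bval_path).ravel()
    bvecs = _read_numeric_table(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise FormatError(f"bvec file {bvec_path} has no axis of length 3")
    if bvecs.shape[0] != bvals.size:
        raise FormatError(
            f"{bvals.size} b-values but {bvecs.shape[0]} gradient directions"
        )
    return GradientTable(bvals, bvecs)


def write_gradient_table(gtab: GradientTable, bval_path, bvec_path) -> None:
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in gtab.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in gtab.bvecs.T:  # FSL 3xM layout
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_nifti_volume(path, gtab: GradientTable) -> DiffusionVolume:
    img = nib.load(str(path))
    return DiffusionVolume(np.asarray(img.dataobj, dtype=float), img.affine, gtab)


def write_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float)), str(path))


def read_region_spec(path) -> dict[int, tuple[str, str]]:
    """Read a label/name/class CSV into a region table."""
    df = pd.read_csv(path)
    required = {"label", "name", "class"}
    if not required.issubset(df.columns):
        raise SchemaError(f"region spec must have columns {sorted(required)}")
    return {
        int(row["label"]): (str(row["name"]), str(row["class"]))
        for _, row in df.iterrows()
    }


def read_label_volume(nifti_path, region_table: dict[int, tuple[str, str]]) -> LabelVolume:
    img = nib.load(str(nifti_path))
    labels = np.asarray(img.dataobj)
    if not np.allclose(labels, np.round(labels)):
        raise FormatError("label volume contains non-integer values")
    return LabelVolume(labels.astype(np.int32), region_table)


def synthesize_t2_like(t1_image: np.ndarray) -> np.ndarray:
    """T2-like contrast from a T1-weighted image.

    Cascade, in order: intensity reversal I' = max(I) - I; log enhancement
    I'' = log(1 + I') rescaled to [0, 1]; discrete histogram equalization.
    The output lies in [0, 1] and its intensity rank order is the reverse of
    the input's.
    """
    img = np.asarray(t1_image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite intensities")
    if np.any(img < 0):
        raise ValueError("negative intensities")
    lo, hi = img.min(), img.max()
    if hi == lo:
        warnings.warn("constant input image: histogram equalization undefined")
        return np.full_like(img, 0.5)
    reversed_ = hi - img
    enhanced = np.log1p(reversed_)
    enhanced = (enhanced - enhanced.min()) / (enhanced.max() - enhanced.min())
    return exposure.equalize_hist(enhanced)


def _validate_summary(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(SUMMARY_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"summary table missing columns {sorted(missing)}")
    bad = set(table["class"].unique()) - set(REGION_CLASSES)
    if bad:
        raise SchemaError(f"unknown region classes {sorted(bad)}")
    return table.loc[:, list(SUMMARY_COLUMNS)]


def write_summary_table(table: pd.DataFrame, path) -> None:
    _validate_summary(table).to_csv(path, index=False, encoding="utf-8")


def read_summary_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        encoding="utf-8",
        dtype={"subject": str, "region": str, "class": str, "measure": str},
    )
    return _validate_summary(df)
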