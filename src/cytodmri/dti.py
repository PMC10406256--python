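"""Single-tensor diffusion model: WLLS fit on the b<=1000 shells, FA, trace.

The tensor is estimated per voxel by linear least squares on the
log-signal followed by one reweighting pass with weights equal to the
squared predicted signal — the standard WLLS estimator, which removes most
of the log-transform heteroscedasticity bias while staying deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cytodmri.io import B0_THRESHOLD, GradientTable

#: highest b-value (s/mm^2) entering the tensor fit
DTI_MAX_B = 1000.0


@dataclass
class TensorFit:
    """Per-voxel tensor fit over a flat voxel axis of length V."""

    s0: np.ndarray        # (V,)
    tensors: np.ndarray   # (V, 3, 3) symmetric, mm^2/s
    evals: np.ndarray     # (V, 3) descending, clamped >= 0
    evecs: np.ndarray     # (V, 3, 3), columns are eigenvectors
    valid: np.ndarray     # (V,) bool — fit usable
    clamped: np.ndarray   # (V,) bool — at least one eigenvalue clamped to 0


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """Rows map [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] to ln S."""
    b = gtab.bvals
    g = gtab.bvecs
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def _tensors_from_coeffs(coeffs: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = (coeffs[:, i] for i in range(1, 7))
    t = np.empty((coeffs.shape[0], 3, 3))
    t[:, 0, 0] = dxx
    t[:, 1, 1] = dyy
    t[:, 2, 2] = dzz
    t[:, 0, 1] = t[:, 1, 0] = dxy
    t[:, 0, 2] = t[:, 2, 0] = dxz
    t[:, 1, 2] = t[:, 2, 1] = dyz
    return t


def fit_dti(signal: np.ndarray, gtab: GradientTable, mask: np.ndarray | None = None) -> TensorFit:
    """Fit the tensor model to the b=0 and b<=1000 measurements.

    Parameters
    ----------
    signal
        Array (..., M) of diffusion signals; leading axes are flattened into
        a voxel axis for the fit and the results keep the flat layout.
    gtab
        Gradient table of length M.  Shells above ``DTI_MAX_B`` are ignored.
    mask
        Optional boolean array over the leading axes; voxels outside are
        marked invalid without fitting.
    """
    sig = np.asarray(signal, dtype=float)
    flat = sig.reshape(-1, sig.shape[-1])
    if flat.shape[1] != len(gtab):
        raise ValueError("signal/gradient-table length mismatch")

    sel = gtab.bvals <= DTI_MAX_B + 1e-9
    if sel.sum() < 7:
        raise ValueError("need at least 7 measurements with b <= 1000 for the tensor fit")
    if not np.any(gtab.bvals[sel] <= B0_THRESHOLD):
        raise ValueError("no b=0 measurement available")
    if not np.any(gtab.bvals[sel] > B0_THRESHOLD):
        raise ValueError("no diffusion-weighted measurement with b <= 1000")

    sub = gtab.subset(sel)
    y = flat[:, sel]
    V = y.shape[0]

    usable = np.all(y > 0, axis=1)
    if mask is not None:
        usable &= np.asarray(mask, bool).ravel()

    X = design_matrix(sub)  # (m, 7)
    coeffs = np.zeros((V, 7))
    if np.any(usable):
        logy = np.log(y[usable])
        # OLS pass
        beta, *_ = np.linalg.lstsq(X, logy.T, rcond=None)
        beta = beta.T  # (Vu, 7)
        # one reweighting pass: weights = predicted signal squared
        w = np.exp(X @ beta.T).T ** 2  # (Vu, m)
        XtW = X.T[None, :, :] * w[:, None, :]          # (Vu, 7, m)
        lhs = XtW @ X                                   # (Vu, 7, 7)
        rhs = np.einsum("vpm,vm->vp", XtW, logy)
        coeffs[usable] = np.linalg.solve(lhs, rhs[..., None])[..., 0]

    tensors = _tensors_from_coeffs(coeffs)
    evals, evecs = np.linalg.eigh(tensors)  # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]
    clamped = np.any(evals < 0, axis=1) & usable
    evals = np.clip(evals, 0.0, None)

    return TensorFit(
        s0=np.exp(coeffs[:, 0]) * usable,
        tensors=tensors,
        evals=evals,
        evecs=evecs,
        valid=usable,
        clamped=clamped,
    )


def fa(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (clamped) eigenvalues; 0 for a zero tensor."""
    ev = np.asarray(evals, dtype=float)
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt((3.0 / 2.0) * np.sum((ev - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(ev**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(out, 0.0, 1.0)


def trace_measure(evals: np.ndarray) -> np.ndarray:
    """Trace (sum of eigenvalues = sum of tensor diagonal), mm^2/s."""
    return np.asarray(evals, dtype=float).sum(axis=-1)
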