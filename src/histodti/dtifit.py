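"""Diffusion tensor fitting, scalar maps, and in-plane projection.

Tensors are fitted voxelwise to the log-signal by ordinary least squares
(the classic linear DTI fit): for measurement k with b-value b_k and unit
gradient direction g_k,

    ln S_k = ln S0 - b_k * g_k^T D g_k,

a linear model in the six unique tensor entries and ln S0.  From the
eigendecomposition of D, fractional anisotropy (FA), mean diffusivity
(MD = trace/3) and radial diffusivity (RD = (lambda2 + lambda3)/2) are
derived, and the principal eigenvector is projected into the sectioning
(xy) plane to give the in-plane axis Phi_DT, the out-of-plane angle, and
the projection length.  Voxels whose principal eigenvector leaves the
plane by more than 45 degrees carry too little in-plane information and
are excluded from orientation comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .phantom import GradientScheme

__all__ = [
    "TensorFitResult",
    "design_matrix",
    "fit_tensor",
    "scalar_maps",
    "project_principal",
    "out_of_plane_filter",
    "estimate_snr",
    "fit_volume",
]

RAYLEIGH_STD = np.sqrt(2.0 - np.pi / 2.0)  # std of |N(0,s) + i N(0,s)| / s


@dataclass
class TensorFitResult:
    """Voxelwise tensor fit: D (..., 3, 3), S0 estimate, clamp flags."""

    D: np.ndarray
    S0: np.ndarray
    clamped: np.ndarray  # True where nonpositive signals had to be clamped


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Log-linear DTI design: rows [-b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz, 1]."""
    b = scheme.bvals[:, None]
    g = scheme.bvecs
    return np.hstack(
        [
            -b * g[:, 0:1] ** 2,
            -b * g[:, 1:2] ** 2,
            -b * g[:, 2:3] ** 2,
            -2.0 * b * g[:, 0:1] * g[:, 1:2],
            -2.0 * b * g[:, 0:1] * g[:, 2:3],
            -2.0 * b * g[:, 1:2] * g[:, 2:3],
            np.ones_like(b),
        ]
    )


def _coef_to_tensor(coef: np.ndarray) -> np.ndarray:
    """Map OLS coefficients (..., 6) to symmetric tensors (..., 3, 3)."""
    dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(coef, -1, 0)
    D = np.empty(coef.shape[:-1] + (3, 3))
    D[..., 0, 0] = dxx
    D[..., 1, 1] = dyy
    D[..., 2, 2] = dzz
    D[..., 0, 1] = D[..., 1, 0] = dxy
    D[..., 0, 2] = D[..., 2, 0] = dxz
    D[..., 1, 2] = D[..., 2, 1] = dyz
    return D


def fit_tensor(signals: np.ndarray, scheme: GradientScheme) -> TensorFitResult:
    """Ordinary least-squares tensor fit on the log-signal.

    ``signals`` has shape ``(..., n_meas)``.  At least 7 measurements
    including one b=0 and 6 non-collinear directions are required for a
    solvable design.  Nonpositive signals are clamped to the smallest
    positive signal of the voxel and the voxel flagged.
    """
    s = np.asarray(signals, float)
    n_meas = s.shape[-1]
    if n_meas != len(scheme.bvals):
        raise ValueError("signal count does not match gradient scheme")
    if n_meas < 7 or not np.any(scheme.bvals == 0):
        raise ValueError("need >= 7 measurements including at least one b=0")
    X = design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "unsolvable design: fewer than 6 distinct non-collinear directions"
        )
    flat = s.reshape(-1, n_meas).copy()
    clamped = np.zeros(flat.shape[0], dtype=bool)
    bad = flat <= 0
    if bad.any():
        rows = bad.any(axis=1)
        clamped[rows] = True
        for r in np.nonzero(rows)[0]:
            pos = flat[r][flat[r] > 0]
            if pos.size == 0:
                raise ValueError("voxel with no positive signal cannot be fitted")
            flat[r][bad[r]] = pos.min()
    coef, *_ = np.linalg.lstsq(X, np.log(flat).T, rcond=None)
    coef = coef.T  # (n_vox, 7)
    D = _coef_to_tensor(coef[:, :6]).reshape(s.shape[:-1] + (3, 3))
    S0 = np.exp(coef[:, 6]).reshape(s.shape[:-1])
    return TensorFitResult(D=D, S0=S0, clamped=clamped.reshape(s.shape[:-1]))


def scalar_maps(D: np.ndarray) -> dict[str, np.ndarray]:
    """Eigendecomposition and the standard DTI scalars.

    Returns a dict with eigenvalues ``lam1 >= lam2 >= lam3``, the unit
    principal eigenvector ``v1``, ``fa``, ``md``, ``rd``, and flags:
    ``negative_eig`` (any eigenvalue < 0) and ``degenerate``
    (lam1 == lam2: the principal axis is not unique).

    FA uses the standard normalized eigenvalue-dispersion formula
    sqrt(3/2) * ||lam - MD|| / ||lam||; an all-zero tensor gets FA = 0.
    """
    D = np.asarray(D, float)
    evals, evecs = np.linalg.eigh(D)  # ascending
    lam = evals[..., ::-1]
    v1 = evecs[..., :, ::-1][..., :, 0]
    md = lam.mean(axis=-1)
    rd = 0.5 * (lam[..., 1] + lam[..., 2])
    sq_norm = (lam**2).sum(axis=-1)
    dev = ((lam - md[..., None]) ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(sq_norm > 0, dev / sq_norm, 0.0))
    fa = np.where(sq_norm > 0, fa, 0.0)
    scale = np.maximum(np.abs(lam).max(axis=-1), 1e-300)
    degenerate = (lam[..., 0] - lam[..., 1]) <= 1e-12 * scale
    return {
        "lam1": lam[..., 0],
        "lam2": lam[..., 1],
        "lam3": lam[..., 2],
        "v1": v1,
        "fa": fa,
        "md": md,
        "rd": rd,
        "negative_eig": lam[..., 2] < 0,
        "degenerate": degenerate,
    }


def project_principal(w: np.ndarray) -> dict[str, np.ndarray]:
    """Project unit principal eigenvectors into the sectioning (xy) plane.

    Discarding the z-coordinate yields the in-plane axis
    ``Phi_DT = atan2(w_y, w_x)`` folded to [0, 180) (the sign of w is
    irrelevant: eigenvectors are axes), the out-of-plane angle
    ``asin(|w_z|)`` in [0, 90] degrees, and the projection length
    ``sqrt(w_x^2 + w_y^2)``.  A vector along z has no in-plane axis:
    Phi is NaN there.
    """
    w = np.asarray(w, float)
    wx, wy, wz = w[..., 0], w[..., 1], w[..., 2]
    length = np.hypot(wx, wy)
    phi = np.mod(np.degrees(np.arctan2(wy, wx)), 180.0)
    phi = np.where(length > 1e-12, phi, np.nan)
    oop = np.degrees(np.arcsin(np.clip(np.abs(wz), 0.0, 1.0)))
    return {"phi_dt": phi, "out_of_plane": oop, "projection_length": length}


def out_of_plane_filter(
    out_of_plane_deg: np.ndarray,
    max_angle_deg: float = 45.0,
) -> tuple[np.ndarray, float]:
    """Retention mask for the out-of-plane criterion (inclusive threshold).

    Returns ``(keep, retained_fraction)``; voxels with out-of-plane angle
    of at most ``max_angle_deg`` are retained.
    """
    angles = np.asarray(out_of_plane_deg, float)
    keep = angles <= max_angle_deg
    return keep, float(keep.mean()) if angles.size else float("nan")


def estimate_snr(
    b0_volumes: np.ndarray,
    tissue_mask: np.ndarray,
    noise_box: tuple[slice, ...],
    *,
    rayleigh_correction: bool = True,
) -> float:
    """SNR from b=0 volumes: mean tissue signal over noise-corner spread.

    ``b0_volumes`` is (..., n_b0) or a single 3D volume; ``noise_box``
    indexes a signal-free corner of each volume.  The raw estimate divides
    the mean tissue signal by the standard deviation of the magnitude
    signal in the corner.  In magnitude MR images the corner noise is
    Rayleigh-distributed with std ~0.655 sigma, so by default the corner
    std is rescaled to the underlying Gaussian sigma
    (``rayleigh_correction=True``); set it False for the raw ratio.
    """
    vols = np.asarray(b0_volumes, float)
    if vols.ndim == 3:
        vols = vols[..., None]
    mask = np.asarray(tissue_mask, bool)
    if not mask.any():
        raise ValueError("tissue mask is empty")
    noise = vols[noise_box]
    if noise.size == 0:
        raise ValueError("noise box is empty")
    if mask[noise_box[:3] if len(noise_box) >= 3 else noise_box].any():
        raise ValueError("noise box overlaps the tissue mask")
    signal = vols[mask, :].mean()
    sd = noise.std()
    if sd == 0:
        warnings.warn("noiseless volume: SNR is infinite")
        return float("inf")
    if rayleigh_correction:
        sd = sd / RAYLEIGH_STD
    return float(signal / sd)


def fit_volume(
    dwi: np.ndarray,
    scheme: GradientScheme,
    tissue_mask: np.ndarray,
    *,
    max_out_of_plane_deg: float = 45.0,
) -> pd.DataFrame:
    """Fit tensors over a masked 4D volume and tabulate per-voxel results.

    ``tissue_mask`` uses labels 0 background, 1 GM, 2 WM; background
    voxels are not fitted.  Returns one row per tissue voxel with indices
    (i=x, j=y, k=z), tissue class, tensor scalars, Phi_DT, out-of-plane
    angle, projection length and quality flags.  The out-of-plane filter
    is *not* applied here — the joining stage applies it so exclusions can
    be tallied.
    """
    dwi = np.asarray(dwi, float)
    labels = np.asarray(tissue_mask)
    tissue = labels > 0
    idx = np.argwhere(tissue)
    signals = dwi[tissue, :]
    fit = fit_tensor(signals, scheme)
    maps = scalar_maps(fit.D)
    proj = project_principal(maps["v1"])
    tissue_name = np.where(labels[tissue] == 2, "WM", "GM")
    return pd.DataFrame(
        {
            "i": idx[:, 0],
            "j": idx[:, 1],
            "k": idx[:, 2],
            "tissue": tissue_name,
            "s0": fit.S0,
            "lam1": maps["lam1"],
            "lam2": maps["lam2"],
            "lam3": maps["lam3"],
            "fa": maps["fa"],
            "md": maps["md"],
            "rd": maps["rd"],
            "phi_dt": proj["phi_dt"],
            "out_of_plane": proj["out_of_plane"],
            "projection_length": proj["projection_length"],
            "negative_eig": maps["negative_eig"],
            "degenerate": maps["degenerate"],
            "clamped": fit.clamped,
        }
    )
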