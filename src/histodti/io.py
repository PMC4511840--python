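"""On-disk formats: NIfTI volumes, FSL gradient tables, TIFF sections,
CSV voxel tables, JSON configuration and run manifests.

All angle columns are stored in degrees with the axial convention
[0, 180); diffusivities in mm^2/s.  The sectioning plane is the xy-plane
of every NIfTI volume; affines are stored, but in-plane arithmetic uses
voxel indices.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .phantom import GradientScheme

__all__ = [
    "PipelineConfig",
    "read_gradient_table",
    "write_gradient_table",
    "read_volume",
    "write_volume",
    "read_section_image",
    "write_section_image",
    "read_voxel_table",
    "write_voxel_table",
    "write_manifest",
]

ANGLE_COLUMNS = {"phi_st", "phi_dt", "theta1", "theta2", "theta3", "tensor_axis"}

#: columns a voxel-record table must provide
VOXEL_TABLE_REQUIRED = ["i", "j", "k", "section_id", "tissue", "phi_dt", "phi_st", "diff"]


@dataclass
class PipelineConfig:
    """All pipeline tunables with their reference-analysis defaults."""

    st_sigma: float = 2.0           # px, Gaussian derivative scale
    st_kernel: int = 9              # px, kernel size (odd)
    fod_voxel_um: float = 340.0     # histological voxel side
    fod_bins: int = 180             # 1 degree per bin
    fod_fwhm_deg: float = 23.0      # histogram smoothing window
    fod_components: int = 3
    fod_window_deg: float = 42.0    # kappa fit half-window
    fod_min_valid_fraction: float = 0.05
    fod_min_stain: float = 0.02
    dti_max_oop_deg: float = 45.0   # out-of-plane exclusion threshold
    stats_fa_bin: float = 0.05
    stats_min_bin_n: int = 100
    stats_trunc_deg: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.st_sigma <= 0 or self.st_kernel % 2 == 0 or self.st_kernel < 3:
            raise ValueError("st_sigma must be > 0 and st_kernel odd >= 3")
        if self.fod_bins != 180:
            raise ValueError("the angular histogram is fixed at 180 one-degree bins")
        for name in ("fod_voxel_um", "fod_fwhm_deg", "fod_window_deg",
                     "stats_fa_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 1 <= self.fod_components <= 3:
            raise ValueError("fod_components must be 1..3")
        if not 0 <= self.dti_max_oop_deg <= 90:
            raise ValueError("dti_max_oop_deg must lie in [0, 90]")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def read_gradient_table(bval_path, bvec_path) -> GradientScheme:
    """FSL-style gradient table: bval one row, bvec three rows (x, y, z).

    Direction vectors whose norm deviates from 1 by more than 1e-6 are
    renormalized with a warning; vectors of b=0 measurements are zeroed.
    """
    bvals = np.loadtxt(bval_path, ndmin=2)
    if bvals.shape[0] != 1:
        raise ValueError(f"bval file must contain exactly 1 row, got {bvals.shape[0]}")
    bvals = bvals.ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must contain exactly 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != len(bvals):
        raise ValueError(
            f"gradient table length mismatch: {len(bvals)} b-values, "
            f"{bvecs.shape[1]} directions"
        )
    vecs = bvecs.T.copy()
    nz = bvals > 0
    if (~nz).any() and np.abs(vecs[~nz]).max(initial=0.0) > 0:
        warnings.warn("nonzero direction vectors on b=0 measurements zeroed")
        vecs[~nz] = 0.0
    norms = np.linalg.norm(vecs[nz], axis=1)
    off = np.abs(norms - 1.0) > 1e-6
    if off.any():
        warnings.warn(f"renormalized {int(off.sum())} gradient direction(s)")
        vecs[np.nonzero(nz)[0][off]] /= norms[off, None]
    return GradientScheme(bvals=bvals, bvecs=vecs)


def write_gradient_table(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.17g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.17g")


def write_volume(data: np.ndarray, path, voxel_size_mm: float = 0.34) -> None:
    """Write a volume as NIfTI-1 with an isotropic diagonal affine."""
    data = np.asarray(data)
    dtype = np.uint8 if data.dtype == np.uint8 else np.float32
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(data.astype(dtype), affine), str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_section_image(pixels: np.ndarray, path) -> None:
    """8-bit grayscale TIFF; gray levels in [0, 1] scaled to 0..255."""
    arr = np.clip(np.asarray(pixels, float), 0.0, 1.0)
    tifffile.imwrite(str(path), np.round(arr * 255).astype(np.uint8))


def read_section_image(path) -> np.ndarray:
    """Read a grayscale TIFF/PNG back to float gray levels in [0, 1]."""
    if str(path).lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr, float)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def write_voxel_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_voxel_table(path, required: Optional[list[str]] = None) -> pd.DataFrame:
    """Read a voxel-record CSV with schema validation.

    Missing required columns raise a format error naming the column;
    unknown extra columns are preserved with a warning.  Angle columns
    outside [0, 180) are normalized modulo 180 with a warning.
    """
    df = pd.read_csv(path)
    for col in required if required is not None else VOXEL_TABLE_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"voxel table is missing required column {col!r}")
    known = set(VOXEL_TABLE_REQUIRED) | ANGLE_COLUMNS | {
        "stain", "valid_fraction", "fa", "md", "rd", "out_of_plane",
        "projection_length", "ampl1", "ampl2", "ampl3", "width1", "width2",
        "width3", "kappa1", "kappa2", "kappa3", "s0", "lam1", "lam2", "lam3",
        "negative_eig", "degenerate", "clamped", "partial",
    }
    extra = set(df.columns) - known
    if extra:
        warnings.warn(f"voxel table has unknown columns (preserved): {sorted(extra)}")
    for col in ANGLE_COLUMNS & set(df.columns):
        vals = df[col].to_numpy(float)
        bad = np.isfinite(vals) & ((vals < 0) | (vals >= 180))
        if bad.any():
            warnings.warn(f"normalized {int(bad.sum())} angles in {col!r} modulo 180")
            df[col] = np.where(bad, np.mod(vals, 180.0), vals)
    return df


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(
    out_dir,
    command: str,
    config: PipelineConfig,
    inputs: Optional[list] = None,
    seed: Optional[int] = None,
) -> Path:
    """Run manifest for bit-reproducible reruns: config hash, seed, input checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_digest": config.digest(),
        "config": asdict(config),
        "seed": seed if seed is not None else config.seed,
        "inputs": {
            str(p): _checksum(Path(p)) for p in (inputs or []) if Path(p).exists()
        },
    }
    path = out_dir / f"manifest_{command}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path
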