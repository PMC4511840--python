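"""Section-to-slice alignment: 2D similarity transforms and z-assignment.

Each histological section is aligned to its MRI slice by a similarity
transform — one in-plane rotation, two translations and one isotropic
scale — stored as a 3x3 matrix in homogeneous coordinates.  The third
dimension is handled by assigning sections to slices by their physical
depth.  Transforms can be composed, inverted, estimated from landmark
pairs by least squares, and serialized to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.transform import SimilarityTransform

__all__ = [
    "SectionAlignment",
    "make_affine",
    "apply_affine",
    "invert_affine",
    "compose",
    "decompose_affine",
    "fit_alignment",
    "assign_sections",
]


@dataclass
class SectionAlignment:
    """Alignment of one section to one MRI z-slice."""

    section_id: int
    z_slice: int
    matrix: np.ndarray  # 3x3 homogeneous, histology -> MRI in-plane mm

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float).reshape(3, 3)
        if abs(np.linalg.det(self.matrix)) < 1e-15:
            raise ValueError("alignment matrix must be invertible")

    def to_dict(self) -> dict:
        return {
            "section_id": int(self.section_id),
            "z_slice": int(self.z_slice),
            "matrix": [float(v) for v in self.matrix.ravel()],
            "units": "mm",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SectionAlignment":
        return cls(
            section_id=int(d["section_id"]),
            z_slice=int(d["z_slice"]),
            matrix=np.asarray(d["matrix"], float).reshape(3, 3),
        )


def make_affine(
    rotation_deg: float = 0.0,
    tx: float = 0.0,
    ty: float = 0.0,
    scale: float = 1.0,
) -> np.ndarray:
    """Similarity matrix ``T @ R @ S`` about the origin.

    Rotation in degrees (from +x toward +y), translations in mm,
    isotropic scale > 0.  Identity parameters give the identity matrix.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    a = np.radians(rotation_deg)
    c, s = np.cos(a), np.sin(a)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    S = np.diag([scale, scale, 1.0])
    T = np.array([[1.0, 0.0, tx], [0.0, 1.0, ty], [0.0, 0.0, 1.0]])
    return T @ R @ S


def apply_affine(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a homogeneous 3x3 transform to (N, 2) points (or one point)."""
    pts = np.atleast_2d(np.asarray(points, float))
    hom = np.hstack([pts, np.ones((len(pts), 1))])
    out = (np.asarray(matrix, float) @ hom.T).T
    out = out[:, :2] / out[:, 2:3]
    return out[0] if np.asarray(points).ndim == 1 else out


def invert_affine(matrix: np.ndarray) -> np.ndarray:
    return np.linalg.inv(np.asarray(matrix, float))


def compose(*matrices: np.ndarray) -> np.ndarray:
    """Compose transforms; ``compose(A, B)`` applies B first, then A."""
    out = np.eye(3)
    for m in matrices:
        out = out @ np.asarray(m, float)
    return out


def decompose_affine(matrix: np.ndarray) -> dict[str, float]:
    """Recover (rotation_deg, tx, ty, scale) from a similarity matrix.

    Raises if the matrix contains shear or anisotropic scale beyond
    numerical tolerance — separate x/y scaling is deliberately outside
    the model.
    """
    M = np.asarray(matrix, float)
    A = M[:2, :2]
    scale = float(np.sqrt(abs(np.linalg.det(A))))
    if scale <= 0:
        raise ValueError("degenerate matrix")
    R = A / scale
    if not np.allclose(R.T @ R, np.eye(2), atol=1e-8) or np.linalg.det(R) < 0:
        raise ValueError("matrix is not a rotation-scale-translation similarity")
    rotation = float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))
    return {
        "rotation_deg": rotation,
        "tx": float(M[0, 2]),
        "ty": float(M[1, 2]),
        "scale": scale,
    }


def fit_alignment(
    src_points: np.ndarray,
    dst_points: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Least-squares similarity transform from landmark pairs.

    Estimates rotation, translation and isotropic scale minimizing the
    summed squared residuals of ``src -> dst`` (standard Umeyama
    estimate).  Needs at least 2 non-coincident pairs; collinear
    configurations remain solvable because the model has only 4 degrees
    of freedom.  Returns ``(matrix, rms_residual)``.
    """
    src = np.atleast_2d(np.asarray(src_points, float))
    dst = np.atleast_2d(np.asarray(dst_points, float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (N, 2) arrays")
    if len(src) < 2:
        raise ValueError("underdetermined: need at least 2 landmark pairs")
    if np.allclose(src, src[0]) or np.allclose(dst, dst[0]):
        raise ValueError("underdetermined: coincident landmark points")
    tf = SimilarityTransform.from_estimate(src, dst)
    if not tf:
        raise ValueError("similarity estimation failed")
    matrix = np.asarray(tf.params, float)
    resid = apply_affine(matrix, src) - dst
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return matrix, rms


def assign_sections(
    section_spacing_um: float,
    slice_thickness_um: float,
    n_sections: int,
    n_slices: int,
) -> list[tuple[int, int]]:
    """Pair each section with the MRI slice at the matching depth.

    Section m (center depth m * spacing) maps to slice
    ``round(m * spacing / thickness)``, clipped to the slice range; a
    slice may receive 0, 1 or 2 sections.  With 300 um section spacing
    and 340 um slices this reproduces the approximately 1:1 assignment
    in which roughly every tenth slice receives two consecutive sections.
    """
    if section_spacing_um <= 0 or slice_thickness_um <= 0:
        raise ValueError("spacings must be > 0")
    pairs = []
    for m in range(n_sections):
        z = int(round(m * section_spacing_um / slice_thickness_um))
        pairs.append((m, int(np.clip(z, 0, n_slices - 1))))
    return pairs


def save_alignments(alignments: Sequence[SectionAlignment], path) -> None:
    with open(path, "w") as fh:
        json.dump([a.to_dict() for a in alignments], fh, indent=1)


def load_alignments(path) -> list[SectionAlignment]:
    with open(path) as fh:
        return [SectionAlignment.from_dict(d) for d in json.load(fh)]
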