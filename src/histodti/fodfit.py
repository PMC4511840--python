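"""Voxel-scale fiber orientation distributions and axial von Mises mixtures.

Pixel-level orientation fields are pooled into "histological voxels":
square tiles whose side matches the MRI voxel size (340 um in the
reference acquisition).  Per tile the module computes a staining
intensity (1 - mean gray level), a normalized 180-bin orientation
histogram (1 degree per bin), smooths it with a circular Gaussian window
(23 degree FWHM by default), and greedily fits up to three axial von
Mises components.  The center of the first fitted component is the
voxel's primary histological orientation Phi_ST.

The axial von Mises density is 180-degree periodic,

    f(x; theta, kappa) ∝ exp(kappa * cos(2 * (x - theta))),

normalized so the 180 one-degree bins sum to one.  The greedy fit takes
the histogram maximum as component center and amplitude, estimates kappa
by least squares in a +/-42 degree window around the center, subtracts
the component, and repeats.  A component's width is defined relative to
the most concentrated component of the analysis set as 1 - kappa/kappa_max.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.ndimage import convolve1d

from .sttensor import SectionImage

__all__ = [
    "N_BINS",
    "VonMisesComponent",
    "VoxelFOD",
    "Tile",
    "voxelize",
    "staining_intensity",
    "orientation_histogram",
    "smooth_histogram",
    "axial_von_mises_pdf",
    "fit_von_mises_mixture",
    "component_width",
    "build_voxel_fods",
    "fods_to_table",
]

N_BINS = 180  # one-degree angular resolution over [0, 180)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VonMisesComponent:
    """One fitted axial von Mises component.

    ``theta`` in degrees [0, 180); ``kappa`` > 0 concentration;
    ``amplitude`` is the component's peak height in histogram-density
    units; ``width`` is filled in once kappa_max of the analysis set is
    known.
    """

    theta: float
    kappa: float
    amplitude: float
    width: Optional[float] = None


@dataclass
class VoxelFOD:
    """Per-voxel fiber orientation distribution and its mixture fit."""

    i: int
    j: int
    section_id: int
    stain: float
    valid_fraction: float
    histogram: np.ndarray
    smoothed: np.ndarray
    components: list[VonMisesComponent] = field(default_factory=list)
    partial: bool = False

    @property
    def primary_orientation(self) -> float:
        """Phi_ST: center of the first fitted component (NaN if none)."""
        return self.components[0].theta if self.components else float("nan")


@dataclass
class Tile:
    """One voxel-sized subimage of a section."""

    i: int  # column (x) tile index
    j: int  # row (y) tile index
    rows: slice
    cols: slice
    partial: bool


def voxelize(
    section: SectionImage,
    voxel_size_um: float = 340.0,
) -> tuple[list[Tile], int]:
    """Partition a section into voxel-sized square tiles.

    Tile side is ``round(voxel_size_um / pixel_size_um)`` pixels, anchored
    at the image origin.  Edge tiles that do not fully fit are flagged
    partial.  Returns ``(tiles, tile_side_px)``.
    """
    if voxel_size_um < section.pixel_size_um:
        raise ValueError("voxel_size_um must be >= pixel_size_um")
    side = int(round(voxel_size_um / section.pixel_size_um))
    ny, nx = section.pixels.shape
    tiles: list[Tile] = []
    for j in range((ny + side - 1) // side):
        for i in range((nx + side - 1) // side):
            r0, c0 = j * side, i * side
            r1, c1 = min(r0 + side, ny), min(c0 + side, nx)
            tiles.append(
                Tile(
                    i=i,
                    j=j,
                    rows=slice(r0, r1),
                    cols=slice(c0, c1),
                    partial=(r1 - r0 < side) or (c1 - c0 < side),
                )
            )
    return tiles, side


def staining_intensity(pixels: np.ndarray, valid_mask: np.ndarray) -> float:
    """Staining intensity of a tile: ``1 - mean gray level`` over valid pixels."""
    valid = np.asarray(valid_mask, bool)
    if not valid.any():
        raise ValueError("tile has no valid pixels")
    return float(1.0 - np.asarray(pixels, float)[valid].mean())


def orientation_histogram(
    phi: np.ndarray,
    valid_mask: Optional[np.ndarray] = None,
    *,
    divisor: str = "defined",
    total_pixels: Optional[int] = None,
) -> np.ndarray:
    """180-bin normalized histogram of pixel orientation axes.

    Bin ``b`` counts orientations in ``[b, b+1)`` degrees.  With
    ``divisor="defined"`` (default) the counts are divided by the number
    of pixels that contributed — valid pixels with a defined orientation —
    so that holes in the validity mask do not deflate amplitudes.  The
    literal alternative ``divisor="total"`` divides by the full tile pixel
    count (``total_pixels``, defaulting to ``phi.size``).
    """
    phi = np.asarray(phi, float)
    keep = np.isfinite(phi)
    if valid_mask is not None:
        keep &= np.asarray(valid_mask, bool)
    values = np.mod(phi[keep], 180.0)
    n_defined = values.size
    if n_defined == 0:
        raise ValueError("no defined orientations in tile")
    counts, _ = np.histogram(values, bins=N_BINS, range=(0.0, 180.0))
    if divisor == "defined":
        denom = n_defined
    elif divisor == "total":
        denom = total_pixels if total_pixels is not None else phi.size
    else:
        raise ValueError(f"unknown divisor: {divisor!r}")
    return counts / float(denom)


def smooth_histogram(h: np.ndarray, fwhm_deg: float = 23.0) -> np.ndarray:
    """Denoise a 180-bin angular histogram by circular Gaussian convolution.

    The window has the given full width at half maximum in degrees
    (sigma = FWHM / (2 sqrt(2 ln 2))) and unit sum, so total histogram
    mass is conserved.  Convolution wraps at the 0/180 boundary: axial
    data are 180-degree periodic.
    """
    if fwhm_deg <= 0:
        raise ValueError("fwhm_deg must be > 0")
    h = np.asarray(h, float)
    if h.shape != (N_BINS,):
        raise ValueError(f"histogram must have {N_BINS} bins")
    sigma = fwhm_deg * FWHM_TO_SIGMA
    offsets = np.arange(N_BINS) - N_BINS // 2
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()
    return convolve1d(h, kernel, mode="wrap")


def axial_von_mises_pdf(
    x_deg: np.ndarray | float,
    theta_deg: float,
    kappa: float,
) -> np.ndarray | float:
    """Axial (180-degree periodic) von Mises density per 1-degree bin.

    Normalized so that the density summed over the 180 integer bin
    positions equals one; hence ``kappa = 0`` gives the uniform density
    1/180, and f(theta) is the maximum.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    x = np.asarray(x_deg, float)
    grid = np.arange(N_BINS, dtype=float)
    log_unnorm = kappa * np.cos(2.0 * np.radians(grid - theta_deg))
    z = np.exp(log_unnorm - kappa).sum()  # factor e^-kappa for stability
    out = np.exp(kappa * np.cos(2.0 * np.radians(x - theta_deg)) - kappa) / z
    return float(out) if np.isscalar(x_deg) else out


def _component_curve(theta: float, kappa: float, amplitude: float) -> np.ndarray:
    """Component evaluated on the 180-bin grid, scaled to peak height ``amplitude``."""
    grid = np.arange(N_BINS, dtype=float)
    f = axial_von_mises_pdf(grid, theta, kappa)
    peak = axial_von_mises_pdf(theta, theta, kappa)
    return amplitude * f / peak


def fit_von_mises_mixture(
    smoothed: np.ndarray,
    n_components: int = 3,
    window_halfwidth_deg: float = 42.0,
    kappa_bounds: tuple[float, float] = (0.01, 100.0),
) -> list[VonMisesComponent]:
    """Greedy axial von Mises mixture fit of a smoothed 180-bin histogram.

    Per iteration: (1) the histogram maximum gives the component center
    theta (ties break to the lowest bin index) and amplitude d; (2) kappa
    minimizes the squared error between the histogram and the component
    curve ``d * f(x; theta, kappa) / f(theta; theta, kappa)`` over the
    circularly wrapped window ``theta +/- window_halfwidth``; (3) the
    component curve is subtracted (residuals are not clipped) and the loop
    repeats.  Greediness guarantees non-increasing amplitudes.

    An all-zero (or non-positive) histogram yields an empty component
    list: the voxel carries no orientation signal.
    """
    h = np.asarray(smoothed, float).copy()
    if h.shape != (N_BINS,):
        raise ValueError(f"histogram must have {N_BINS} bins")
    lo, hi = kappa_bounds
    if not (0 < lo < hi):
        raise ValueError("kappa bounds must satisfy 0 < lo < hi")
    components: list[VonMisesComponent] = []
    halfwidth = int(round(window_halfwidth_deg))
    for _ in range(n_components):
        idx = int(np.argmax(h))
        d = float(h[idx])
        if d <= 0.0:
            break
        theta = float(idx)
        window = np.mod(np.arange(idx - halfwidth, idx + halfwidth + 1), N_BINS)
        target = h[window]

        def sse(kappa: float) -> float:
            curve = _component_curve(theta, kappa, d)[window]
            return float(((target - curve) ** 2).sum())

        res = optimize.minimize_scalar(
            sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
        )
        kappa = float(res.x)
        h -= _component_curve(theta, kappa, d)
        components.append(VonMisesComponent(theta=theta, kappa=kappa, amplitude=d))
    return components


def component_width(kappa: float, kappa_max: float) -> float:
    """Relative component width ``1 - kappa / kappa_max`` in [0, 1]."""
    if kappa_max <= 0:
        raise ValueError("kappa_max must be > 0")
    if kappa < 0 or kappa > kappa_max:
        raise ValueError("kappa must lie in [0, kappa_max]")
    return 1.0 - kappa / kappa_max


def build_voxel_fods(
    section: SectionImage,
    phi: np.ndarray,
    voxel_size_um: float = 340.0,
    *,
    fwhm_deg: float = 23.0,
    n_components: int = 3,
    window_halfwidth_deg: float = 42.0,
    kappa_bounds: tuple[float, float] = (0.01, 100.0),
    min_valid_fraction: float = 0.05,
    min_stain: float = 0.02,
    histogram_divisor: str = "defined",
) -> list[VoxelFOD]:
    """Run the full histological voxel-space pipeline on one section.

    Tiles the section, computes staining intensity and the smoothed
    orientation histogram per tile, and fits the von Mises mixture.
    Voxels are discarded when the valid-pixel fraction falls below
    ``min_valid_fraction`` (tissue damage) or the staining intensity below
    ``min_stain`` (no stained material), mirroring the exclusion stages of
    a real analysis; discarded voxels are simply absent from the output.
    """
    tiles, _ = voxelize(section, voxel_size_um)
    out: list[VoxelFOD] = []
    for tile in tiles:
        pix = section.pixels[tile.rows, tile.cols]
        mask = section.valid_mask[tile.rows, tile.cols]
        n_total = pix.size
        valid_fraction = float(mask.sum()) / n_total
        if valid_fraction < min_valid_fraction:
            continue
        stain = staining_intensity(pix, mask)
        if stain < min_stain:
            continue
        tile_phi = phi[tile.rows, tile.cols]
        defined = np.isfinite(tile_phi) & mask
        if not defined.any():
            continue
        hist = orientation_histogram(
            tile_phi, mask, divisor=histogram_divisor, total_pixels=n_total
        )
        smoothed = smooth_histogram(hist, fwhm_deg)
        comps = fit_von_mises_mixture(
            smoothed,
            n_components=n_components,
            window_halfwidth_deg=window_halfwidth_deg,
            kappa_bounds=kappa_bounds,
        )
        out.append(
            VoxelFOD(
                i=tile.i,
                j=tile.j,
                section_id=section.section_id,
                stain=stain,
                valid_fraction=valid_fraction,
                histogram=hist,
                smoothed=smoothed,
                components=comps,
                partial=tile.partial,
            )
        )
    return out


def fods_to_table(
    fods: Sequence[VoxelFOD],
    kappa_max: Optional[float] = None,
) -> pd.DataFrame:
    """Tabulate fitted voxel FODs; one row per voxel.

    ``kappa_max`` defaults to the maximum kappa over all fitted components
    of the given voxels, and component widths are computed against it.
    Columns: i, j, section_id, stain, valid_fraction, then theta/kappa/
    ampl/width for components 1..3 (NaN where a component was not fitted).
    """
    if kappa_max is None:
        kappas = [c.kappa for f in fods for c in f.components]
        kappa_max = max(kappas) if kappas else float("nan")
    rows = []
    for f in fods:
        row: dict[str, float] = {
            "i": f.i,
            "j": f.j,
            "section_id": f.section_id,
            "stain": f.stain,
            "valid_fraction": f.valid_fraction,
        }
        for k in range(3):
            if k < len(f.components):
                c = f.components[k]
                width = component_width(min(c.kappa, kappa_max), kappa_max)
                row[f"theta{k + 1}"] = c.theta
                row[f"kappa{k + 1}"] = c.kappa
                row[f"ampl{k + 1}"] = c.amplitude
                row[f"width{k + 1}"] = width
            else:
                for name in ("theta", "kappa", "ampl", "width"):
                    row[f"{name}{k + 1}"] = float("nan")
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["kappa_max"] = kappa_max
    return df
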