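"""Structure-tensor orientation analysis of stained section images.

The local orientation of fibrous texture in a 2D grayscale image is
estimated from the structure tensor

    J = [[f_xx, f_xy],
         [f_xy, f_yy]],

where ``f_x``, ``f_y`` are derivative-of-Gaussian image gradients and the
tensor entries are the Gaussian-smoothed pointwise products of the
gradients.  The eigenvector of the larger eigenvalue points across the
local stripes (dominant gray-level variation); the fiber axis is that
axis rotated by 90 degrees.

Angle convention, used throughout the package: axes in degrees in
``[0, 180)``, measured from the +x (column) axis toward the +y (row)
axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "SectionImage",
    "OrientationField",
    "gaussian_kernel_2d",
    "image_gradient",
    "structure_tensor_field",
    "st_orientation",
    "orientation_field",
]

#: gradient magnitudes (squared) below this are treated as isotropic
ISOTROPY_TOL = 1e-12


@dataclass
class SectionImage:
    """One 2D grayscale histology section.

    Gray levels lie in ``[0, 1]`` with 0 the darkest stain.  ``valid_mask``
    is False over damaged or unstained pixels that must not contribute to
    any downstream statistic.
    """

    pixels: np.ndarray
    pixel_size_um: float
    valid_mask: Optional[np.ndarray] = None
    section_id: int = 0
    z_slice: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.pixels.shape:
                raise ValueError("valid_mask shape must match pixels")


@dataclass
class OrientationField:
    """Per-pixel structure-tensor results for one section."""

    f_xx: np.ndarray
    f_xy: np.ndarray
    f_yy: np.ndarray
    lam1: np.ndarray = field(init=False)
    lam2: np.ndarray = field(init=False)
    coherence: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        # closed-form symmetric 2x2 eigendecomposition
        half_trace = 0.5 * (self.f_xx + self.f_yy)
        # guard tiny negative arguments from rounding
        disc = np.sqrt(
            np.maximum(0.25 * (self.f_xx - self.f_yy) ** 2 + self.f_xy**2, 0.0)
        )
        self.lam1 = half_trace + disc
        self.lam2 = half_trace - disc
        denom = self.lam1 + self.lam2
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.where(denom > 0, (self.lam1 - self.lam2) / denom, 0.0)
        self.coherence = np.clip(coh, 0.0, 1.0)


def gaussian_kernel_2d(sigma: float, kernel_size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled rotationally symmetric Gaussian and its partial derivatives.

    Returns ``(G, Gx, Gy)`` on a ``kernel_size x kernel_size`` grid.  G is
    normalized to unit sum; the derivative kernels are scaled consistently
    so that convolving a ramp image ``I(x, y) = x`` yields a gradient of 1.
    """
    if kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    r = kernel_size // 2
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    g = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    g /= g.sum()
    gx = -(x / sigma**2) * g
    gy = -(y / sigma**2) * g
    return g, gx, gy


def image_gradient(
    image: np.ndarray | SectionImage,
    sigma: float = 2.0,
    kernel_size: int = 9,
) -> tuple[np.ndarray, np.ndarray]:
    """Derivative-of-Gaussian image gradient ``(f_x, f_y)``.

    Convolves the image with the partial derivatives of a rotationally
    symmetric Gaussian (default: 9-pixel kernel, sigma 2).  Boundaries are
    handled by reflection.
    """
    pixels = image.pixels if isinstance(image, SectionImage) else np.asarray(image, float)
    _, gx, gy = gaussian_kernel_2d(sigma, kernel_size)
    # true convolution (kernel flipped), equal to d/dx (I * G)
    f_x = ndimage.convolve(pixels, gx, mode="reflect")
    f_y = ndimage.convolve(pixels, gy, mode="reflect")
    return f_x, f_y


def structure_tensor_field(
    f_x: np.ndarray,
    f_y: np.ndarray,
    sigma: float = 2.0,
    kernel_size: int = 9,
) -> OrientationField:
    """Gaussian-smoothed gradient products f_xx, f_xy, f_yy.

    The same kernel is used for smoothing the products as for the
    differentiation stage.
    """
    f_x = np.asarray(f_x, float)
    f_y = np.asarray(f_y, float)
    if f_x.shape != f_y.shape:
        raise ValueError("gradient fields must have the same shape")
    g, _, _ = gaussian_kernel_2d(sigma, kernel_size)
    f_xx = ndimage.convolve(f_x * f_x, g, mode="reflect")
    f_xy = ndimage.convolve(f_x * f_y, g, mode="reflect")
    f_yy = ndimage.convolve(f_y * f_y, g, mode="reflect")
    return OrientationField(f_xx=f_xx, f_xy=f_xy, f_yy=f_yy)


def st_orientation(
    field: OrientationField,
    convention: str = "fiber",
) -> np.ndarray:
    """Per-pixel orientation axis in degrees ``[0, 180)``; NaN where undefined.

    ``convention="gradient"`` returns the axis of the eigenvector of the
    larger eigenvalue, which points across the stripes.  The default
    ``convention="fiber"`` returns that axis rotated by 90 degrees — the
    stripe (fiber) direction used by all downstream comparisons.

    Pixels with an isotropic tensor (``lam1 == lam2``, including blank
    areas with negligible gradient energy) have no defined orientation and
    are returned as NaN.
    """
    if convention not in ("fiber", "gradient"):
        raise ValueError(f"unknown convention: {convention!r}")
    # axis of the lam1 eigenvector of [[fxx,fxy],[fxy,fyy]]
    phi = 0.5 * np.degrees(np.arctan2(2.0 * field.f_xy, field.f_xx - field.f_yy))
    phi = np.mod(phi, 180.0)
    if convention == "fiber":
        phi = np.mod(phi + 90.0, 180.0)
    undefined = (field.lam1 - field.lam2) <= ISOTROPY_TOL * np.maximum(field.lam1, 1e-300)
    undefined |= field.lam1 <= ISOTROPY_TOL
    phi = np.where(undefined, np.nan, phi)
    return phi


def orientation_field(
    section: SectionImage | np.ndarray,
    sigma: float = 2.0,
    kernel_size: int = 9,
    convention: str = "fiber",
) -> tuple[OrientationField, np.ndarray]:
    """Convenience: gradient, structure tensor and orientation in one call.

    Returns ``(field, phi)`` where ``phi`` is additionally NaN outside the
    section's validity mask.
    """
    f_x, f_y = image_gradient(section, sigma=sigma, kernel_size=kernel_size)
    field = structure_tensor_field(f_x, f_y, sigma=sigma, kernel_size=kernel_size)
    phi = st_orientation(field, convention=convention)
    if isinstance(section, SectionImage):
        phi = np.where(section.valid_mask, phi, np.nan)
    return field, phi
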