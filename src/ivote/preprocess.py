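"""Image containers, noise suppression and gradient-field initialization.

The detector operates on a scalar intensity lattice (2D image or 3D stack)
with known physical voxel spacing.  Pre-processing consists of an optional
Gaussian blur followed by a finite-difference gradient whose magnitude
weights every lattice site as a voter and whose (possibly negated)
direction orients that voter's vote cone toward the cell interior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "GradientField",
    "gaussian_blur",
    "compute_gradient",
    "default_blur_sigma",
    "read_image",
    "write_image",
]

#: polarity flags: which side of an intensity edge the cell interior lies on
BRIGHT_CELLS = "bright_cells"
DARK_CELLS = "dark_cells"
_POLARITIES = (BRIGHT_CELLS, DARK_CELLS)


@dataclass(frozen=True)
class ImageGrid:
    """A 2D or 3D scalar intensity lattice with per-axis physical spacing.

    Parameters
    ----------
    values
        Intensity array, indexed in array order ``(y, x)`` or ``(z, y, x)``.
    spacing
        Physical size of one lattice step per axis, in micrometers, in the
        same axis order as ``values``.  All entries must be positive.
    """

    values: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        spacing = tuple(float(s) for s in self.spacing)
        object.__setattr__(self, "spacing", spacing)
        if values.ndim not in (2, 3):
            raise ValueError(f"image must be 2D or 3D, got {values.ndim}D")
        if len(spacing) != values.ndim:
            raise ValueError(
                f"spacing has {len(spacing)} entries for a {values.ndim}D image"
            )
        if any(s <= 0 for s in spacing):
            raise ValueError("all spacing entries must be strictly positive")
        if any(n < 3 for n in values.shape):
            raise ValueError(
                "every axis must have at least 3 sites for the gradient stencil"
            )

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class GradientField:
    """Per-site vote magnitude and vote direction.

    ``vectors`` stores the unit vote direction per site (array-axis order,
    physical space); sites with zero magnitude carry the null direction
    (the zero vector) and never cast votes.  For 2D fields the angular
    representation used by the classic formulation is available through
    :meth:`angles`.
    """

    magnitude: np.ndarray
    vectors: np.ndarray
    spacing: tuple[float, ...]
    polarity: str = DARK_CELLS

    def __post_init__(self) -> None:
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}")
        if self.vectors.shape != self.magnitude.shape + (self.magnitude.ndim,):
            raise ValueError("vectors must have shape (*magnitude.shape, ndim)")

    @property
    def ndim(self) -> int:
        return self.magnitude.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.magnitude.shape

    def angles(self) -> np.ndarray:
        """2D vote direction as an angle in [0, 2*pi); NaN at null sites."""
        if self.ndim != 2:
            raise ValueError("angles are defined for 2D fields only")
        # angle measured from the +x (column) axis: atan2(Iy, Ix)
        theta = np.arctan2(self.vectors[..., 0], self.vectors[..., 1])
        theta = np.mod(theta, 2.0 * np.pi)
        theta[self.magnitude == 0] = np.nan
        return theta


def default_blur_sigma(image: ImageGrid, sigma_px: float = 2.0) -> tuple[float, ...]:
    """Per-axis blur sigma (in pixels) giving a physically isotropic blur.

    The reference sigma applies to the finest-sampled axis; coarser axes
    are blurred by proportionally fewer pixels so that the physical blur
    width is identical on every axis.
    """
    finest = min(image.spacing)
    return tuple(sigma_px * finest / s for s in image.spacing)


def gaussian_blur(image: ImageGrid, sigma) -> ImageGrid:
    """Gaussian smoothing with reflective boundaries (mass conserving).

    ``sigma`` is in pixels, scalar or per-axis; ``sigma = 0`` returns the
    input values unchanged.
    """
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if sigma.size == 1:
        sigma = np.full(image.ndim, sigma[0])
    if sigma.size != image.ndim:
        raise ValueError("sigma must be scalar or one value per axis")
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    if np.all(sigma == 0):
        return ImageGrid(image.values.copy(), image.spacing)
    blurred = ndimage.gaussian_filter(image.values, sigma=sigma, mode="reflect")
    return ImageGrid(blurred, image.spacing)


def compute_gradient(image: ImageGrid, polarity: str = DARK_CELLS) -> GradientField:
    """Finite-difference gradient, converted to a voter field.

    Interior sites use second-order central differences, boundary sites
    first-order one-sided differences.  Derivatives are taken in physical
    units (per micrometer) so anisotropic stacks yield correct orientations.
    The stored vote direction is the unit gradient for ``bright_cells`` and
    the negated unit gradient for ``dark_cells``, so the cone always opens
    from the cell boundary toward the cell interior.
    """
    if polarity not in _POLARITIES:
        raise ValueError(f"polarity must be one of {_POLARITIES}")
    grads = np.gradient(image.values, *image.spacing, edge_order=1)
    g = np.stack(grads, axis=-1)
    magnitude = np.sqrt(np.sum(g * g, axis=-1))
    vectors = np.zeros_like(g)
    nz = magnitude > 0
    vectors[nz] = g[nz] / magnitude[nz][..., None]
    if polarity == DARK_CELLS:
        vectors = -vectors
    return GradientField(
        magnitude=magnitude, vectors=vectors, spacing=image.spacing, polarity=polarity
    )


def read_image(path, spacing) -> ImageGrid:
    """Read a single-page (2D) or multi-page (3D, z as page index) TIFF.

    Integer intensities are rescaled by the dtype range to [0, 1]; floating
    inputs are clipped to [0, 1].
    """
    values = tifffile.imread(str(path))
    values = np.squeeze(values)
    if values.ndim not in (2, 3):
        raise ValueError(f"unsupported TIFF dimensionality: {values.ndim}")
    if np.issubdtype(values.dtype, np.integer):
        info = np.iinfo(values.dtype)
        values = values.astype(np.float64) / float(info.max)
    else:
        values = np.clip(values.astype(np.float64), 0.0, 1.0)
    spacing = tuple(float(s) for s in np.atleast_1d(spacing))
    if len(spacing) == 1:
        spacing = spacing * values.ndim
    return ImageGrid(values, spacing)


def write_image(path, image: ImageGrid) -> None:
    """Write an ImageGrid as 32-bit float TIFF (multi-page for 3D)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), image.values.astype(np.float32))
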