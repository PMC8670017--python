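"""Core containers: image grids, projection geometry and sinograms.

Coordinate convention (shared by every module)
----------------------------------------------
Images are square ``N x N`` arrays of attenuation values.  The physical
coordinate system has its origin at pixel index ``(N//2, N//2)``, the
``a``-axis pointing rightward along columns and the ``b``-axis pointing
upward (i.e. against the row index).  Physical positions are pixel indices
times ``pixel_size``.  Detector bin ``D//2`` sits on the rotation axis
(plus an optional ``detector_center_offset``).

A parallel projection at angle ``alpha`` integrates the image along rays
with direction ``(-sin(alpha), cos(alpha))``; the signed detector
coordinate of a point ``(a, b)`` is ``s = a*cos(alpha) + b*sin(alpha)``
and the along-ray coordinate is ``c = b*cos(alpha) - a*sin(alpha)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class GeometryError(ValueError):
    """Raised when an image/geometry combination is inconsistent."""


class TruncationWarning(UserWarning):
    """Detector array does not span the image diagonal (truncated projections)."""


@dataclass
class ImageGrid:
    """A square 2D attenuation map with physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (N, N)
        Attenuation values in arbitrary but consistent units (per unit
        length if sinograms are to be read as dimensionless line integrals).
    pixel_size : float
        Physical edge length of one pixel (mm per pixel by convention).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise GeometryError(f"image must be square 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise GeometryError("image contains non-finite values")
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")

    @property
    def n(self) -> int:
        return self.pixels.shape[0]

    def coords_1d(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical ``a`` (column) and ``b`` (row) coordinates of pixel centers."""
        n = self.n
        a = (np.arange(n) - n // 2) * self.pixel_size
        b = (n // 2 - np.arange(n)) * self.pixel_size
        return a, b

    def coords_2d(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast ``(a, b)`` coordinate arrays of shape (N, N)."""
        a, b = self.coords_1d()
        return np.broadcast_to(a[None, :], (self.n, self.n)), np.broadcast_to(
            b[:, None], (self.n, self.n)
        )

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.pixels.copy(), self.pixel_size)


@dataclass
class ProjectionGeometry:
    """Parallel-beam acquisition geometry.

    ``angles`` are in radians, strictly increasing, within ``[0, 2*pi)``;
    ``detector_spacing`` shares the image's length unit.
    """

    angles: np.ndarray
    n_detectors: int
    detector_spacing: float = 1.0
    detector_center_offset: float = 0.0

    def __post_init__(self) -> None:
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if self.angles.size == 0:
            raise GeometryError("angle set is empty")
        if np.any(np.diff(self.angles) <= 0):
            raise GeometryError("angles must be strictly increasing")
        if self.angles[0] < 0 or self.angles[-1] >= 2 * np.pi:
            raise GeometryError("angles must lie in [0, 2*pi)")
        if self.n_detectors < 2:
            raise GeometryError("need at least 2 detector bins")
        if self.detector_spacing <= 0:
            raise GeometryError("detector_spacing must be positive")

    @property
    def n_angles(self) -> int:
        return self.angles.size

    def detector_coords(self) -> np.ndarray:
        """Signed physical coordinate ``s`` of each detector bin center."""
        d = self.n_detectors
        return (np.arange(d) - d // 2) * self.detector_spacing + self.detector_center_offset

    @property
    def span(self) -> float:
        """Physical width covered by the detector array."""
        return self.n_detectors * self.detector_spacing


@dataclass
class Sinogram:
    """Angles-by-detectors array of line integrals with its geometry."""

    values: np.ndarray
    geometry: ProjectionGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_angles, self.geometry.n_detectors)
        if self.values.shape != expected:
            raise GeometryError(
                f"sinogram shape {self.values.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("sinogram contains non-finite values")

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), replace(self.geometry, angles=self.geometry.angles.copy()))


@dataclass
class FilteredSinogram(Sinogram):
    """A sinogram whose rows have been convolved with a reconstruction filter."""

    filter_name: str = "none"


def default_geometry(
    n: int,
    n_angles: int = 180,
    *,
    pixel_size: float = 1.0,
    full_circle: bool = False,
) -> ProjectionGeometry:
    """Equally spaced angles over ``[0, pi)`` (or ``[0, 2*pi)``), D = N detectors.

    The half-circle default matches the inverse-Radon integral, which only
    needs angles over ``[0, pi)``; the full circle is used for projection
    symmetry checks.
    """
    arc = 2 * np.pi if full_circle else np.pi
    angles = np.arange(n_angles) * (arc / n_angles)
    return ProjectionGeometry(
        angles=angles, n_detectors=n, detector_spacing=pixel_size, detector_center_offset=0.0
    )
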