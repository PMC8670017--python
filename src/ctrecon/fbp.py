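"""Filtered backprojection: filter each projection, smear it across the image.

Reconstruction evaluates, for every pixel (a, b),

    f(a, b) = (pi / P) * sum_alpha g_alpha(a cos alpha + b sin alpha)

where g_alpha is the filtered projection and the sum discretizes the angle
integral over [0, pi).  Detector lookups use linear interpolation by
default (nearest-neighbor available for speed comparisons); ray coordinates
falling outside the detector span contribute nothing.
"""

from __future__ import annotations

import numpy as np

from .filters import ReconFilter, filter_projections
from .geometry import FilteredSinogram, GeometryError, ImageGrid, Sinogram

__all__ = ["backproject", "fbp_reconstruct"]


def backproject(
    fsino: FilteredSinogram | Sinogram,
    n: int,
    *,
    pixel_size: float | None = None,
    interpolation: str = "linear",
) -> ImageGrid:
    """Backproject filtered projections onto an ``n x n`` grid."""
    if n < 16:
        raise GeometryError("output grid size must be at least 16")
    geom = fsino.geometry
    if geom.n_angles == 0:
        raise GeometryError("empty angle set")
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    px = geom.detector_spacing if pixel_size is None else pixel_size
    out = ImageGrid(np.zeros((n, n)), px)
    a2, b2 = out.coords_2d()
    d = geom.n_detectors
    ds = geom.detector_spacing
    off = geom.detector_center_offset
    acc = np.zeros((n, n))
    for k, alpha in enumerate(geom.angles):
        s = a2 * np.cos(alpha) + b2 * np.sin(alpha)
        u = (s - off) / ds + d // 2  # fractional detector bin
        row = fsino.values[k]
        if interpolation == "nearest":
            j = np.rint(u).astype(int)
            inside = (j >= 0) & (j < d)
            contrib = np.where(inside, row[np.clip(j, 0, d - 1)], 0.0)
        else:
            j0 = np.floor(u).astype(int)
            frac = u - j0
            inside0 = (j0 >= 0) & (j0 < d)
            inside1 = (j0 + 1 >= 0) & (j0 + 1 < d)
            v0 = np.where(inside0, row[np.clip(j0, 0, d - 1)], 0.0)
            v1 = np.where(inside1, row[np.clip(j0 + 1, 0, d - 1)], 0.0)
            contrib = (1.0 - frac) * v0 + frac * v1
        acc += contrib
    out.pixels[:] = acc * (np.pi / geom.n_angles)
    return out


def fbp_reconstruct(
    sino: Sinogram,
    filt: ReconFilter | str = "ram-lak",
    n: int | None = None,
    *,
    pixel_size: float | None = None,
    interpolation: str = "linear",
) -> ImageGrid:
    """Filter the sinogram then backproject: the standard two-step inversion.

    ``filt`` may be a :class:`ReconFilter` or a filter name; ``n`` defaults
    to the detector count.  Deterministic: identical inputs give
    bit-identical output.
    """
    if isinstance(filt, str):
        filt = ReconFilter(name=filt)
    if np.any(sino.geometry.angles >= np.pi):
        raise GeometryError("FBP expects angles in [0, pi); fold the sinogram first")
    if n is None:
        n = sino.geometry.n_detectors
    fsino = filter_projections(sino, filt)
    return backproject(fsino, n, pixel_size=pixel_size, interpolation=interpolation)
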