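"""Direct Fourier reconstruction via the central slice theorem.

The 1D Fourier transform of a parallel projection at angle alpha equals the
slice of the image's 2D transform along the line through the origin at that
angle.  Direct Fourier reconstruction therefore 1D-transforms every
projection, scatters the polar samples onto a Cartesian frequency grid
(gridding), and inverts the 2D transform.  Simple gridding (nearest or
inverse-distance bilinear scatter with per-cell weight normalization) is
used deliberately: its interpolation artifacts are exactly what makes
filtered backprojection the sharper method in the three-algorithm
comparison this package benchmarks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import GeometryError, ImageGrid, ProjectionGeometry, Sinogram
from .projection import radon_forward

__all__ = ["fourier_slice_check", "fourier_reconstruct", "SliceCheckReport"]


def _projection_spectrum(values: np.ndarray, geom: ProjectionGeometry, m: int) -> np.ndarray:
    """Continuous-FT estimate of each projection row, sampled at fftfreq(m, ds).

    The detector center bin D//2 holds s = offset; rows are embedded in a
    length-m array with the center bin at index 0 (wrap-around order) so the
    DFT's phase convention matches a transform about s = 0, then scaled by
    the bin width.  A linear phase accounts for any detector center offset.
    """
    d = geom.n_detectors
    ds = geom.detector_spacing
    padded = np.zeros((values.shape[0], m))
    shift = d // 2
    padded[:, :d] = values
    padded = np.roll(padded, -shift, axis=1)
    spec = np.fft.fft(padded, axis=1) * ds
    if geom.detector_center_offset != 0.0:
        freqs = np.fft.fftfreq(m, d=ds)
        spec *= np.exp(-2j * np.pi * freqs * geom.detector_center_offset)[None, :]
    return spec


@dataclass
class SliceCheckReport:
    """Per-angle agreement between projection spectra and central image slices."""

    angles: np.ndarray
    rel_error: np.ndarray  # relative L2 error per angle

    @property
    def max_error(self) -> float:
        return float(np.max(self.rel_error)) if self.rel_error.size else 0.0

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.rel_error)) if self.rel_error.size else 0.0


def fourier_slice_check(
    img: ImageGrid, geom: ProjectionGeometry, pad_factor: int = 4
) -> SliceCheckReport:
    """Verify the central slice theorem on a concrete image and geometry.

    For each angle, the 1D spectrum of the forward projection is compared
    against the image's 2D spectrum interpolated along the central line at
    that angle; the report carries the relative L2 error per angle.  The
    image is zero-padded by ``pad_factor`` before the 2D transform so the
    bilinear interpolation between spectrum samples is not the dominant
    error.  A zero image yields zero error by convention.
    """
    sino = radon_forward(img, geom)
    d = geom.n_detectors
    ds = geom.detector_spacing
    m = 1 << int(np.ceil(np.log2(max(2 * d, 2))))
    spec = _projection_spectrum(sino.values, geom, m)
    freqs = np.fft.fftfreq(m, d=ds)

    n = img.n
    px = img.pixel_size
    # centered 2D spectrum on a pad_factor-finer frequency grid; the image's
    # center pixel (n//2, n//2) must land on the padded center (pn//2, pn//2)
    pn = pad_factor * n
    shift = pn // 2 - n // 2
    padded = np.zeros((pn, pn))
    padded[shift : shift + n, shift : shift + n] = img.pixels
    f2 = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(padded))) * px**2
    grid_freqs = np.fft.fftshift(np.fft.fftfreq(pn, d=px))
    f0 = grid_freqs[0]
    dfreq = grid_freqs[1] - grid_freqs[0]

    # restrict to frequencies the image grid can represent
    fmax = np.abs(grid_freqs).max()
    keep = np.abs(freqs) <= fmax

    errors = np.empty(geom.n_angles)
    for k, alpha in enumerate(geom.angles):
        fi = freqs[keep] * np.cos(alpha)  # a-frequency
        fj = freqs[keep] * np.sin(alpha)  # b-frequency
        # image rows run along -b, columns along +a
        rows = (-fj - f0) / dfreq
        cols = (fi - f0) / dfreq
        slice_re = map_coordinates(f2.real, [rows, cols], order=1, mode="grid-constant", cval=0.0, prefilter=False)
        slice_im = map_coordinates(f2.imag, [rows, cols], order=1, mode="grid-constant", cval=0.0, prefilter=False)
        central = slice_re + 1j * slice_im
        denom = np.linalg.norm(central)
        diff = np.linalg.norm(spec[k][keep] - central)
        errors[k] = diff / denom if denom > 0 else (0.0 if diff == 0 else np.inf)
    return SliceCheckReport(angles=geom.angles.copy(), rel_error=errors)


def fourier_reconstruct(
    sino: Sinogram,
    n: int | None = None,
    interp: str = "linear",
    *,
    pixel_size: float | None = None,
    full_output: bool = False,
):
    """Reconstruct by polar-to-Cartesian gridding of projection spectra.

    Every projection row is transformed, its samples placed on an n-by-n
    frequency grid at polar position (omega, alpha) by the chosen gridding
    rule, cells normalized by accumulated weight, unvisited cells zeroed
    (an implicit low-pass on the corners), conjugate symmetry enforced, and
    the 2D transform inverted.  Returns the real part.
    """
    if interp not in ("nearest", "linear"):
        raise ValueError("interp must be 'nearest' or 'linear'")
    geom = sino.geometry
    if np.any(geom.angles >= np.pi):
        raise GeometryError("direct Fourier reconstruction expects angles in [0, pi)")
    if n is None:
        n = geom.n_detectors
    if n < 16:
        raise GeometryError("output grid size must be at least 16")
    px = geom.detector_spacing if pixel_size is None else pixel_size

    d = geom.n_detectors
    ds = geom.detector_spacing
    m = 1 << int(np.ceil(np.log2(max(2 * d, 2))))
    spec = _projection_spectrum(sino.values, geom, m)
    freqs = np.fft.fftfreq(m, d=ds)

    dfreq = 1.0 / (n * px)  # target grid frequency spacing
    half = n // 2
    fmax = dfreq * half
    keep = np.abs(freqs) <= fmax

    acc = np.zeros((n, n), dtype=complex)  # centered frequency grid
    wsum = np.zeros((n, n))
    radius = freqs[keep] / dfreq  # in grid cells
    for k, alpha in enumerate(geom.angles):
        u = radius * np.cos(alpha) + half  # column index (a-frequency)
        v = half - radius * np.sin(alpha)  # row index (b-frequency up)
        vals = spec[k][keep]
        if interp == "nearest":
            iu = np.rint(u).astype(int)
            iv = np.rint(v).astype(int)
            ok = (iu >= 0) & (iu < n) & (iv >= 0) & (iv < n)
            np.add.at(acc, (iv[ok], iu[ok]), vals[ok])
            np.add.at(wsum, (iv[ok], iu[ok]), 1.0)
        else:
            u0 = np.floor(u).astype(int)
            v0 = np.floor(v).astype(int)
            fu = u - u0
            fv = v - v0
            for dv, dv_w in ((0, 1.0 - fv), (1, fv)):
                for du, du_w in ((0, 1.0 - fu), (1, fu)):
                    w = dv_w * du_w
                    iu = u0 + du
                    iv = v0 + dv
                    ok = (iu >= 0) & (iu < n) & (iv >= 0) & (iv < n) & (w > 0)
                    np.add.at(acc, (iv[ok], iu[ok]), vals[ok] * w[ok])
                    np.add.at(wsum, (iv[ok], iu[ok]), w[ok])

    visited = wsum > 0
    unvisited_frac = 1.0 - visited.sum() / visited.size
    if unvisited_frac > 0.5:
        warnings.warn(
            f"{unvisited_frac:.0%} of frequency cells unvisited: severe angular undersampling",
            stacklevel=2,
        )
    grid = np.zeros((n, n), dtype=complex)
    grid[visited] = acc[visited] / wsum[visited]

    # enforce F(-k) = conj(F(k)) so the inverse transform is (nearly) real
    g = np.fft.ifftshift(grid)
    g_neg = np.roll(g[::-1, ::-1], 1, axis=(0, 1))  # index map k -> -k mod n
    g = 0.5 * (g + np.conj(g_neg))

    complex_img = np.fft.fftshift(np.fft.ifft2(g)) * (n**2) * dfreq**2
    out = ImageGrid(complex_img.real, px)
    if full_output:
        real_norm = np.linalg.norm(complex_img.real)
        diagnostics = {
            "unvisited_frac": float(unvisited_frac),
            "imag_ratio": float(
                np.linalg.norm(complex_img.imag) / real_norm if real_norm > 0 else 0.0
            ),
        }
        return out, diagnostics
    return out
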