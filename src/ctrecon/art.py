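"""Algebraic reconstruction: imaging as a sparse linear system.

Writing the image as the unknown vector x and each (angle, detector)
measurement as one row of a sparse system A x = T, reconstruction becomes a
linear solve.  The solver is the Kaczmarz row-action method (ART): cycle
through rows in seeded random order, each time projecting the iterate onto
the hyperplane of one equation,

    x <- x + lam * (T_i - <a_i, x>) / ||a_i||^2 * a_i,    0 < lam < 2.

On consistent systems the distance to the solution set is non-increasing
per update.  The system matrix uses the same ray-driven bilinear sampling
as the forward projector, so A @ vec(img) agrees with ``radon_forward``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import sparse

from .geometry import GeometryError, ImageGrid, ProjectionGeometry, Sinogram
from .projection import _ray_samples

__all__ = ["build_system_matrix", "kaczmarz", "sirt", "art_reconstruct"]

log = logging.getLogger(__name__)


def build_system_matrix(
    geom: ProjectionGeometry, n: int, pixel_size: float = 1.0
) -> sparse.csr_matrix:
    """Sparse ray-pixel weight matrix matching ``radon_forward``'s sampling.

    One row per (angle, detector) pair in sinogram order; each ray is
    sampled along its length at the forward projector's step size and each
    sample scatters ``step`` times its bilinear footprint onto the four
    surrounding pixels.  A ray missing the grid gives an all-zero row.
    """
    if n < 2:
        raise GeometryError("grid too small")
    img_stub = ImageGrid(np.zeros((n, n)), pixel_size)
    s, c, step = _ray_samples(img_stub, geom)
    d = geom.n_detectors
    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    vals_out: list[np.ndarray] = []
    for k, alpha in enumerate(geom.angles):
        cos_a, sin_a = np.cos(alpha), np.sin(alpha)
        a = s[:, None] * cos_a - c[None, :] * sin_a
        b = s[:, None] * sin_a + c[None, :] * cos_a
        r = n // 2 - b / pixel_size  # fractional row
        q = a / pixel_size + n // 2  # fractional col
        r0 = np.floor(r).astype(int)
        q0 = np.floor(q).astype(int)
        fr = r - r0
        fq = q - q0
        ray_idx = np.broadcast_to(np.arange(d)[:, None], r.shape)
        for dr, wr in ((0, 1.0 - fr), (1, fr)):
            for dq, wq in ((0, 1.0 - fq), (1, fq)):
                rr = r0 + dr
                qq = q0 + dq
                w = wr * wq * step
                ok = (rr >= 0) & (rr < n) & (qq >= 0) & (qq < n) & (w != 0)
                rows_out.append(k * d + ray_idx[ok])
                cols_out.append(rr[ok] * n + qq[ok])
                vals_out.append(w[ok])
    mat = sparse.coo_matrix(
        (np.concatenate(vals_out), (np.concatenate(rows_out), np.concatenate(cols_out))),
        shape=(geom.n_angles * d, n * n),
    )
    return mat.tocsr()


def kaczmarz(
    a_mat,
    b: np.ndarray,
    sweeps: int = 10,
    relaxation: float = 1.0,
    seed_order: int = 0,
    nonneg: bool = False,
    x0: np.ndarray | None = None,
    residual_tol: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Kaczmarz row-action solve of A x = b; returns (x, residual norms per sweep).

    Rows are visited in a fresh seeded random permutation each sweep;
    zero-norm rows are skipped (count logged).  With ``nonneg`` the iterate
    is clamped to x >= 0 after each sweep.  ``residual_tol`` > 0 enables an
    early stop when the residual norm's relative change over a sweep falls
    below it.
    """
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    if not 0 < relaxation < 2:
        raise ValueError("relaxation must lie in (0, 2)")
    a_csr = sparse.csr_matrix(a_mat, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    n_rows, n_cols = a_csr.shape
    if b.size != n_rows:
        raise ValueError("right-hand side length does not match the matrix")
    row_norm2 = np.asarray(a_csr.multiply(a_csr).sum(axis=1)).ravel()
    zero_rows = int(np.count_nonzero(row_norm2 == 0))
    if zero_rows:
        log.info("kaczmarz: skipping %d zero-norm rows", zero_rows)
    usable = np.flatnonzero(row_norm2 > 0)

    x = np.zeros(n_cols) if x0 is None else np.array(x0, dtype=float).ravel().copy()
    indptr, indices, data = a_csr.indptr, a_csr.indices, a_csr.data
    rng = np.random.default_rng(seed_order)
    residuals = np.empty(sweeps)
    prev = np.linalg.norm(a_csr @ x - b)
    for sw in range(sweeps):
        order = rng.permutation(usable)
        for i in order:
            lo, hi = indptr[i], indptr[i + 1]
            cols = indices[lo:hi]
            vals = data[lo:hi]
            resid = b[i] - vals @ x[cols]
            x[cols] += (relaxation * resid / row_norm2[i]) * vals
        if nonneg:
            np.maximum(x, 0.0, out=x)
        residuals[sw] = np.linalg.norm(a_csr @ x - b)
        if residual_tol > 0 and (
            residuals[sw] == 0.0
            or (prev > 0 and abs(prev - residuals[sw]) / prev < residual_tol)
        ):
            residuals = residuals[: sw + 1]
            break
        prev = residuals[sw]
    return x, residuals


def sirt(
    a_mat,
    b: np.ndarray,
    sweeps: int = 10,
    relaxation: float = 1.0,
    nonneg: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Simultaneous iterative reconstruction (SIRT) comparator.

    x <- x + lam * C A^T R (b - A x) with R, C the inverse row/column sums.
    """
    a_csr = sparse.csr_matrix(a_mat, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    row_sum = np.asarray(a_csr.sum(axis=1)).ravel()
    col_sum = np.asarray(a_csr.sum(axis=0)).ravel()
    r_inv = np.where(row_sum > 0, 1.0 / np.maximum(row_sum, 1e-300), 0.0)
    c_inv = np.where(col_sum > 0, 1.0 / np.maximum(col_sum, 1e-300), 0.0)
    x = np.zeros(a_csr.shape[1])
    residuals = np.empty(sweeps)
    for sw in range(sweeps):
        resid = b - a_csr @ x
        x += relaxation * (c_inv * (a_csr.T @ (r_inv * resid)))
        if nonneg:
            np.maximum(x, 0.0, out=x)
        residuals[sw] = np.linalg.norm(a_csr @ x - b)
    return x, residuals


def art_reconstruct(
    sino: Sinogram,
    n: int | None = None,
    sweeps: int = 10,
    relaxation: float = 0.5,
    seed_order: int = 0,
    nonneg: bool = False,
    *,
    pixel_size: float | None = None,
    method: str = "kaczmarz",
    system_matrix: sparse.csr_matrix | None = None,
    return_residuals: bool = False,
):
    """Algebraic reconstruction of a sinogram on an ``n x n`` grid.

    Builds (or reuses) the ray-driven system matrix and runs seeded Kaczmarz
    sweeps from the zero image (SIRT behind ``method='sirt'``).  Deterministic
    given ``seed_order``.
    """
    geom = sino.geometry
    if n is None:
        n = geom.n_detectors
    px = geom.detector_spacing if pixel_size is None else pixel_size
    a_mat = system_matrix if system_matrix is not None else build_system_matrix(geom, n, px)
    if a_mat.shape != (geom.n_angles * geom.n_detectors, n * n):
        raise GeometryError("system matrix shape does not match geometry/grid")
    b = sino.values.ravel()
    if method == "kaczmarz":
        x, residuals = kaczmarz(
            a_mat, b, sweeps=sweeps, relaxation=relaxation, seed_order=seed_order, nonneg=nonneg
        )
    elif method == "sirt":
        x, residuals = sirt(a_mat, b, sweeps=sweeps, relaxation=relaxation, nonneg=nonneg)
    else:
        raise ValueError("method must be 'kaczmarz' or 'sirt'")
    img = ImageGrid(x.reshape(n, n), px)
    if return_residuals:
        return img, residuals
    return img
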