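"""Matrix-free fan-ray projector for the TCT geometry.

The system matrix A has one row per ray (source point -> detector element
center) and one column per image pixel; entry a_ij is the exact intersection
length (mm) of ray i with pixel j, computed by Siddon grid traversal.  The
forward projection, its exact adjoint, and the SART normalization sums
(row sums a_i+ and column sums a_+j) all share the identical traversal, so
<Af, g> == <f, A^T g> holds to floating-point round-off.

Kernels are JIT-compiled with numba; traversal order is fixed and there are no
stochastic elements, so all outputs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit, prange

from .geometry import ScanGeometry

__all__ = [
    "ImageGrid",
    "Sinogram",
    "ProjectionOperator",
    "forward_project",
    "back_project",
    "normalization_sums",
]


@dataclass
class ImageGrid:
    """Square 2-D attenuation map on a physical mm grid, centered on the axis.

    ``values[iy, ix]`` covers the half-open cell
    [xmin + ix*ps, xmin + (ix+1)*ps) x [ymin + iy*ps, ymin + (iy+1)*ps)
    with ps = ``pixel_size`` and xmin = ymin = -n*ps/2.
    """

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"image must be square 2-D, got shape {self.values.shape}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def extent(self) -> float:
        """Physical side length in mm."""
        return self.n * self.pixel_size

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.values.copy(), self.pixel_size)


@dataclass
class Sinogram:
    """Line-integral projection data, one value per (view, detector element)."""

    values: np.ndarray
    geometry: ScanGeometry = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.sinogram_shape:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.sinogram_shape}"
            )

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.geometry)


@njit(cache=True)
def _ray_grid_entry(sx, sy, ex, ey, xmin, ps, n):
    """Clip the segment (s -> e) against the grid square; return (t0, t1, hit)."""
    dx = ex - sx
    dy = ey - sy
    t0 = 0.0
    t1 = 1.0
    lo = xmin
    hi = xmin + n * ps
    # x slabs
    if dx == 0.0:
        if sx < lo or sx >= hi:
            return 0.0, 0.0, False
    else:
        ta = (lo - sx) / dx
        tb = (hi - sx) / dx
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    # y slabs
    if dy == 0.0:
        if sy < lo or sy >= hi:
            return 0.0, 0.0, False
    else:
        ta = (lo - sy) / dy
        tb = (hi - sy) / dy
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    if t1 <= t0:
        return 0.0, 0.0, False
    return t0, t1, True


@njit(cache=True, inline="always")
def _traverse(sx, sy, ex, ey, xmin, ps, n, image, sino_val, mode):
    """Siddon walk of one ray.

    mode 0: accumulate line integral over ``image`` and return it.
    mode 1: splat ``sino_val`` * length into ``image``; return total length.
    """
    t0, t1, hit = _ray_grid_entry(sx, sy, ex, ey, xmin, ps, n)
    if not hit:
        return 0.0
    dx = ex - sx
    dy = ey - sy
    length = np.sqrt(dx * dx + dy * dy)
    # Starting cell, nudged inside to dodge boundary-degenerate starts.
    eps = 1e-12
    tmid = t0 + eps * (t1 - t0)
    ix = int((sx + tmid * dx - xmin) / ps)
    iy = int((sy + tmid * dy - ymin_of(xmin)) / ps)
    if ix < 0:
        ix = 0
    if ix > n - 1:
        ix = n - 1
    if iy < 0:
        iy = 0
    if iy > n - 1:
        iy = n - 1
    step_x = 1 if dx > 0 else -1
    step_y = 1 if dy > 0 else -1
    if dx != 0.0:
        next_xb = xmin + (ix + (1 if dx > 0 else 0)) * ps
        tx = (next_xb - sx) / dx
        dtx = ps / abs(dx)
    else:
        tx = 1e30
        dtx = 1e30
    if dy != 0.0:
        next_yb = xmin + (iy + (1 if dy > 0 else 0)) * ps
        ty = (next_yb - sy) / dy
        dty = ps / abs(dy)
    else:
        ty = 1e30
        dty = 1e30
    t = t0
    acc = 0.0
    total = 0.0
    while t < t1 - 1e-14:
        if tx < ty:
            tn = tx
        else:
            tn = ty
        if tn > t1:
            tn = t1
        seg = (tn - t) * length
        if seg > 0.0:
            if mode == 0:
                acc += seg * image[iy, ix]
            else:
                image[iy, ix] += seg * sino_val
            total += seg
        t = tn
        if tx <= ty:
            ix += step_x
            tx += dtx
            if ix < 0 or ix >= n:
                break
        else:
            iy += step_y
            ty += dty
            if iy < 0 or iy >= n:
                break
    if mode == 0:
        return acc
    return total


@njit(cache=True, inline="always")
def ymin_of(xmin):
    # Square grid centered at the origin: ymin == xmin.
    return xmin


@njit(cache=True, parallel=True)
def _forward_kernel(src, det, xmin, ps, n, image, out):
    n_views = src.shape[0]
    n_det = det.shape[1]
    for v in prange(n_views):
        for d in range(n_det):
            out[v, d] = _traverse(
                src[v, 0], src[v, 1], det[v, d, 0], det[v, d, 1],
                xmin, ps, n, image, 0.0, 0,
            )


@njit(cache=True)
def _back_kernel(src, det, xmin, ps, n, sino, out):
    n_views = src.shape[0]
    n_det = det.shape[1]
    for v in range(n_views):
        for d in range(n_det):
            _traverse(
                src[v, 0], src[v, 1], det[v, d, 0], det[v, d, 1],
                xmin, ps, n, out, sino[v, d], 1,
            )


@njit(cache=True, parallel=True)
def _row_sums_kernel(src, det, xmin, ps, n, out):
    dummy = np.zeros((1, 1))
    n_views = src.shape[0]
    n_det = det.shape[1]
    for v in prange(n_views):
        for d in range(n_det):
            t0, t1, hit = _ray_grid_entry(
                src[v, 0], src[v, 1], det[v, d, 0], det[v, d, 1], xmin, ps, n
            )
            if hit:
                dx = det[v, d, 0] - src[v, 0]
                dy = det[v, d, 1] - src[v, 1]
                out[v, d] = (t1 - t0) * np.sqrt(dx * dx + dy * dy)
            else:
                out[v, d] = 0.0


def _check_grid(image: ImageGrid, geom: ScanGeometry) -> None:
    p = geom.params
    if image.n != p.image_pixels or abs(image.pixel_size - p.pixel_size) > 1e-12:
        raise ValueError(
            f"image grid ({image.n} px, {image.pixel_size} mm) does not match "
            f"geometry grid ({p.image_pixels} px, {p.pixel_size} mm)"
        )


def forward_project(image: ImageGrid, geom: ScanGeometry) -> Sinogram:
    """Line integrals of ``image`` along every ray of ``geom`` (Siddon)."""
    _check_grid(image, geom)
    n = image.n
    xmin = -n * image.pixel_size / 2.0
    out = np.empty(geom.sinogram_shape, dtype=np.float64)
    _forward_kernel(
        geom.source_points, geom.detector_points, xmin, image.pixel_size, n,
        np.ascontiguousarray(image.values), out,
    )
    return Sinogram(out, geom)


def back_project(sino: Sinogram, geom: ScanGeometry) -> ImageGrid:
    """Unnormalized adjoint A^T: pixel j = sum_i a_ij g_i, same weights as A."""
    if sino.geometry is not geom and sino.values.shape != geom.sinogram_shape:
        raise ValueError("sinogram does not match geometry")
    p = geom.params
    n = p.image_pixels
    ps = p.pixel_size
    xmin = -n * ps / 2.0
    out = np.zeros((n, n), dtype=np.float64)
    _back_kernel(
        geom.source_points, geom.detector_points, xmin, ps, n,
        np.ascontiguousarray(sino.values), out,
    )
    return ImageGrid(out, ps)


def normalization_sums(geom: ScanGeometry) -> tuple[np.ndarray, np.ndarray]:
    """SART normalization sums over the geometry's configured grid.

    Returns ``(row_sums, col_sums)``: row_sums[v, d] = a_i+ (total intersection
    length of ray i with the grid, equal to forward-projecting an all-ones
    image); col_sums[iy, ix] = a_+j.  Rays that miss the image square have row
    sum 0 and are flagged by ``row_sums == 0``; pixels crossed by no ray have
    column sum 0.
    """
    p = geom.params
    n = p.image_pixels
    ps = p.pixel_size
    xmin = -n * ps / 2.0
    row = np.empty(geom.sinogram_shape, dtype=np.float64)
    _row_sums_kernel(geom.source_points, geom.detector_points, xmin, ps, n, row)
    ones = Sinogram(np.ones(geom.sinogram_shape), geom)
    col = back_project(ones, geom).values
    return row, col


@dataclass
class ProjectionOperator:
    """Bound (geometry, grid) pair exposing A, A^T and the normalization sums."""

    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self._row_sums: np.ndarray | None = None
        self._col_sums: np.ndarray | None = None

    def apply(self, image: ImageGrid) -> Sinogram:
        return forward_project(image, self.geometry)

    def apply_adjoint(self, sino: Sinogram) -> ImageGrid:
        return back_project(sino, self.geometry)

    @property
    def row_sums(self) -> np.ndarray:
        if self._row_sums is None:
            self._row_sums, self._col_sums = normalization_sums(self.geometry)
        return self._row_sums

    @property
    def col_sums(self) -> np.ndarray:
        if self._col_sums is None:
            self._row_sums, self._col_sums = normalization_sums(self.geometry)
        return self._col_sums
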