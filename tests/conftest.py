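"""Shared fixtures and the dense brute-force system-matrix oracle.

The oracle computes every a_ij as the exact ray/pixel-box intersection length
by interval clipping, completely independently of the Siddon traversal used by
the package; it is tractable only for small grids (<= 32 x 32, few views).
"""

from __future__ import annotations

import numpy as np
import pytest

from tctrecon.geometry import TCTParams, ScanGeometry, build_tct_geometry


def small_params(n_pixels: int = 16, n_views: int = 25, n_det: int = 32) -> TCTParams:
    """Reduced bench keeping the physical layout but few rays/pixels."""
    return TCTParams(
        n_views_per_segment=n_views,
        view_spacing=29.0 / max(1, n_views - 1),
        n_detector_elements=n_det,
        detector_element_size=800.0 / n_det,
        image_pixels=n_pixels,
        pixel_size=1.38 * 256 / n_pixels,
    )


def dense_system_matrix(geom: ScanGeometry) -> np.ndarray:
    """Exact (M, N) system matrix from interval clipping of each ray against
    each pixel box.  Independent of the package's Siddon traversal."""
    p = geom.params
    n = p.image_pixels
    ps = p.pixel_size
    xmin = -n * ps / 2.0
    edges = xmin + np.arange(n + 1) * ps

    def slab(lo, hi, s, d):
        if d == 0.0:
            inside = (s >= lo) & (s < hi)
            return (
                np.where(inside, -np.inf, np.inf),
                np.where(inside, np.inf, -np.inf),
            )
        t1 = (lo - s) / d
        t2 = (hi - s) / d
        return np.minimum(t1, t2), np.maximum(t1, t2)

    rows = []
    for v in range(geom.n_views_total):
        sx, sy = geom.source_points[v]
        for d in range(p.n_detector_elements):
            ex, ey = geom.detector_points[v, d]
            dx, dy = ex - sx, ey - sy
            length = np.hypot(dx, dy)
            txlo, txhi = slab(edges[:-1][None, :], edges[1:][None, :], sx, dx)
            tylo, tyhi = slab(edges[:-1][:, None], edges[1:][:, None], sy, dy)
            tlo = np.maximum(np.maximum(txlo, tylo), 0.0)
            thi = np.minimum(np.minimum(txhi, tyhi), 1.0)
            rows.append((np.clip(thi - tlo, 0.0, None) * length).ravel())
    return np.asarray(rows)


def dense_sart_sweeps(A: np.ndarray, b: np.ndarray, f0: np.ndarray, beta: float, sweeps: int) -> np.ndarray:
    """Literal simultaneous update from the dense matrix: one sweep is
    f <- f + beta * (1/a_+j) * sum_i a_ij/a_i+ (b_i - A_i f)."""
    row = A.sum(axis=1)
    col = A.sum(axis=0)
    ray_ok = row > 0
    pix_ok = col > 0
    f = f0.copy()
    for _ in range(sweeps):
        resid = np.where(ray_ok, b - A @ f, 0.0) / np.where(ray_ok, row, 1.0)
        f = f + beta * np.where(pix_ok, (A.T @ resid) / np.where(pix_ok, col, 1.0), 0.0)
    return f


@pytest.fixture(scope="session")
def tiny_geom() -> ScanGeometry:
    """One 25-view segment on a 16 x 16 grid: small enough for the dense oracle."""
    return build_tct_geometry(small_params(16, 25, 32), 30.0)


@pytest.fixture(scope="session")
def tiny_dense_matrix(tiny_geom) -> np.ndarray:
    return dense_system_matrix(tiny_geom)
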