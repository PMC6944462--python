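"""Siddon projector: dense-oracle agreement, adjointness, chord lengths."""

import numpy as np
import pytest

from tctrecon.geometry import build_tct_geometry
from tctrecon.projector import (
    ImageGrid,
    ProjectionOperator,
    Sinogram,
    back_project,
    forward_project,
    normalization_sums,
)

from conftest import small_params, dense_system_matrix


def _grid_image(params, fill):
    n = params.image_pixels
    return ImageGrid(fill(np.zeros((n, n))), params.pixel_size)


def test_zero_image_projects_to_zero(tiny_geom):
    img = _grid_image(tiny_geom.params, lambda z: z)
    assert np.all(forward_project(img, tiny_geom).values == 0.0)


def test_zero_sinogram_backprojects_to_zero(tiny_geom):
    sino = Sinogram(np.zeros(tiny_geom.sinogram_shape), tiny_geom)
    assert np.all(back_project(sino, tiny_geom).values == 0.0)


def test_forward_matches_dense_oracle(tiny_geom, tiny_dense_matrix):
    """Siddon line integrals equal the brute-force a_ij sums, including for
    single-pixel images."""
    rng = np.random.default_rng(42)
    n = tiny_geom.params.image_pixels
    x = rng.random((n, n))
    img = ImageGrid(x, tiny_geom.params.pixel_size)
    expected = (tiny_dense_matrix @ x.ravel()).reshape(tiny_geom.sinogram_shape)
    np.testing.assert_allclose(forward_project(img, tiny_geom).values, expected, atol=1e-9)
    # single nonzero pixel: entries are value * intersection length
    one = np.zeros((n, n))
    one[5, 9] = 2.5
    img = ImageGrid(one, tiny_geom.params.pixel_size)
    expected = (tiny_dense_matrix[:, 5 * n + 9] * 2.5).reshape(tiny_geom.sinogram_shape)
    np.testing.assert_allclose(forward_project(img, tiny_geom).values, expected, atol=1e-10)


def test_backprojection_matches_dense_oracle(tiny_geom, tiny_dense_matrix):
    rng = np.random.default_rng(7)
    g = rng.standard_normal(tiny_geom.sinogram_shape)
    expected = (tiny_dense_matrix.T @ g.ravel()).reshape(16, 16)
    got = back_project(Sinogram(g, tiny_geom), tiny_geom).values
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_normalization_sums_match_dense_oracle(tiny_geom, tiny_dense_matrix):
    row, col = normalization_sums(tiny_geom)
    np.testing.assert_allclose(row.ravel(), tiny_dense_matrix.sum(axis=1), atol=1e-10)
    np.testing.assert_allclose(col.ravel(), tiny_dense_matrix.sum(axis=0), atol=1e-10)


def test_row_sums_equal_projection_of_ones(tiny_geom):
    row, _ = normalization_sums(tiny_geom)
    n = tiny_geom.params.image_pixels
    ones = ImageGrid(np.ones((n, n)), tiny_geom.params.pixel_size)
    np.testing.assert_allclose(row, forward_project(ones, tiny_geom).values, atol=1e-9)


def test_rays_missing_grid_have_zero_row_sum():
    """With a wide detector some edge rays miss the image square entirely."""
    params = small_params(16, 5, 64)
    geom = build_tct_geometry(params, 30.0)
    row, _ = normalization_sums(geom)
    assert (row == 0).any()
    # a missing ray contributes nothing to any pixel
    sino = np.where(row == 0, 1.0, 0.0)
    img = back_project(Sinogram(sino, geom), geom).values
    assert np.all(img == 0.0)


@pytest.mark.parametrize("scan_range", [90.0, 120.0, 150.0])
def test_adjointness_randomized(scan_range):
    """<Af, g> == <f, A^T g> to 1e-10 relative, for all three scan ranges."""
    params = small_params(32, 9, 40)
    geom = build_tct_geometry(params, scan_range)
    rng = np.random.default_rng(int(scan_range))
    f = ImageGrid(rng.standard_normal((32, 32)), params.pixel_size)
    g = rng.standard_normal(geom.sinogram_shape)
    Af = forward_project(f, geom).values
    Atg = back_project(Sinogram(g, geom), geom).values
    lhs = float((Af * g).sum())
    rhs = float((f.values * Atg).sum())
    denom = np.linalg.norm(Af) * np.linalg.norm(g)
    assert abs(lhs - rhs) / denom < 1e-10


@pytest.mark.parametrize(
    "radius,center,value", [(50.0, (0.0, 0.0), 1.0), (80.0, (30.0, -20.0), 0.7), (60.0, (-40.0, 10.0), 1.3)]
)
def test_disk_chord_lengths(radius, center, value):
    """Projections of a uniform disk equal value * 2 sqrt(r^2 - d^2) to within
    one pixel diagonal (x attenuation), over the rays whose distance from the
    disk center is at most 0.7 r -- nearer the rim the chord's sensitivity to
    the rasterized boundary, 2d/sqrt(r^2-d^2), diverges and no rasterization
    can meet a flat bound."""
    params = small_params(64, 25, 100)
    geom = build_tct_geometry(params, 120.0)
    n, ps = 64, params.pixel_size
    c = (np.arange(n) + 0.5) * ps - n * ps / 2
    xx, yy = np.meshgrid(c, c)
    cx, cy = center
    disk = ImageGrid(((xx - cx) ** 2 + (yy - cy) ** 2 < radius**2).astype(float) * value, ps)
    sino = forward_project(disk, geom).values
    src = geom.source_points[:, None, :]
    u = geom.detector_points - src
    u = u / np.linalg.norm(u, axis=2, keepdims=True)
    # signed distance of the ray line from the disk center
    d = np.abs(
        (src[..., 0] - cx) * u[..., 1] - (src[..., 1] - cy) * u[..., 0]
    )
    chord = 2.0 * np.sqrt(np.clip(radius**2 - d**2, 0.0, None)) * value
    mask = d <= 0.7 * radius
    err = np.abs(sino - chord)[mask]
    assert err.max() <= ps * np.sqrt(2) * value


def test_halving_pixel_size_changes_integrals_under_one_percent():
    """Refining the grid with the same smooth physical phantom barely moves
    the line integrals (discretization consistency)."""
    vals = {}
    for n in (128, 256):
        params = small_params(n, 9, 40)
        geom = build_tct_geometry(params, 30.0)
        ps = params.pixel_size
        c = (np.arange(n) + 0.5) * ps - n * ps / 2
        xx, yy = np.meshgrid(c, c)
        blob = np.exp(-((xx - 20) ** 2 + yy**2) / (2 * 40.0**2))
        vals[n] = forward_project(ImageGrid(blob, ps), geom).values
    a, b = vals[128], vals[256]
    assert np.abs(a - b).max() / np.abs(a).max() < 0.01


def test_operator_caches_sums(tiny_geom):
    op = ProjectionOperator(tiny_geom)
    row1 = op.row_sums
    assert op.row_sums is row1
    n = tiny_geom.params.image_pixels
    img = ImageGrid(np.ones((n, n)), tiny_geom.params.pixel_size)
    np.testing.assert_allclose(op.apply(img).values, row1, atol=1e-9)


def test_grid_mismatch_rejected(tiny_geom):
    with pytest.raises(ValueError):
        forward_project(ImageGrid(np.zeros((8, 8)), 1.0), tiny_geom)
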