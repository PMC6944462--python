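"""Synthetic phantoms, sinogram noise, and training-dataset assembly.

The phantom generator emulates 256 x 256 torso-like attenuation maps: either
the classic ten-ellipse head phantom or a seeded random-anatomy phantom (a
body-outline ellipse containing random internal ellipses).  A dataset pair is
(SART reconstruction from limited-angle data, phantom label) — the input/label
pairs on which the artifact-suppression network is trained.

Attenuation values are kept O(0.1)-O(1) per mm so that line integrals across
the ~350 mm field of view are O(10^2); the additive Gaussian projection noise
with variance 10 is then a visible but moderate perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import TCTParams, ScanGeometry, build_tct_geometry, ConfigurationError
from .projector import ImageGrid, Sinogram, forward_project
from .recon import SARTConfig, sart_reconstruct

__all__ = [
    "NoiseModel",
    "PhantomSpec",
    "DatasetPair",
    "make_phantom",
    "add_gaussian_noise",
    "build_dataset",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on the line-integral projection data."""

    mean: float = 0.0
    variance: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ConfigurationError("noise variance must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Reproducible phantom description: identical spec -> identical phantom."""

    kind: str = "random_anatomy"  # or "shepp_logan"
    n_pixels: int = 256
    seed: int = 0
    ellipse_count_range: tuple[int, int] = (4, 9)
    intensity_range: tuple[float, float] = (0.05, 0.45)
    body_outline_intensity: float = 0.25
    body_fill_fraction: tuple[float, float] = (0.75, 0.9)

    def __post_init__(self) -> None:
        if self.n_pixels < 16:
            raise ConfigurationError("n_pixels must be >= 16")
        if self.kind not in ("shepp_logan", "random_anatomy"):
            raise ConfigurationError(f"unknown phantom kind {self.kind!r}")


@dataclass
class DatasetPair:
    """(SART reconstruction, phantom label) with full provenance."""

    input_image: ImageGrid
    label_image: ImageGrid
    provenance: dict = field(default_factory=dict)


# Classic ten-ellipse head phantom (contrast-enhanced variant):
# (value, a, b, x0, y0, phi_deg) in a [-1, 1]^2 frame.
_SHEPP_LOGAN = [
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.874, 0.0, -0.0184, 0.0),
    (-0.2, 0.11, 0.31, 0.22, 0.0, -18.0),
    (-0.2, 0.16, 0.41, -0.22, 0.0, 18.0),
    (0.1, 0.21, 0.25, 0.0, 0.35, 0.0),
    (0.1, 0.046, 0.046, 0.0, 0.1, 0.0),
    (0.1, 0.046, 0.046, 0.0, -0.1, 0.0),
    (0.1, 0.046, 0.023, -0.08, -0.605, 0.0),
    (0.1, 0.023, 0.023, 0.0, -0.606, 0.0),
    (0.1, 0.023, 0.046, 0.06, -0.605, 0.0),
]


def _pixel_centers(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates in a [-1, 1]^2 frame, y increasing with row."""
    c = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    return np.meshgrid(c, c, indexing="xy")


def rasterize_ellipse(
    canvas: np.ndarray, value: float, a: float, b: float, x0: float, y0: float, phi_deg: float
) -> None:
    """Add ``value`` to every pixel whose *center* satisfies the analytic
    ellipse membership inequality ((x'/a)^2 + (y'/b)^2 <= 1 in the rotated
    frame).  Frame is [-1, 1]^2."""
    n = canvas.shape[0]
    xx, yy = _pixel_centers(n)
    phi = np.deg2rad(phi_deg)
    xr = (xx - x0) * np.cos(phi) + (yy - y0) * np.sin(phi)
    yr = -(xx - x0) * np.sin(phi) + (yy - y0) * np.cos(phi)
    canvas[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += value


def make_phantom(spec: PhantomSpec, pixel_size: Optional[float] = None) -> ImageGrid:
    """Rasterize a phantom on an ``n_pixels`` square grid.

    ``pixel_size`` defaults to scaling the bench's 256-pixel / 1.38 mm grid to
    the requested resolution, keeping the ~353 mm physical field of view.
    """
    if pixel_size is None:
        pixel_size = 1.38 * 256.0 / spec.n_pixels
    n = spec.n_pixels
    img = np.zeros((n, n))
    if spec.kind == "shepp_logan":
        for value, a, b, x0, y0, phi in _SHEPP_LOGAN:
            rasterize_ellipse(img, value, a, b, x0, y0, phi)
    else:
        rng = np.random.default_rng(spec.seed)
        lo, hi = spec.body_fill_fraction
        body_a = rng.uniform(lo, hi)
        body_b = rng.uniform(lo, hi)
        rasterize_ellipse(img, spec.body_outline_intensity, body_a, body_b, 0.0, 0.0, 0.0)
        inside = img > 0
        n_ell = rng.integers(spec.ellipse_count_range[0], spec.ellipse_count_range[1] + 1)
        vlo, vhi = spec.intensity_range
        for _ in range(n_ell):
            a = rng.uniform(0.05, 0.35) * body_a
            b = rng.uniform(0.05, 0.35) * body_b
            r = rng.uniform(0.0, 0.7)
            ang = rng.uniform(0.0, 2 * np.pi)
            x0 = r * body_a * np.cos(ang)
            y0 = r * body_b * np.sin(ang)
            value = rng.uniform(vlo, vhi) - spec.body_outline_intensity
            rasterize_ellipse(img, value, a, b, x0, y0, np.rad2deg(rng.uniform(0, np.pi)))
        img[~inside] = 0.0
    np.clip(img, 0.0, None, out=img)
    return ImageGrid(img, pixel_size)


def add_gaussian_noise(sino: Sinogram, noise: NoiseModel) -> Sinogram:
    """Return a noisy copy of the sinogram; the input is not modified."""
    if noise.variance == 0:
        out = sino.copy()
        out.values += noise.mean
        return out
    rng = np.random.default_rng(noise.seed)
    draw = rng.normal(noise.mean, np.sqrt(noise.variance), size=sino.values.shape)
    return Sinogram(sino.values + draw, sino.geometry)


def desk_scale_params(n_pixels: int = 64) -> TCTParams:
    """Reduced-resolution bench for CPU-scale runs.

    Keeps the physical layout (distances, 30-degree segments, ~353 mm field of
    view and 800 mm detector width) while cutting the view and detector-element
    counts proportionally to the coarser grid.
    """
    factor = 256 // n_pixels
    return TCTParams(
        n_views_per_segment=max(2, (207 + factor - 1) // factor),
        view_spacing=0.145 * factor,
        n_detector_elements=max(2, 800 // factor),
        detector_element_size=1.0 * factor,
        image_pixels=n_pixels,
        pixel_size=1.38 * factor,
    )


def build_dataset(
    n_train: int,
    n_test: int,
    scan_range: float = 120.0,
    noise: Optional[NoiseModel] = None,
    sart_cfg: Optional[SARTConfig] = None,
    master_seed: int = 0,
    params: Optional[TCTParams] = None,
    phantom_kind: str = "random_anatomy",
) -> tuple[list[DatasetPair], list[DatasetPair]]:
    """Generate (SART image, label) pairs for training and testing.

    For each index: phantom -> forward projection -> optional Gaussian noise
    -> SART reconstruction.  Train and test phantoms draw from disjoint seed
    streams spawned from ``master_seed``, so no phantom can appear in both
    splits; the whole pipeline is reproducible bit-for-bit from
    ``(master_seed, configs)``.
    """
    if n_train < 1 or n_test < 1:
        raise ConfigurationError("n_train and n_test must be >= 1")
    params = params or TCTParams()
    sart_cfg = sart_cfg or SARTConfig()
    geom = build_tct_geometry(params, scan_range)

    def _make_split(split_idx: int, count: int) -> list[DatasetPair]:
        pairs = []
        root = np.random.SeedSequence(master_seed)
        for i in range(count):
            seeds = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(split_idx, i)
            ).generate_state(2)
            spec = PhantomSpec(
                kind=phantom_kind, n_pixels=params.image_pixels, seed=int(seeds[0])
            )
            phantom = make_phantom(spec, pixel_size=params.pixel_size)
            sino = forward_project(phantom, geom)
            if noise is not None and noise.variance > 0:
                sino = add_gaussian_noise(
                    sino, NoiseModel(noise.mean, noise.variance, seed=int(seeds[1]))
                )
            recon = sart_reconstruct(sino, geom, sart_cfg)
            pairs.append(
                DatasetPair(
                    input_image=recon,
                    label_image=phantom,
                    provenance={
                        "split": "train" if split_idx == 0 else "test",
                        "index": i,
                        "scan_range": scan_range,
                        "phantom_seed": int(seeds[0]),
                        "noise": None
                        if noise is None
                        else {"mean": noise.mean, "variance": noise.variance,
                              "seed": int(seeds[1])},
                        "sart": {"relax_beta": sart_cfg.relax_beta,
                                 "n_iterations": sart_cfg.n_iterations,
                                 "update_mode": sart_cfg.update_mode},
                        "master_seed": master_seed,
                    },
                )
            )
        return pairs

    return _make_split(0, n_train), _make_split(1, n_test)
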