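"""Translational CT (TCT) scanning geometry.

The scanner acquires one 30-degree *segment* per translation: the source slides
along a line on one side of the rotation axis while the flat-panel detector
slides in the opposite direction on the other side.  Between segments the
whole source/detector pair is rotated rigidly about the axis by the segment
span.  A limited-angle scan of range K x 30 degrees therefore consists of K
segments of ``n_views_per_segment`` views each, and every view contributes one
fan of ``n_detector_elements`` rays.

Coordinate convention: rotation axis at the origin, units in mm, image pixel
grid centered on the axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["TCTParams", "ScanGeometry", "build_tct_geometry", "view_angles"]


class ConfigurationError(ValueError):
    """Invalid scanner or reconstruction configuration."""


@dataclass(frozen=True)
class TCTParams:
    """Physical parameters of the simulated TCT scanner.

    Defaults follow the reference bench: source-to-detector distance 1300 mm,
    source-to-axis distance 900 mm, 207 source positions per 30-degree segment
    sampled every 0.145 degrees, an 800-element flat detector with 1 mm
    elements, and a 256 x 256 image grid with 1.38 mm pixels.
    """

    dist_source_detector: float = 1300.0
    dist_source_axis: float = 900.0
    view_spacing: float = 0.145
    segment_span: float = 30.0
    n_views_per_segment: int = 207
    n_detector_elements: int = 800
    detector_element_size: float = 1.0
    image_pixels: int = 256
    pixel_size: float = 1.38
    # Nominal field-of-view diameter; recorded as metadata only, never used in
    # any computation (its exact derivation from the bench is not defined).
    fov_diameter: float = 352.90

    def __post_init__(self) -> None:
        positive = {
            "dist_source_detector": self.dist_source_detector,
            "dist_source_axis": self.dist_source_axis,
            "view_spacing": self.view_spacing,
            "segment_span": self.segment_span,
            "n_views_per_segment": self.n_views_per_segment,
            "n_detector_elements": self.n_detector_elements,
            "detector_element_size": self.detector_element_size,
            "image_pixels": self.image_pixels,
            "pixel_size": self.pixel_size,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {value!r}")
        if not self.dist_source_axis < self.dist_source_detector:
            raise ConfigurationError(
                "dist_source_axis must be smaller than dist_source_detector"
            )
        span = (self.n_views_per_segment - 1) * self.view_spacing
        if span > self.segment_span + 1e-9:
            raise ConfigurationError(
                f"views span {span:.4f} deg, exceeding the segment span "
                f"{self.segment_span} deg"
            )

    def to_dict(self) -> dict:
        """Serializable form, suitable for YAML/JSON echoing of the bench table."""
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TCTParams":
        return cls(**d)


@dataclass(frozen=True)
class ScanGeometry:
    """The full set of TCT views for one limited-angle scan.

    Attributes
    ----------
    params : TCTParams
    scan_range : float
        Nominal angular coverage in degrees (a positive multiple of the
        segment span; 90, 120 and 150 are the standard presets).
    source_points : ndarray, shape (n_views_total, 2)
        Source (x, y) per view, mm, ordered segment-major then view order.
    detector_points : ndarray, shape (n_views_total, n_detector_elements, 2)
        Detector element center positions per view, mm.
    """

    params: TCTParams
    scan_range: float
    source_points: np.ndarray = field(repr=False)
    detector_points: np.ndarray = field(repr=False)

    @property
    def n_segments(self) -> int:
        return int(round(self.scan_range / self.params.segment_span))

    @property
    def n_views_total(self) -> int:
        return self.source_points.shape[0]

    @property
    def n_rays_total(self) -> int:
        """M: total number of rays (views x detector elements)."""
        return self.n_views_total * self.params.n_detector_elements

    @property
    def sinogram_shape(self) -> tuple[int, int]:
        return (self.n_views_total, self.params.n_detector_elements)

    def segment(self, m: int) -> tuple[np.ndarray, np.ndarray]:
        """Source and detector points of segment ``m`` (0-based)."""
        nv = self.params.n_views_per_segment
        sl = slice(m * nv, (m + 1) * nv)
        return self.source_points[sl], self.detector_points[sl]


def _segment_frame_views(params: TCTParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Source and detector points for one segment in its local frame.

    In the local frame the source translates along y = +R_s and the detector
    along y = -(D - R_s), where R_s is the source-axis distance and D the
    source-detector distance.  View k sits at deflection angle
    gamma_k = -span/2 + k * view_spacing (span = (n_views - 1) * view_spacing);
    the source is placed at (-R_s tan gamma_k, R_s) so that the view angle at
    the axis increases with k.  The detector array is centered where the
    source-axis line crosses the detector translation line and stays parallel
    to that line (a translating flat panel).
    """
    rs = params.dist_source_axis
    rd = params.dist_source_detector - params.dist_source_axis
    n_views = params.n_views_per_segment
    span = (n_views - 1) * params.view_spacing
    gamma = np.deg2rad(-span / 2.0 + np.arange(n_views) * params.view_spacing)

    src = np.stack([-rs * np.tan(gamma), np.full(n_views, rs)], axis=1)
    # Source-axis line continued to the detector line y = -rd.
    det_center = np.stack([rd * np.tan(gamma), np.full(n_views, -rd)], axis=1)
    n_det = params.n_detector_elements
    offsets = (np.arange(n_det) - (n_det - 1) / 2.0) * params.detector_element_size
    elem_offsets = np.stack([offsets, np.zeros(n_det)], axis=1)
    det = det_center[:, None, :] + elem_offsets[None, :, :]
    return np.rad2deg(gamma), src, det


def _rotate(points: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return points @ rot.T


def build_tct_geometry(params: TCTParams, scan_range: float) -> ScanGeometry:
    """Construct the limited-angle TCT geometry for a given scan range.

    ``scan_range`` must be a positive integer multiple of the segment span.
    Segment m (0-based) is segment 0 rotated rigidly about the axis by
    m x segment_span degrees; segment m's central view direction sits at
    segment_span/2 + m x segment_span degrees in the global frame.
    """
    span = params.segment_span
    ratio = scan_range / span
    n_segments = int(round(ratio))
    if n_segments < 1 or abs(ratio - n_segments) > 1e-9:
        raise ConfigurationError(
            f"scan_range {scan_range} deg is not a positive multiple of the "
            f"segment span {span} deg"
        )

    _, src0, det0 = _segment_frame_views(params)
    sources = []
    detectors = []
    for m in range(n_segments):
        # Local frame has the central view pointing at 90 deg; place it at the
        # segment's nominal center span/2 + m*span.
        theta = span / 2.0 + m * span - 90.0
        sources.append(_rotate(src0, theta))
        detectors.append(_rotate(det0.reshape(-1, 2), theta).reshape(det0.shape))
    return ScanGeometry(
        params=params,
        scan_range=float(scan_range),
        source_points=np.concatenate(sources, axis=0),
        detector_points=np.concatenate(detectors, axis=0),
    )


def view_angles(geom: ScanGeometry) -> np.ndarray:
    """Per-view angle (degrees) of the source-axis line in the global frame.

    Strictly increasing within each segment; the central view of segment m is
    at segment_span/2 + m x segment_span.
    """
    p = geom.params
    gamma, _, _ = _segment_frame_views(p)
    bases = p.segment_span / 2.0 + np.arange(geom.n_segments) * p.segment_span
    return (bases[:, None] + gamma[None, :]).ravel()
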