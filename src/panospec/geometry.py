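"""Dental arch definition and the panoramic source/detector sweep.

The arch is recovered from the bone labels as a symmetric quartic
``y(x) = a0 + a2 (x - x0)^2 + a4 (x - x0)^4`` fitted in the axial slab around
the occlusal plane, then resampled to equal arc length.  The panoramic
trajectory sweeps the arch station by station: at each station the central ray
runs along the outward arch normal, the source sits behind the arch (lingual
side) and the detector column in front (buccal side); detector rows form a
vertical fan from the source point.

The focal layer is sharp exactly on the arch curve.  A real
orthopantomograph's moving rotation center is not modeled; the normal-ray
sweep reproduces the projected-thickness semantics of the panoramic layer
without vendor kinematics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .volume import BONE, LabelVolume


@dataclass
class ArchCurve:
    """Planar arch curve at height ``z_arch``, with outward (buccal) normals."""

    points: np.ndarray        # (N, 2) mm, ordered left -> right
    normals: np.ndarray       # (N, 2) unit outward normals
    arc_length: np.ndarray    # (N,) cumulative arc length, strictly increasing
    z_arch: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("arch curve needs at least two planar points")
        if np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc length must be strictly increasing")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("normals must be unit length")

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1] - self.arc_length[0])


@dataclass
class TrajectoryConfig:
    n_columns: int = 700
    n_rows: int = 500
    source_to_arch_mm: float = 400.0
    arch_to_detector_mm: float = 100.0
    vertical_fov_mm: float = 120.0   # vertical field at the arch plane

    def __post_init__(self) -> None:
        if self.n_columns < 1 or self.n_rows < 1:
            raise ValueError("n_columns and n_rows must be >= 1")
        if self.source_to_arch_mm <= 0 or self.arch_to_detector_mm <= 0:
            raise ValueError("source-to-arch and arch-to-detector distances must be positive")
        if self.vertical_fov_mm <= 0:
            raise ValueError("vertical_fov_mm must be positive")

    @property
    def magnification_at_arch(self) -> float:
        """Size on the detector per size at the arch plane (similar triangles)."""
        d_sd = self.source_to_arch_mm + self.arch_to_detector_mm
        return d_sd / self.source_to_arch_mm

    @property
    def row_pitch_mm(self) -> float:
        """Detector row pitch so the rows span the vertical field at the arch."""
        return self.vertical_fov_mm * self.magnification_at_arch / self.n_rows


@dataclass
class PanoramicGeometry:
    """Per-column source points and per-(row, column) ray directions."""

    sources: np.ndarray        # (C, 3)
    arch_points: np.ndarray    # (C, 3)
    det_bases: np.ndarray      # (C, 3) detector column centers
    directions: np.ndarray     # (R, C, 3) unit ray directions source -> detector pixel
    row_pitch_mm: float
    config: TrajectoryConfig
    geometry_id: str = ""

    def __post_init__(self) -> None:
        if not self.geometry_id:
            h = hash((self.sources.tobytes(), self.det_bases.tobytes(), self.directions.shape))
            self.geometry_id = f"geom-{h & 0xFFFFFFFF:08x}"

    @property
    def n_columns(self) -> int:
        return self.sources.shape[0]

    @property
    def n_rows(self) -> int:
        return self.directions.shape[0]

    def to_json(self, path: str) -> None:
        doc = {
            "geometry_id": self.geometry_id,
            "n_columns": self.n_columns,
            "n_rows": self.n_rows,
            "row_pitch_mm": self.row_pitch_mm,
            "source_to_arch_mm": self.config.source_to_arch_mm,
            "arch_to_detector_mm": self.config.arch_to_detector_mm,
            "sources": self.sources.tolist(),
            "arch_points": self.arch_points.tolist(),
            "det_bases": self.det_bases.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def detect_occlusal_plane(labels: LabelVolume, z_window: tuple[float, float] | None = None) -> float:
    """z (mm) of the axial slice with the largest bone cross-section.

    ``z_window`` restricts the search to a jaw region; by default all slices
    are searched.
    """
    bone = labels.mask(BONE)
    if not bone.any():
        raise ValueError("no bone voxels in volume")
    z = labels.axis_coords(2)
    counts = bone.sum(axis=(0, 1))
    if z_window is not None:
        sel = (z >= z_window[0]) & (z <= z_window[1])
        if not sel.any():
            raise ValueError("z_window contains no slices")
        counts = np.where(sel, counts, -1)
    return float(z[int(np.argmax(counts))])


def fit_dental_arch(
    labels: LabelVolume,
    n_points: int = 400,
    slab_half_thickness_mm: float = 12.0,
    z_occlusal: float | None = None,
    z_window: tuple[float, float] | None = None,
    min_support: int = 8,
) -> ArchCurve:
    """Fit the symmetric quartic dental arch to the bone labels.

    Bone occupancy in the axial slab around the occlusal plane (auto-detected
    as the z of maximum bone cross-section unless given) is collapsed along z;
    for every x column the bone centroid in y provides one support point, and
    the even quartic is fitted about the bone center of mass.  The curve is
    resampled to ``n_points`` equal arc-length stations with outward normals.
    """
    bone = labels.mask(BONE)
    if not bone.any():
        raise ValueError("no bone voxels in volume")
    if z_occlusal is None:
        z_occlusal = detect_occlusal_plane(labels, z_window)
    z = labels.axis_coords(2)
    slab = np.abs(z - z_occlusal) <= slab_half_thickness_mm
    occ = bone[:, :, slab].any(axis=2)          # (nx, ny)

    x = labels.axis_coords(0)
    y = labels.axis_coords(1)
    counts = occ.sum(axis=1)
    support = counts > 0
    if support.sum() < max(min_support, 3):
        raise ValueError(f"only {support.sum()} support columns; cannot fit a quartic")
    xs = x[support]
    ys = (occ[support] @ y) / counts[support]   # per-column bone centroid in y

    x0 = float(np.average(xs, weights=counts[support]))
    u = xs - x0
    basis = np.column_stack([np.ones_like(u), u**2, u**4])
    coeffs, *_ = np.linalg.lstsq(basis, ys, rcond=None)

    xmin, xmax = xs.min(), xs.max()
    return _quartic_arch((float(coeffs[0]), float(coeffs[1]), float(coeffs[2])), x0,
                         float(xmin), float(xmax), n_points, float(z_occlusal))


def _quartic_arch(
    coeffs: tuple[float, float, float],
    x0: float,
    xmin: float,
    xmax: float,
    n_points: int,
    z_arch: float,
) -> ArchCurve:
    """Equal arc-length sampling of ``y = a0 + a2 u^2 + a4 u^4`` (u = x - x0).

    Normals come from the analytic derivative, so they are exactly
    perpendicular to the curve tangent at every station.
    """
    a0, a2, a4 = coeffs
    xd = np.linspace(xmin, xmax, 8001)
    yd = a0 + a2 * (xd - x0) ** 2 + a4 * (xd - x0) ** 4
    seg = np.hypot(np.diff(xd), np.diff(yd))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    stations = np.linspace(0.0, s[-1], n_points)
    px = np.interp(stations, s, xd)
    py = a0 + a2 * (px - x0) ** 2 + a4 * (px - x0) ** 4

    dydx = 2 * a2 * (px - x0) + 4 * a4 * (px - x0) ** 3
    norm = np.hypot(1.0, dydx)
    # tangent (1, y') / |.|  ->  outward normal (-y', 1) / |.| (points to +y)
    normals = np.column_stack([-dydx / norm, 1.0 / norm])
    return ArchCurve(np.column_stack([px, py]), normals, stations, z_arch)


def arch_from_quartic(
    coeffs: tuple[float, float, float],
    half_span: float,
    z_arch: float,
    n_points: int = 400,
) -> ArchCurve:
    """Analytic arch from quartic coefficients (useful for symmetric phantoms)."""
    return _quartic_arch(tuple(float(c) for c in coeffs), 0.0,
                         -half_span, half_span, n_points, z_arch)


def build_trajectory(arch: ArchCurve, config: TrajectoryConfig | None = None) -> PanoramicGeometry:
    """Construct the panoramic sweep along the arch.

    ``C`` stations are placed at equal arc length; per station the source lies
    ``source_to_arch_mm`` behind the arch point along the inward normal and the
    detector column center ``arch_to_detector_mm`` in front.  Rows fan
    vertically from the source through detector pixels centered on the arch
    plane.  Column order (left to right along the arch) is image column order.
    """
    config = config or TrajectoryConfig()
    C, R = config.n_columns, config.n_rows
    stations = np.linspace(arch.arc_length[0], arch.arc_length[-1], C)
    px = np.interp(stations, arch.arc_length, arch.points[:, 0])
    py = np.interp(stations, arch.arc_length, arch.points[:, 1])
    nx = np.interp(stations, arch.arc_length, arch.normals[:, 0])
    ny = np.interp(stations, arch.arc_length, arch.normals[:, 1])
    nrm = np.sqrt(nx**2 + ny**2)
    nx, ny = nx / nrm, ny / nrm

    arch_pts = np.column_stack([px, py, np.full(C, arch.z_arch)])
    normal3 = np.column_stack([nx, ny, np.zeros(C)])
    sources = arch_pts - config.source_to_arch_mm * normal3
    det_bases = arch_pts + config.arch_to_detector_mm * normal3

    pitch = config.row_pitch_mm
    row_offsets = (np.arange(R) - (R - 1) / 2.0) * pitch
    det_pixels = det_bases[None, :, :].repeat(R, axis=0)
    det_pixels = det_pixels + row_offsets[:, None, None] * np.array([0.0, 0.0, 1.0])
    dirs = det_pixels - sources[None, :, :]
    dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)

    return PanoramicGeometry(
        sources=sources,
        arch_points=arch_pts,
        det_bases=det_bases,
        directions=dirs,
        row_pitch_mm=pitch,
        config=config,
    )
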