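"""Synthetic labeled head phantom generator.

The phantom emulates the structural classes a panoramic simulation pipeline
must handle: an ellipsoidal soft-tissue head, a U-shaped dental arch of bone
(mandibular and maxillary walls following the same quartic curve), individual
teeth with soft-tissue root canals sitting in the occlusal band between the
two jaw walls, and an air pocket behind the arch mimicking the pharynx /
tongue-palate gap.  It makes no claim to population anatomy — it provides
ground-truth labels so segmentation, arch fitting and projection are testable
without patient data.

The dental arch is the symmetric quartic ``y(x) = a0 + a2 x^2 + a4 x^4``
(head-centered coordinates, mm) swept vertically; teeth are placed at equal
arc-length intervals along it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .volume import AIR, BONE, SOFT, HUVolume, LabelVolume


@dataclass
class PhantomParams:
    """Geometry and intensity configuration of the synthetic head.

    All lengths in mm, all coordinates head-centered (the grid is centered on
    the origin).  HU assignments must satisfy air < soft < bone.
    """

    shape: tuple[int, int, int] = (160, 160, 120)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    head_semiaxes: tuple[float, float, float] = (70.0, 75.0, 55.0)
    # arch quartic y(x) = a0 + a2 x^2 + a4 x^4 over |x| <= arch_half_span
    arch_coeffs: tuple[float, float, float] = (35.0, -0.018, -6.0e-6)
    arch_half_span: float = 45.0
    arch_half_width: float = 3.0          # half thickness of the jaw bone wall
    mandible_z: tuple[float, float] = (-28.0, -8.0)
    maxilla_z: tuple[float, float] = (8.0, 28.0)
    tooth_count: int = 14
    tooth_radius: float = 4.0
    tooth_z: tuple[float, float] = (-8.0, 8.0)
    root_canal_radius: float = 1.0
    # pharynx-like air pocket behind the arch (axis-aligned box)
    air_gap_thickness: float = 12.0
    air_gap_half_width: float = 20.0
    air_gap_y_top: float = 15.0
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_bone: float = 1200.0
    hu_tooth: float = 1800.0
    jitter_sigma: float = 0.0             # Gaussian HU noise, 0 = noise free
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tooth_count < 0:
            raise ValueError("tooth_count must be >= 0")
        for name in ("spacing", "head_semiaxes"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} components must be positive")
        if not (self.hu_air < self.hu_soft < self.hu_bone):
            raise ValueError("HU ordering must satisfy air < soft < bone")
        if self.tooth_radius <= 0 or self.arch_half_width <= 0:
            raise ValueError("tooth_radius and arch_half_width must be positive")
        if not (0 <= self.root_canal_radius < self.tooth_radius):
            raise ValueError("root canal must fit strictly inside the tooth")
        if self.air_gap_thickness < 0:
            raise ValueError("air_gap_thickness must be >= 0")

    def arch_y(self, x: np.ndarray | float) -> np.ndarray | float:
        a0, a2, a4 = self.arch_coeffs
        return a0 + a2 * x**2 + a4 * x**4


def _arch_polyline(params: PhantomParams, n: int = 4001) -> np.ndarray:
    x = np.linspace(-params.arch_half_span, params.arch_half_span, n)
    return np.column_stack([x, params.arch_y(x)])


def arch_arc_length(params: PhantomParams) -> float:
    """Total arc length of the arch curve over its configured span."""
    pts = _arch_polyline(params)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def tooth_centers(params: PhantomParams) -> np.ndarray:
    """(x, y) centers of the teeth, equally spaced in arc length.

    Teeth are inset from the curve ends by half an inter-tooth spacing so the
    crowns stay on the tooth-bearing span.
    """
    if params.tooth_count == 0:
        return np.empty((0, 2))
    pts = _arch_polyline(params)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    step = total / params.tooth_count
    stations = (np.arange(params.tooth_count) + 0.5) * step
    cx = np.interp(stations, s, pts[:, 0])
    cy = np.interp(stations, s, pts[:, 1])
    return np.column_stack([cx, cy])


def generate_head_phantom(params: PhantomParams) -> tuple[HUVolume, LabelVolume]:
    """Build the paired HU volume and ground-truth label volume.

    Deterministic for a fixed ``params.seed``.  Raises if the configured head
    does not fit inside the grid's field of view.
    """
    nx, ny, nz = params.shape
    dx, dy, dz = params.spacing
    fov = (nx * dx / 2, ny * dy / 2, nz * dz / 2)
    if any(a >= f for a, f in zip(params.head_semiaxes, fov)):
        raise ValueError(
            f"head semi-axes {params.head_semiaxes} exceed the field of view half-extents {fov}"
        )

    # voxel-center coordinates, grid centered on the origin
    origin = tuple(-(n - 1) / 2 * s for n, s in zip(params.shape, params.spacing))
    x = origin[0] + dx * np.arange(nx)
    y = origin[1] + dy * np.arange(ny)
    z = origin[2] + dz * np.arange(nz)

    ax, ay, az = params.head_semiaxes
    head2d = (x[:, None] / ax) ** 2 + (y[None, :] / ay) ** 2      # (nx, ny)
    inside_head = head2d[:, :, None] + (z[None, None, :] / az) ** 2 <= 1.0

    labels = np.full(params.shape, AIR, dtype=np.int8)
    labels[inside_head] = SOFT
    tooth_mask = np.zeros(params.shape, dtype=bool)

    # in-plane distance of every (x, y) voxel column to the arch polyline
    pts = _arch_polyline(params)
    grid_xy = np.column_stack([np.repeat(x, ny), np.tile(y, nx)])
    dist2d = cKDTree(pts).query(grid_xy, workers=-1)[0].reshape(nx, ny)
    wall = dist2d <= params.arch_half_width

    zmask_mand = (z >= params.mandible_z[0]) & (z <= params.mandible_z[1])
    zmask_max = (z >= params.maxilla_z[0]) & (z <= params.maxilla_z[1])
    labels[wall[:, :, None] & zmask_mand[None, None, :]] = BONE
    labels[wall[:, :, None] & zmask_max[None, None, :]] = BONE

    zmask_tooth = (z >= params.tooth_z[0]) & (z <= params.tooth_z[1])
    for cx, cy in tooth_centers(params):
        r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
        crown = (r2 <= params.tooth_radius**2)[:, :, None] & zmask_tooth[None, None, :]
        labels[crown] = BONE
        tooth_mask |= crown
        if params.root_canal_radius > 0:
            canal = (r2 <= params.root_canal_radius**2)[:, :, None] & zmask_tooth[None, None, :]
            labels[canal] = SOFT
            tooth_mask &= ~canal

    if params.air_gap_thickness > 0:
        gap = (
            (np.abs(x)[:, None, None] <= params.air_gap_half_width)
            & (y[None, :, None] <= params.air_gap_y_top)
            & (y[None, :, None] >= params.air_gap_y_top - params.air_gap_thickness)
            & zmask_tooth[None, None, :]
        )
        labels[gap] = AIR
        tooth_mask &= ~gap

    hu = np.full(params.shape, params.hu_air, dtype=np.float32)
    hu[labels == SOFT] = params.hu_soft
    hu[labels == BONE] = params.hu_bone
    hu[tooth_mask] = params.hu_tooth
    if params.jitter_sigma > 0:
        rng = np.random.default_rng(params.seed)
        hu = hu + rng.normal(0.0, params.jitter_sigma, size=hu.shape).astype(np.float32)

    hu_vol = HUVolume(hu, params.spacing, origin)
    label_vol = LabelVolume(labels, params.spacing, origin, ground_truth=True)
    return hu_vol, label_vol


def analytic_label_volumes(params: PhantomParams) -> dict[int, float]:
    """Closed-form volumes (mm^3) of each label class of the phantom.

    Used as an independent check on the voxelization:

    * BONE = two swept jaw walls (arc length x thickness x height, plus the
      semicircular end caps) + tooth annuli (crown minus root canal);
    * internal AIR = the pharynx box; total AIR adds the space outside the
      head ellipsoid;
    * SOFT = head ellipsoid minus bone minus the pharynx box.
    """
    L = arch_arc_length(params)
    w = params.arch_half_width
    h_mand = params.mandible_z[1] - params.mandible_z[0]
    h_max = params.maxilla_z[1] - params.maxilla_z[0]
    wall_area = L * 2 * w + np.pi * w**2            # stadium footprint of one wall
    v_walls = wall_area * (h_mand + h_max)
    h_tooth = params.tooth_z[1] - params.tooth_z[0]
    v_teeth = params.tooth_count * np.pi * (params.tooth_radius**2 - params.root_canal_radius**2) * h_tooth
    v_bone = v_walls + v_teeth

    # root canals stay SOFT, so only the annular crown volume leaves SOFT
    v_gap = 2 * params.air_gap_half_width * params.air_gap_thickness * h_tooth
    ax, ay, az = params.head_semiaxes
    v_head = 4.0 / 3.0 * np.pi * ax * ay * az
    v_soft = v_head - v_walls - v_teeth - v_gap

    nx, ny, nz = params.shape
    v_total = nx * ny * nz * np.prod(params.spacing)
    v_air = v_total - v_head + v_gap
    return {AIR: v_air, SOFT: v_soft, BONE: v_bone}
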