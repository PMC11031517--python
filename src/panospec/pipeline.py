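"""End-to-end simulation: HU volume -> five spectral panoramic images.

Chains segmentation, arch fitting, trajectory construction, forward
projection and spectral synthesis, mirroring the three-step workflow of
panoramic simulation from CT: (1) define the arch and the source/detector
sweep, (2) segment and forward project to material thickness images,
(3) synthesize the conventional and virtual monoenergetic images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ArchCurve, PanoramicGeometry, TrajectoryConfig, build_trajectory, fit_dental_arch
from .projector import MaterialThicknessImage, project_thicknesses
from .segmentation import SegmentationConfig, segment
from .spectral import (
    AttenuationTable,
    MonoImage,
    PanImage,
    Spectrum,
    synthesize_pan,
    synthesize_pvmi,
    tungsten_spectrum,
)
from .volume import BONE, SOFT, HUVolume, LabelVolume


@dataclass
class SimulationResult:
    labels: LabelVolume
    arch: ArchCurve
    geometry: PanoramicGeometry
    peti_bone: MaterialThicknessImage
    peti_soft: MaterialThicknessImage
    pan: PanImage
    pvmi: dict[float, MonoImage]


def simulate(
    volume: HUVolume,
    seg_config: SegmentationConfig | None = None,
    traj_config: TrajectoryConfig | None = None,
    spectrum: Spectrum | None = None,
    mono_energies_kev: tuple[float, ...] = (40.0, 60.0),
    labels: LabelVolume | None = None,
    arch: ArchCurve | None = None,
) -> SimulationResult:
    """Run the full simulation on an HU volume.

    ``labels`` and ``arch`` may be supplied to skip segmentation or arch
    fitting (e.g. ground-truth phantom labels or an analytic arch).  The
    default evaluation energies 40 and 60 keV are the usual presets for
    virtual monoenergetic review.
    """
    if labels is None:
        labels = segment(volume, seg_config or SegmentationConfig())
    if arch is None:
        arch = fit_dental_arch(labels)
    geometry = build_trajectory(arch, traj_config or TrajectoryConfig())
    thicknesses = project_thicknesses(labels, geometry)
    t_b, t_s = thicknesses[BONE], thicknesses[SOFT]
    spectrum = spectrum or tungsten_spectrum(kvp=120.0)
    tables = AttenuationTable()
    pan = synthesize_pan(t_b, t_s, spectrum, tables)
    pvmi = {e: synthesize_pvmi(t_b, t_s, e, tables) for e in mono_energies_kev}
    return SimulationResult(labels, arch, geometry, t_b, t_s, pan, pvmi)
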