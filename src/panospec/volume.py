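"""Voxel volume containers and NIfTI/DICOM I/O.

Conventions used throughout the package:

* array axis order is ``(x, y, z)`` with 0-based indices;
* patient-like axes: x = left-right, y = posterior-anterior, z = inferior-superior;
* ``spacing`` is the voxel pitch in mm, ``origin`` is the world position (mm)
  of the *center* of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

# material label alphabet
AIR = 0
SOFT = 1
BONE = 2
LABEL_NAMES = {AIR: "air", SOFT: "soft", BONE: "bone"}


def _check_grid(voxels: np.ndarray, spacing, origin) -> None:
    if voxels.ndim != 3 or voxels.size == 0:
        raise ValueError("voxel grid must be a non-empty 3-D array")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive values, got {spacing}")
    if len(origin) != 3:
        raise ValueError("origin must have three components")


@dataclass
class HUVolume:
    """A CT volume in Hounsfield units with physical voxel geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        _check_grid(self.voxels, self.spacing, self.origin)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


@dataclass
class LabelVolume:
    """A three-class material map (AIR / SOFT / BONE) on a voxel grid."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ground_truth: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer valued")
        self.labels = self.labels.astype(np.int8, copy=False)
        _check_grid(self.labels, self.spacing, self.origin)
        present = np.unique(self.labels)
        if not np.isin(present, [AIR, SOFT, BONE]).all():
            raise ValueError(f"labels must be in {{AIR={AIR}, SOFT={SOFT}, BONE={BONE}}}, found {present}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.labels.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


# --------------------------------------------------------------------------
# NIfTI read/write

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: HUVolume | LabelVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 (.nii / .nii.gz).

    HU volumes are stored as float32, label volumes as int16 so that the
    integer labels round-trip exactly.
    """
    import nibabel as nib

    path = os.fspath(path)
    if not (path.endswith(".nii") or path.endswith(".nii.gz")):
        raise ValueError("output path must end in .nii or .nii.gz")
    if isinstance(volume, LabelVolume):
        data = volume.labels.astype(np.int16)
    else:
        data = volume.voxels.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)


def _read_nifti(path: str):
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    # the NIfTI-1 header stores geometry as float32; round to nanometer
    # precision so written spacings like 0.67 mm round-trip exactly
    zooms = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    origin = tuple(round(float(v), 6) for v in img.affine[:3, 3])
    return data, zooms, origin


def load_volume(path: str | os.PathLike) -> HUVolume:
    """Load a NIfTI file or a DICOM series directory as an HU volume.

    For DICOM series, RescaleSlope/RescaleIntercept are applied and slice
    geometry is validated (consistent orientation, uniform slice spacing).
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        return _load_dicom_series(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data, zooms, origin = _read_nifti(path)
    return HUVolume(np.asarray(data, dtype=np.float32), zooms, origin)


def load_label_volume(path: str | os.PathLike) -> LabelVolume:
    """Load a NIfTI label volume written by :func:`write_volume`."""
    data, zooms, origin = _read_nifti(os.fspath(path))
    return LabelVolume(np.asarray(data).astype(np.int8), zooms, origin)


def _load_dicom_series(directory: str) -> HUVolume:
    import pydicom

    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {directory}")

    orientations = {tuple(round(float(v), 6) for v in ds.ImageOrientationPatient) for ds in slices}
    if len(orientations) != 1:
        raise ValueError("DICOM series has mixed slice orientations; refusing to reorder silently")
    iop = np.array(slices[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(iop[:3], iop[3:])
    pos = np.array([np.dot(normal, np.array(ds.ImagePositionPatient, dtype=float)) for ds in slices])
    order = np.argsort(pos)
    slices = [slices[i] for i in order]
    pos = pos[order]

    if len(slices) > 1:
        steps = np.diff(pos)
        if steps.min() <= 0:
            raise ValueError("duplicate or non-increasing DICOM slice positions")
        if (steps.max() - steps.min()) > 0.01 * steps.mean():
            raise ValueError("inconsistent DICOM slice spacing")
        dz = float(steps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    first = slices[0]
    if not hasattr(first, "RescaleSlope") or not hasattr(first, "RescaleIntercept"):
        raise ValueError("DICOM series lacks RescaleSlope/RescaleIntercept; cannot convert to HU")
    rows_px, cols_px = int(first.Rows), int(first.Columns)
    stack = np.empty((cols_px, rows_px, len(slices)), dtype=np.float32)
    for k, ds in enumerate(slices):
        arr = ds.pixel_array.astype(np.float32)
        hu = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        # pixel_array is (row, col) = (y, x); transpose to (x, y)
        stack[:, :, k] = hu.T
    dy, dx = (float(v) for v in first.PixelSpacing)  # PixelSpacing is (row, col)
    ipp = np.array(first.ImagePositionPatient, dtype=float)
    return HUVolume(stack, (dx, dy, dz), tuple(ipp))
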