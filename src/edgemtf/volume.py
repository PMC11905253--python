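"""Calibrated CT volumes: DICOM series I/O and geometric cropping.

A :class:`CTVolume` is a 3-D grid of Hounsfield units with physical
spacing, an origin and patient-axis directions following the DICOM LPS
convention (+x left, +y posterior, +z superior).  The voxel array is
indexed ``voxels[i, j, k]`` with ``i`` along the image column direction
(x), ``j`` along the row direction (y) and ``k`` along the slice stack
(z); voxel coordinates refer to voxel centers.

Two cropping rules are applied before any surface extraction:

* a fixed margin (default 10 mm) is removed at both longitudinal ends so
  sampling lines never run out of out-of-plane support, and
* everything posterior of a horizontal plane 50 pixels below the volume
  center is treated as CT table and excluded (the plane offset is
  pixel-scaled: 50 x s_x mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import VolumeError

AIR_HU = -1000.0


@dataclass
class CTVolume:
    """A physically calibrated HU voxel grid.

    Parameters
    ----------
    voxels
        ``(nx, ny, nz)`` array of intensities in HU.
    spacing
        ``(s_x, s_y, s_z)`` voxel pitch in mm.
    origin
        Patient-space (LPS) position of voxel ``(0, 0, 0)`` in mm.
    axes
        3x3 matrix whose columns are the patient-space directions of the
        three array axes.  Identity means array x/y/z == patient L/P/S.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if self.voxels.ndim != 3:
            raise VolumeError("voxel array must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise VolumeError("all spacing components must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Patient-space position (mm) of voxel-center index ``idx``."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx * np.asarray(self.spacing)) @ self.axes.T

    def mm_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Continuous voxel index of patient-space position ``pos`` (mm)."""
        pos = np.asarray(pos, dtype=float)
        return ((pos - self.origin) @ self.axes) / np.asarray(self.spacing)


def _slice_geometry(ds) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    try:
        iop = np.asarray([float(v) for v in ds.ImageOrientationPatient])
        ipp = np.asarray([float(v) for v in ds.ImagePositionPatient])
    except AttributeError as exc:
        raise VolumeError("orientation unknown") from exc
    col_dir, row_dir = iop[:3], iop[3:]
    return col_dir, row_dir, ipp


def read_dicom_series(path: str | Path) -> CTVolume:
    """Read one axial CT series from a directory into a :class:`CTVolume`.

    Slices are ordered by the projection of their position onto the
    slice-normal direction (robust to export order); HU rescale is
    applied from the RescaleSlope/RescaleIntercept tags.

    Raises
    ------
    VolumeError
        ``"mixed series"`` for more than one SeriesInstanceUID,
        ``"irregular spacing"`` when inter-slice gaps deviate by >1%,
        ``"uncalibrated pixels"`` when rescale tags are missing.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:
            continue
    if len(datasets) < 3:
        raise VolumeError("need at least 3 DICOM slices")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise VolumeError("mixed series")

    col_dir, row_dir, _ = _slice_geometry(datasets[0])
    normal = np.cross(col_dir, row_dir)
    positions = [float(np.dot(_slice_geometry(ds)[2], normal)) for ds in datasets]
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    gaps = np.diff(positions)
    if np.any(gaps <= 0):
        raise VolumeError("irregular spacing")
    mean_gap = float(np.mean(gaps))
    if np.any(np.abs(gaps - mean_gap) > 0.01 * mean_gap):
        raise VolumeError("irregular spacing")

    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise VolumeError("uncalibrated pixels")

    row_spacing, col_spacing = (float(v) for v in datasets[0].PixelSpacing)
    spacing = (col_spacing, row_spacing, mean_gap)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        arr = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        # pixel_array is (rows, cols) = (y, x); store as (x, y)
        slices.append(arr.T)
    voxels = np.stack(slices, axis=-1)

    axes = np.column_stack([col_dir, row_dir, normal])
    origin = _slice_geometry(datasets[0])[2]
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin, axes=axes)


def write_dicom_series(vol: CTVolume, path: str | Path) -> list[Path]:
    """Write ``vol`` as one CT DICOM file per slice; returns the paths.

    Values are stored as signed 16-bit with slope 1 / intercept -1024,
    so integer-valued HU volumes round-trip bit-identically.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    nx, ny, nz = vol.dims
    intercept = -1024.0
    written = []
    for k in range(nz):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = list(vol.axes[:, 0]) + list(vol.axes[:, 1])
        ds.ImagePositionPatient = list(vol.index_to_mm([0, 0, k]))
        ds.PixelSpacing = [vol.spacing[1], vol.spacing[0]]  # row, col
        ds.SliceThickness = vol.spacing[2]
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.RescaleType = "HU"
        stored = np.rint(vol.voxels[:, :, k] - intercept).astype(np.int16)
        ds.PixelData = np.ascontiguousarray(stored.T).tobytes()  # (rows, cols)
        out = path / f"slice_{k:04d}.dcm"
        pydicom.dcmwrite(out, ds, enforce_file_format=True)
        written.append(out)
    return written


def crop_longitudinal(vol: CTVolume, margin_mm: float = 10.0) -> CTVolume:
    """Remove ``ceil(margin_mm / s_z)`` slices from each longitudinal end."""
    if margin_mm < 0:
        raise VolumeError("margin must be non-negative")
    n = math.ceil(margin_mm / vol.spacing[2])
    nz = vol.dims[2]
    if n == 0:
        return replace(vol, voxels=vol.voxels.copy())
    if 2 * n >= nz:
        raise VolumeError("volume exhausted by crop")
    new_origin = vol.index_to_mm([0, 0, n])
    return CTVolume(
        voxels=vol.voxels[:, :, n : nz - n].copy(),
        spacing=vol.spacing,
        origin=new_origin,
        axes=vol.axes,
    )


def table_plane_offset_mm(vol: CTVolume, distance_pixels: int = 50) -> float:
    """Posterior offset of the table-crop plane from the volume center.

    The plane sits ``distance_pixels`` x s_x mm posterior of the center
    (pixel-scaled; 0.977 mm pixels put it at 48.85 mm).
    """
    return distance_pixels * vol.spacing[0]


def table_keep_mask(vol: CTVolume, distance_pixels: int = 50) -> np.ndarray:
    """Boolean array, True for voxels anterior of the table-crop plane.

    Posterior is the patient +y direction; the array axis most aligned
    with it is found from ``vol.axes`` so flipped exports behave.
    """
    post = np.array([0.0, 1.0, 0.0])
    align = vol.axes.T @ post  # alignment of each array axis with +y
    ax = int(np.argmax(np.abs(align)))
    sign = 1.0 if align[ax] > 0 else -1.0
    if abs(align[ax]) < 0.9:
        raise VolumeError("orientation unknown")
    n = vol.dims[ax]
    center = (n - 1) / 2.0
    offset_vox = table_plane_offset_mm(vol, distance_pixels) / vol.spacing[ax]
    idx = np.arange(n)
    keep_1d = sign * (idx - center) <= offset_vox
    shape = [1, 1, 1]
    shape[ax] = n
    return np.broadcast_to(keep_1d.reshape(shape), vol.dims).copy()


def crop_table(vol: CTVolume, distance_pixels: int = 50) -> CTVolume:
    """Set every voxel posterior of the table-crop plane to air (-1000 HU).

    The segmentation path uses :func:`table_keep_mask` on the binary mask
    instead (geometry-preserving); this voxel-level form is provided for
    direct inspection and the spec'd volume interface.
    """
    keep = table_keep_mask(vol, distance_pixels)
    voxels = vol.voxels.copy()
    voxels[~keep] = AIR_HU
    return replace(vol, voxels=voxels)
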