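"""Reading and writing CT volumes and binary masks.

All of vesselseg uses a single in-memory convention:

* voxel arrays are indexed ``(z, row, column)`` with axial slices stacked
  along ``z``, ordered inferior -> superior;
* ``spacing`` is the physical voxel size ``(row_mm, column_mm, slice_mm)``,
  strictly positive;
* CT intensities are Hounsfield units, clamped to ``[-1024, 3071]`` on read;
* masks hold exactly the values 0 and 1.

The only places where on-disk axis orders or stored-value scalings exist are
the functions in this module: DICOM series directories (read/write, used for
synthetic fixtures) and NIfTI-1 files (read/write).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

HU_MIN = -1024.0
HU_MAX = 3071.0

MASK_LABELS = ("spine", "lumen", "thrombus")


class GeometryError(ValueError):
    """Missing or contradictory image geometry; never silently defaulted."""


@dataclass
class CTVolume:
    """A 3D CT scalar field in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, rows, columns)
        HU values, axial slices stacked along axis 0 (inferior -> superior).
    spacing : tuple of float
        Physical voxel size ``(row_mm, column_mm, slice_mm)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D voxel array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]

    def slices(self) -> Iterator[np.ndarray]:
        yield from self.voxels

    def copy(self) -> "CTVolume":
        return CTVolume(self.voxels.copy(), self.spacing)


@dataclass
class BinaryMask3D:
    """A {0,1} label field on the same grid as its companion CTVolume."""

    voxels: np.ndarray
    label: str
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask array, got ndim={arr.ndim}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be exactly 0/1, found {vals[:10]}")
        self.voxels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def same_grid(self, other) -> bool:
        return self.voxels.shape == other.voxels.shape

    def copy(self) -> "BinaryMask3D":
        return BinaryMask3D(self.voxels.copy(), self.label, self.spacing)


def _clamp_hu(arr: np.ndarray) -> np.ndarray:
    return np.clip(arr, HU_MIN, HU_MAX)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def read_dicom_series(directory: os.PathLike | str) -> CTVolume:
    """Read a single-frame axial CT series from *directory* into a CTVolume.

    Slices are sorted by physical position along the slice axis (Image
    Position (Patient) z), regardless of on-disk file order, and the rescale
    slope/intercept is applied so voxels are in HU.

    Raises
    ------
    GeometryError
        If the directory mixes series, or pixel / slice spacing cannot be
        determined from the metadata (there is no silent 1 mm default).
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in paths:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise GeometryError(f"no DICOM images found in {directory}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise GeometryError(f"directory mixes multiple series: {sorted(uids)}")

    def z_pos(ds: Dataset) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is None:
            raise GeometryError("slice lacks ImagePositionPatient; cannot sort by position")
        return float(ipp[2])

    datasets.sort(key=z_pos)

    first = datasets[0]
    ps = getattr(first, "PixelSpacing", None)
    if ps is None:
        raise GeometryError("series lacks PixelSpacing; refusing to guess")
    row_mm, col_mm = float(ps[0]), float(ps[1])

    if len(datasets) >= 2:
        zs = np.array([z_pos(ds) for ds in datasets])
        dz = np.diff(zs)
        slice_mm = float(np.median(np.abs(dz)))
        if slice_mm <= 0:
            raise GeometryError("duplicate slice positions; slice spacing undefined")
    else:
        st = getattr(first, "SliceThickness", None)
        if st is None:
            raise GeometryError("single-slice series lacks SliceThickness; refusing to guess")
        slice_mm = float(st)

    slices = []
    shape = None
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise GeometryError(f"inconsistent slice shapes {shape} vs {arr.shape}")
        slices.append(arr)

    voxels = _clamp_hu(np.stack(slices, axis=0)).astype(np.float32)
    return CTVolume(voxels, (row_mm, col_mm, slice_mm))


def write_dicom_series(volume: CTVolume, directory: os.PathLike | str,
                       intercept: float = -1024.0, slope: float = 1.0) -> Path:
    """Write *volume* as a minimal single-frame CT DICOM series.

    Intended for synthetic data; stores ``round((HU - intercept) / slope)``
    as unsigned 16-bit integers with the rescale tags set accordingly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    row_mm, col_mm, slice_mm = volume.spacing
    for i, sl in enumerate(volume.voxels):
        stored = np.round((sl.astype(np.float64) - intercept) / slope)
        stored = np.clip(stored, 0, 65535).astype(np.uint16)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * slice_mm]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [row_mm, col_mm]
        ds.SliceThickness = slice_mm
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.Rows, ds.Columns = sl.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.tobytes()
        ds.save_as(directory / f"slice_{i:04d}.dcm", enforce_file_format=True)
    return directory


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _nifti_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    row_mm, col_mm, slice_mm = spacing
    # on-disk axes (i, j, k) = (column, row, slice)
    return np.diag([col_mm, row_mm, slice_mm, 1.0])


def write_nifti(obj: CTVolume | BinaryMask3D, path: os.PathLike | str) -> Path:
    """Write a volume (float32) or mask (uint8) to a NIfTI-1 file."""
    path = Path(path)
    if isinstance(obj, BinaryMask3D):
        data = obj.voxels.astype(np.uint8)
    elif isinstance(obj, CTVolume):
        data = obj.voxels.astype(np.float32)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    # (z, row, col) -> (col, row, z)
    data_disk = np.transpose(data, (2, 1, 0))
    img = nib.Nifti1Image(data_disk, _nifti_affine(obj.spacing))
    img.header.set_zooms(tuple(np.abs(np.diag(_nifti_affine(obj.spacing))[:3])))
    nib.save(img, str(path))
    return path


def _load_nifti(path: os.PathLike | str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D single-channel image, got shape {img.shape}")
    data_disk = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    # header zooms are float32; round to 1e-6 mm so written spacings
    # round-trip to the exact Python floats they came from
    col_mm, row_mm, slice_mm = (round(float(z), 6) for z in zooms)
    if min(col_mm, row_mm, slice_mm) <= 0:
        raise GeometryError(f"non-positive zooms in {path}: {zooms}")
    data = np.transpose(data_disk, (2, 1, 0))
    return data, (row_mm, col_mm, slice_mm)


def read_nifti(path: os.PathLike | str) -> CTVolume:
    """Read a 3D NIfTI file as a CTVolume (values clamped to the HU range)."""
    data, spacing = _load_nifti(path)
    return CTVolume(_clamp_hu(data.astype(np.float32)), spacing)


def read_nifti_mask(path: os.PathLike | str, label: str) -> BinaryMask3D:
    """Read a 3D NIfTI file as a BinaryMask3D with the given label."""
    data, spacing = _load_nifti(path)
    return BinaryMask3D(data, label, spacing)
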