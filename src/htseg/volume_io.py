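"""Reading and writing head-CT volumes and binary lesion masks.

Volumes are held as :class:`CTVolume` objects: a 3-D ``float32`` grid of
Hounsfield Units (HU) in ``(z, y, x)`` axis order together with voxel
spacing in millimetres.  DICOM series are calibrated to HU at read time
(rescale slope/intercept applied); NIfTI is used as the on-disk format
for derived volumes and masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

__all__ = [
    "CTVolume",
    "BinaryMask",
    "FormatError",
    "GeometryError",
    "read_dicom_series",
    "read_nifti",
    "write_volume_nifti",
    "write_mask_nifti",
    "read_mask_nifti",
    "mask_volume_ml",
]


class FormatError(ValueError):
    """A file or series violates the expected format."""


class GeometryError(ValueError):
    """Series or affine geometry is inconsistent or unsupported."""


@dataclass(frozen=True)
class CTVolume:
    """A 3-D CT volume in Hounsfield Units.

    Attributes
    ----------
    voxels:
        ``float32`` array indexed ``[z, y, x]`` (slice, row, column).
    spacing:
        Voxel edge lengths ``(z, y, x)`` in mm; all strictly positive.
    origin:
        Physical position of voxel ``(0, 0, 0)`` in mm.
    case_id:
        Opaque identifier carried through the pipeline.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    case_id: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float32)
        if vox.ndim != 3:
            raise FormatError(f"expected 3-D voxel grid, got ndim={vox.ndim}")
        if not np.all(np.isfinite(vox)):
            raise FormatError("non-finite HU values in volume")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        """Copy of this volume with a new voxel grid on the same geometry."""
        return replace(self, voxels=voxels)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean grid aligned voxel-for-voxel with a :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels).astype(bool)
        if vox.ndim != 3:
            raise FormatError(f"expected 3-D mask, got ndim={vox.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    @classmethod
    def like(cls, vol: CTVolume, voxels: np.ndarray) -> "BinaryMask":
        if voxels.shape != vol.shape:
            raise GeometryError(f"mask shape {voxels.shape} != volume shape {vol.shape}")
        return cls(voxels=voxels, spacing=vol.spacing, origin=vol.origin)


# ---------------------------------------------------------------------------
# DICOM


def read_dicom_series(directory: str | Path, slice_gap_tol: float = 0.10) -> CTVolume:
    """Read a single axial DICOM series into an HU-calibrated :class:`CTVolume`.

    Slices are sorted by ascending physical z; the stored values are mapped
    to HU via each slice's RescaleSlope/RescaleIntercept.  The directory
    must contain exactly one series with a consistent orientation and
    in-plane geometry.

    Parameters
    ----------
    directory:
        Directory holding the ``.dcm`` files of one series.
    slice_gap_tol:
        Maximum relative deviation of any inter-slice gap from the median
        gap before a :class:`GeometryError` is raised.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() == ".dcm")
    if not paths:
        paths = sorted(p for p in directory.iterdir() if p.is_file())
    if not paths:
        raise FormatError(f"no DICOM files found in {directory}")

    datasets = [pydicom.dcmread(str(p)) for p in paths]

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise FormatError(f"directory mixes {len(uids)} series (SeriesInstanceUID)")
    for attr in ("ImagePositionPatient", "PixelSpacing", "Rows", "Columns"):
        if any(not hasattr(ds, attr) for ds in datasets):
            raise FormatError(f"missing required attribute {attr}")
    orientations = {tuple(round(float(v), 4) for v in ds.ImageOrientationPatient) for ds in datasets}
    if len(orientations) != 1:
        raise FormatError("inconsistent ImageOrientationPatient across slices")
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise FormatError("inconsistent Rows/Columns across slices")

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])

    if len(datasets) > 1:
        gaps = np.diff(zs)
        if np.any(gaps <= 0):
            raise GeometryError("duplicate or non-increasing slice positions")
        med = float(np.median(gaps))
        if np.any(np.abs(gaps - med) > slice_gap_tol * med):
            raise GeometryError(
                f"non-uniform slice gaps (median {med:.3f} mm, range "
                f"{gaps.min():.3f}-{gaps.max():.3f} mm) beyond {slice_gap_tol:.0%} tolerance"
            )
        dz = med
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    dy, dx = (float(v) for v in datasets[0].PixelSpacing)  # PixelSpacing is (row, col)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    vox = np.stack(slices, axis=0)

    ipp = datasets[0].ImagePositionPatient
    origin = (float(ipp[2]), float(ipp[1]), float(ipp[0]))
    return CTVolume(voxels=vox, spacing=(dz, dy, dx), origin=origin, case_id=directory.name)


# ---------------------------------------------------------------------------
# NIfTI

_SHEAR_TOL = 1e-3


def _affine_to_geometry(affine: np.ndarray, shape_xyz) -> tuple[tuple, tuple]:
    """Extract (z, y, x) spacing and origin from a NIfTI affine.

    Rejects affines with shear: each world axis must be carried by a
    single voxel axis.
    """
    rot = affine[:3, :3]
    spacing_xyz = np.sqrt((rot**2).sum(axis=0))
    if np.any(spacing_xyz <= 0):
        raise GeometryError("degenerate affine with zero-length axis")
    # off-diagonal mass after normalising columns
    direction = rot / spacing_xyz
    if np.abs(np.abs(direction) - np.eye(3)).max() > _SHEAR_TOL:
        raise GeometryError("affine has shear/oblique rotation above tolerance; not supported")
    spacing = (float(spacing_xyz[2]), float(spacing_xyz[1]), float(spacing_xyz[0]))
    origin = (float(affine[2, 3]), float(affine[1, 3]), float(affine[0, 3]))
    return spacing, origin


def _geometry_to_affine(spacing: tuple, origin: tuple) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0] = spacing[2]
    affine[1, 1] = spacing[1]
    affine[2, 2] = spacing[0]
    affine[0, 3] = origin[2]
    affine[1, 3] = origin[1]
    affine[2, 3] = origin[0]
    return affine


def read_nifti(path: str | Path) -> CTVolume:
    """Read a NIfTI volume; data axes are reordered to (z, y, x)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected 3-D NIfTI, got ndim={data.ndim}")
    spacing, origin = _affine_to_geometry(img.affine, data.shape)
    vox = np.transpose(data, (2, 1, 0)).astype(np.float32)  # nibabel is (x, y, z)
    return CTVolume(voxels=vox, spacing=spacing, origin=origin, case_id=path.stem)


def write_volume_nifti(vol: CTVolume, path: str | Path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    data = np.transpose(vol.voxels, (2, 1, 0)).astype(np.float32)
    img = nib.Nifti1Image(data, _geometry_to_affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def write_mask_nifti(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as unsigned 8-bit {0, 1} NIfTI."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    data = np.transpose(mask.voxels.astype(np.uint8), (2, 1, 0))
    img = nib.Nifti1Image(data, _geometry_to_affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


def read_mask_nifti(path: str | Path) -> BinaryMask:
    vol = read_nifti(path)
    return BinaryMask(voxels=vol.voxels > 0.5, spacing=vol.spacing, origin=vol.origin)


# ---------------------------------------------------------------------------
# Volume quantification


def mask_volume_ml(mask: BinaryMask) -> float:
    """Physical volume of the true voxels in millilitres.

    One voxel occupies ``dz * dy * dx`` mm^3; 1 mL = 1000 mm^3.
    """
    dz, dy, dx = mask.spacing
    if dz <= 0 or dy <= 0 or dx <= 0:
        raise GeometryError(f"invalid spacing {mask.spacing}")
    return mask.count() * dz * dy * dx / 1000.0


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
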