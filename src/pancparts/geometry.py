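"""Core volume containers and NIfTI / DICOM geometry plumbing.

All containers pair a voxel array with its grid geometry: a per-axis
``spacing`` in mm and a 4x4 ``affine`` mapping 0-based voxel indices
(voxel-center convention) to world (scanner) coordinates in mm.  The affine
is authoritative for the world mapping; ``spacing`` is used for voxel
volumes and anisotropy-aware distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .exceptions import DimensionalityError, GeometryError, GridError

__all__ = [
    "BinaryMask3D",
    "PartsLabelMap",
    "ProbabilisticTemplate",
    "PDFFSlice",
    "Plane3D",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
    "read_template",
    "write_template",
    "read_pdff_slice",
    "read_pdff_dicom",
    "check_partition",
    "grids_match",
]

#: Part label semantics shared across the package.
LABEL_HEAD, LABEL_BODY, LABEL_TAIL = 1, 2, 3
PART_NAMES = {LABEL_HEAD: "head", LABEL_BODY: "body", LABEL_TAIL: "tail"}


def _validate_geometry(spacing, affine):
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise GeometryError(f"spacing must be 3 strictly positive values, got {spacing}")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got shape {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("affine is not invertible")
    return spacing, affine


@dataclass
class BinaryMask3D:
    """A whole-organ binary segmentation on a 3D voxel grid."""

    voxels: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DimensionalityError(f"expected a 3D volume, got {self.voxels.ndim}D")
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be exactly 0 or 1, found {vals[:10]}")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing, self.affine = _validate_geometry(self.spacing, self.affine)

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n,3) voxel indices to (n,3) world mm through the affine."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def foreground_world(self) -> np.ndarray:
        """World coordinates (mm) of all foreground voxel centers, (n,3)."""
        return self.voxel_to_world(np.argwhere(self.voxels > 0))

    def centroid_world(self) -> np.ndarray:
        if self.n_foreground == 0:
            raise ValueError("centroid of an empty mask is undefined")
        return self.foreground_world().mean(axis=0)

    def copy(self) -> "BinaryMask3D":
        return BinaryMask3D(self.voxels.copy(), self.spacing.copy(), self.affine.copy())


@dataclass
class PartsLabelMap:
    """Head/body/tail label volume: 0 background, 1 head, 2 body, 3 tail."""

    labels: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError(f"expected a 3D volume, got {self.labels.ndim}D")
        vals = np.unique(self.labels)
        if not np.all(np.isin(vals, (0, 1, 2, 3))):
            raise ValueError(f"labels must be within {{0,1,2,3}}, found {vals[:10]}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing, self.affine = _validate_geometry(self.spacing, self.affine)

    @property
    def shape(self):
        return self.labels.shape

    def part_mask(self, label: int) -> BinaryMask3D:
        """Extract one part as a binary mask on the same grid."""
        return BinaryMask3D((self.labels == label).astype(np.uint8),
                            self.spacing.copy(), self.affine.copy())

    def as_mask(self) -> BinaryMask3D:
        """Union of all parts as a whole-organ mask."""
        return BinaryMask3D((self.labels > 0).astype(np.uint8),
                            self.spacing.copy(), self.affine.copy())

    def copy(self) -> "PartsLabelMap":
        return PartsLabelMap(self.labels.copy(), self.spacing.copy(), self.affine.copy())


@dataclass
class ProbabilisticTemplate:
    """Population-average shape: per-voxel foreground frequency in [0, 1]."""

    values: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise DimensionalityError(f"expected a 3D volume, got {self.values.ndim}D")
        if self.values.size and (self.values.min() < -1e-6 or self.values.max() > 1 + 1e-6):
            raise ValueError("template values must lie within [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)
        self.spacing, self.affine = _validate_geometry(self.spacing, self.affine)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class PDFFSlice:
    """2D proton-density fat-fraction map (percent) with scanner geometry.

    ``values[i, j]`` maps to world mm through ``affine @ (i, j, 0, 1)``.
    Non-finite entries are treated as missing.  ``spacing`` holds the two
    in-plane pixel sizes followed by the slice thickness.
    """

    values: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionalityError(f"expected a 2D map, got {self.values.ndim}D")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -10.0 or finite.max() > 110.0):
            raise ValueError("PDFF values outside the plausible [-10, 110]% range")
        self.spacing, self.affine = _validate_geometry(self.spacing, self.affine)

    @property
    def shape(self):
        return self.values.shape

    def pixel_to_world(self, ij: np.ndarray) -> np.ndarray:
        """Map (n,2) pixel indices to (n,3) world mm (in-plane, k=0)."""
        ij = np.atleast_2d(np.asarray(ij, dtype=float))
        ijk = np.column_stack([ij, np.zeros(len(ij))])
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class Plane3D:
    """An oriented plane: a point on it and a unit normal, both world mm."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise GeometryError("plane normal must be non-zero")
        self.normal = n / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance (mm) of world points to the plane; positive on
        the side the normal points to."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal


# ---------------------------------------------------------------------------
# shared grid predicates


def grids_match(a, b, atol: float = 1e-5) -> bool:
    """True when two volumes share shape, spacing and affine."""
    return (
        tuple(a.shape) == tuple(b.shape)
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.affine, b.affine, atol=atol)
    )


def require_same_grid(a, b, what: str = "inputs"):
    if not grids_match(a, b):
        raise GridError(f"{what} must share shape, spacing and affine")


def check_partition(mask: BinaryMask3D, labels: PartsLabelMap) -> bool:
    """Partition property: labels are >0 exactly where the mask is 1."""
    require_same_grid(mask, labels, "mask and labels")
    return bool(np.array_equal(labels.labels > 0, mask.voxels > 0))


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_nifti(path):
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises various types for bad files
        raise OSError(f"cannot read volume from {path!r}: {exc}") from exc
    return img, data


def _geometry_of(img):
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return zooms, np.asarray(img.affine, dtype=float)


def read_mask(path) -> BinaryMask3D:
    """Read a binary mask from NIfTI; stored values >0.5 become foreground.

    The >0.5 rule tolerates 0/255 encodings and interpolated masks.
    """
    img, data = _load_nifti(path)
    if data.ndim != 3:
        raise DimensionalityError(f"{path!r}: expected a 3D volume, got {data.ndim}D")
    spacing, affine = _geometry_of(img)
    return BinaryMask3D((np.asarray(data, dtype=float) > 0.5).astype(np.uint8),
                        spacing, affine)


def write_mask(mask: BinaryMask3D, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def read_labels(path) -> PartsLabelMap:
    """Read a head/body/tail label volume from NIfTI (values rounded)."""
    img, data = _load_nifti(path)
    if data.ndim != 3:
        raise DimensionalityError(f"{path!r}: expected a 3D volume, got {data.ndim}D")
    spacing, affine = _geometry_of(img)
    return PartsLabelMap(np.rint(np.asarray(data, dtype=float)).astype(np.uint8),
                         spacing, affine)


def write_labels(labels: PartsLabelMap, path) -> None:
    """Write labels as the smallest unsigned integer type (uint8)."""
    img = nib.Nifti1Image(labels.labels.astype(np.uint8), labels.affine)
    nib.save(img, str(path))


def read_template(path) -> ProbabilisticTemplate:
    img, data = _load_nifti(path)
    if data.ndim != 3:
        raise DimensionalityError(f"{path!r}: expected a 3D volume, got {data.ndim}D")
    spacing, affine = _geometry_of(img)
    return ProbabilisticTemplate(np.asarray(data, dtype=np.float32), spacing, affine)


def write_template(template: ProbabilisticTemplate, path) -> None:
    """Probabilistic templates are stored as 32-bit reals."""
    img = nib.Nifti1Image(template.values.astype(np.float32), template.affine)
    nib.save(img, str(path))


def read_pdff_slice(path) -> PDFFSlice:
    """Read a 2D PDFF map stored as a 2D or single-slice 3D NIfTI."""
    img, data = _load_nifti(path)
    data = np.asarray(data, dtype=float)
    zooms = np.asarray(img.header.get_zooms(), dtype=float)
    affine = np.asarray(img.affine, dtype=float)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise DimensionalityError(
                f"{path!r}: a PDFF slice must be 2D or single-slice 3D, got {data.shape}")
        data = data[:, :, 0]
    elif data.ndim != 2:
        raise DimensionalityError(f"{path!r}: expected a 2D map, got {data.ndim}D")
    spacing = np.array([zooms[0], zooms[1], zooms[2] if len(zooms) > 2 else 1.0])
    return PDFFSlice(data, spacing, affine)


def write_pdff_slice(pdff: PDFFSlice, path) -> None:
    img = nib.Nifti1Image(pdff.values[:, :, None].astype(np.float32), pdff.affine)
    nib.save(img, str(path))


def read_pdff_dicom(path) -> PDFFSlice:
    """Read a single-slice PDFF map from DICOM.

    Geometry comes from the DICOM Reference Coordinate System fields
    ImagePositionPatient, ImageOrientationPatient and PixelSpacing; pixel
    values are rescaled with RescaleSlope/RescaleIntercept when present.
    The returned affine maps (row, column) pixel indices to the DICOM
    patient coordinate frame; callers are responsible for using 3D volumes
    expressed in the same frame.
    """
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        pixels = ds.pixel_array.astype(float)
    except Exception as exc:
        raise OSError(f"cannot read DICOM from {path!r}: {exc}") from exc
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    values = pixels * slope + intercept

    try:
        ipp = np.asarray(ds.ImagePositionPatient, dtype=float)
        iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
        ps = np.asarray(ds.PixelSpacing, dtype=float)  # (row spacing, col spacing)
    except AttributeError as exc:
        raise GeometryError(f"{path!r}: missing DICOM RCS geometry fields") from exc
    thickness = float(getattr(ds, "SliceThickness", 1.0) or 1.0)

    row_dir, col_dir = iop[:3], iop[3:]  # along increasing column / row index
    normal = np.cross(row_dir, col_dir)
    affine = np.eye(4)
    affine[:3, 0] = col_dir * ps[0]   # stepping down rows
    affine[:3, 1] = row_dir * ps[1]   # stepping across columns
    affine[:3, 2] = normal * thickness
    affine[:3, 3] = ipp
    return PDFFSlice(values, np.array([ps[0], ps[1], thickness]), affine)
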