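"""Bring input masks onto the common grid the registration stage requires.

Mirrors the study preprocessing: resample whole-organ masks to 2 mm
isotropic resolution, then minimally co-register subjects by translating
them to align their foreground centroids with an arbitrary reference
subject.  Alignment uses integer-voxel shifts so masks stay binary; the
sub-voxel residual is absorbed by the nonlinear registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates

from .exceptions import GridError
from .geometry import BinaryMask3D, PartsLabelMap, grids_match

__all__ = ["CohortGrid", "resample_isotropic", "resample_mask_and_labels",
           "centroid_align", "shift_integer"]


@dataclass(frozen=True)
class CohortGrid:
    """The shared grid of a preprocessed cohort."""

    shape: tuple
    spacing: tuple
    reference_centroid: tuple  # world mm


def _target_grid(mask: BinaryMask3D, target_spacing: float):
    old_spacing = mask.spacing
    direction = mask.affine[:3, :3] / old_spacing  # unit direction cosines
    new_spacing = np.full(3, float(target_spacing))
    new_shape = np.maximum(
        np.ceil(np.asarray(mask.shape) * old_spacing / new_spacing).astype(int), 1)
    new_affine = np.eye(4)
    new_affine[:3, :3] = direction * new_spacing
    new_affine[:3, 3] = mask.affine[:3, 3]
    return new_shape, new_spacing, new_affine


def _resample_to(volume: np.ndarray, old_affine, new_shape, new_affine, order: int):
    """Sample `volume` on the new grid through world coordinates."""
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in new_shape], indexing="ij")
    ijk_new = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = ijk_new @ new_affine[:3, :3].T + new_affine[:3, 3]
    inv = np.linalg.inv(old_affine)
    ijk_old = world @ inv[:3, :3].T + inv[:3, 3]
    out = map_coordinates(volume.astype(float), ijk_old.T, order=order,
                          mode="constant", cval=0.0)
    return out.reshape(tuple(new_shape))


def resample_isotropic(mask: BinaryMask3D, target_spacing: float) -> BinaryMask3D:
    """Resample a mask to an isotropic grid (linear interpolation, 0.5 cut).

    Linear interpolation of the binary volume followed by thresholding at
    0.5 approximately preserves foreground volume.  A mask already on the
    target isotropic grid is returned unchanged.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if np.allclose(mask.spacing, target_spacing):
        return mask.copy()
    if mask.n_foreground == 0:
        warnings.warn("resampling an empty mask", stacklevel=2)
    new_shape, new_spacing, new_affine = _target_grid(mask, target_spacing)
    vals = _resample_to(mask.voxels, mask.affine, new_shape, new_affine, order=1)
    return BinaryMask3D((vals >= 0.5).astype(np.uint8), new_spacing, new_affine)


def resample_mask_and_labels(mask: BinaryMask3D, labels: PartsLabelMap,
                             target_spacing: float):
    """Jointly resample a mask and its part labels, keeping the partition.

    The mask is resampled linearly and thresholded; labels follow with the
    nearest-label rule (so no new label values appear), then are made
    consistent with the resampled mask: labels are clipped to the mask and
    mask voxels left unlabeled take the nearest labeled voxel's label.
    """
    new_mask = resample_isotropic(mask, target_spacing)
    if np.allclose(mask.spacing, target_spacing):
        new_lab = labels.labels.copy()
    else:
        new_shape = new_mask.shape
        new_lab = _resample_to(labels.labels, labels.affine, new_shape,
                               new_mask.affine, order=0)
        new_lab = np.rint(new_lab).astype(np.uint8)
    new_lab[new_mask.voxels == 0] = 0
    missing = (new_mask.voxels == 1) & (new_lab == 0)
    if np.any(missing) and np.any(new_lab > 0):
        _, idx = distance_transform_edt(new_lab == 0, sampling=new_mask.spacing,
                                        return_indices=True)
        new_lab[missing] = new_lab[tuple(i[missing] for i in idx)]
    return new_mask, PartsLabelMap(new_lab, new_mask.spacing.copy(),
                                   new_mask.affine.copy())


def shift_integer(volume: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Shift a volume by an integer number of voxels, zero-filling."""
    out = np.zeros_like(volume)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(int(v) for v in shift):
        n = volume.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            dst[ax] = slice(s, n)
            src[ax] = slice(0, n - s)
        else:
            dst[ax] = slice(0, n + s)
            src[ax] = slice(-s, n)
    out[tuple(dst)] = volume[tuple(src)]
    return out


def centroid_align(masks, reference_index: int = 0):
    """Translate masks so foreground centroids match a reference subject.

    Shifts are rounded to whole voxels (masks stay binary); each returned
    translation is the applied world-space offset in mm, zero for the
    reference.  All masks must share the same grid.
    """
    if not masks:
        raise ValueError("no masks given")
    for i, m in enumerate(masks):
        if m.n_foreground == 0:
            raise ValueError(f"mask {i} is empty; cannot centroid-align")
        if not grids_match(m, masks[reference_index]):
            raise GridError(f"mask {i} is not on the reference grid")
    ref_centroid = masks[reference_index].centroid_world()
    lin = masks[reference_index].affine[:3, :3]
    inv_lin = np.linalg.inv(lin)

    aligned, translations = [], []
    for m in masks:
        delta_world = ref_centroid - m.centroid_world()
        shift_vox = np.rint(inv_lin @ delta_world).astype(int)
        moved = shift_integer(m.voxels, shift_vox)
        if moved.sum() != m.voxels.sum():
            raise ValueError("centroid alignment would push foreground off the grid; "
                             "pad the volumes first")
        aligned.append(BinaryMask3D(moved, m.spacing.copy(), m.affine.copy()))
        translations.append(lin @ shift_vox)
    return aligned, np.asarray(translations)
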