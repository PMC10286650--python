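"""Subsegment a whole-pancreas mask into head, body and tail.

Two methods are provided: the template method (register the subject mask
to the template, carry the parts template back through the inverse warp,
propagate labels to every subject voxel) and the unsupervised k-means
baseline (k=3 on foreground world coordinates with k-means++ seeding,
clusters relabeled head/body/tail along the organ axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from sklearn.cluster import KMeans

from .exceptions import GridError
from .geometry import BinaryMask3D, PartsLabelMap, check_partition, grids_match
from .preprocess import shift_integer
from .registration import RegistrationConfig, apply_transform, register
from .template import PartsTemplate

__all__ = ["SubsegmentationResult", "subsegment_template", "subsegment_kmeans",
           "principal_orientation"]


@dataclass
class SubsegmentationResult:
    """Parts of one subject plus method diagnostics."""

    parts: PartsLabelMap
    warped_parts_coverage: float
    method: str
    diagnostics: dict = field(default_factory=dict)


def _fill_nearest_label(labels: np.ndarray, target_fg: np.ndarray,
                        spacing: np.ndarray) -> np.ndarray:
    """Give every target foreground voxel a label: keep the warped label
    where present, else the nearest (world mm) labeled voxel's label, ties
    broken toward the lowest label index (head < body < tail)."""
    out = np.zeros_like(labels)
    covered = (labels > 0) & target_fg
    out[covered] = labels[covered]
    missing = target_fg & (labels == 0)
    if not np.any(missing):
        return out
    if not np.any(labels > 0):
        raise ValueError("warped template carries no labels to propagate")
    dists = np.stack([
        distance_transform_edt(labels != lab, sampling=spacing)
        for lab in (1, 2, 3)
    ])
    # argmin returns the first (lowest) label on exact ties
    out[missing] = 1 + np.argmin(dists[:, missing], axis=0).astype(np.uint8)
    return out


def subsegment_template(subject: BinaryMask3D, parts_template: PartsTemplate,
                        config: RegistrationConfig | None = None) -> SubsegmentationResult:
    """Template-based parts segmentation of a preprocessed subject mask.

    The subject must already be resampled onto the template grid; the
    method centroid-initializes (whole-voxel shift), registers the subject
    to the template, applies the inverse warp to the parts template with
    nearest-label interpolation, and propagates labels so the result
    exactly partitions the subject mask (on the subject's input grid).
    """
    tmpl_mask = parts_template.template_mask
    if not grids_match(subject, tmpl_mask):
        raise GridError("subject must be preprocessed onto the template grid")
    if subject.n_foreground == 0:
        raise ValueError("subject mask is empty")

    # centroid initialization, whole voxels so the mask stays binary
    lin_inv = np.linalg.inv(subject.affine[:3, :3])
    delta = tmpl_mask.centroid_world() - subject.centroid_world()
    shift_vox = np.rint(lin_inv @ delta).astype(int)
    moved = shift_integer(subject.voxels, shift_vox)
    if moved.sum() != subject.voxels.sum():
        raise ValueError("centroid initialization pushed the subject off the grid")
    aligned = BinaryMask3D(moved, subject.spacing.copy(), subject.affine.copy())

    transform = register(aligned, tmpl_mask, config)
    warped_parts = apply_transform(transform, parts_template.parts,
                                   direction="inverse",
                                   interpolation="nearest-label")

    fg = aligned.voxels > 0
    coverage = float((warped_parts.labels[fg] > 0).mean())
    filled = _fill_nearest_label(warped_parts.labels, fg, subject.spacing)
    # undo the initialization shift so the result lives on the input grid
    filled = shift_integer(filled, -shift_vox)
    parts = PartsLabelMap(filled, subject.spacing.copy(), subject.affine.copy())
    assert check_partition(subject, parts)
    return SubsegmentationResult(
        parts=parts, warped_parts_coverage=coverage, method="template",
        diagnostics={
            "iterations": transform.iterations,
            "final_similarity": transform.final_similarity,
            "converged": transform.converged,
            "centroid_shift_voxels": shift_vox.tolist(),
        })


def principal_orientation(mask: BinaryMask3D) -> np.ndarray:
    """First principal axis of the foreground, signed head -> tail.

    The sign convention makes the bulkier end the head: among foreground
    projections onto the axis, the quarter of the projection range at the
    start must hold more voxels than the quarter at the end, else the axis
    is flipped.  Raises DegenerateShapeError for non-elongated shapes.
    """
    from .exceptions import DegenerateShapeError

    pts = mask.foreground_world()
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    if np.sqrt(evals[-1] / max(evals[-2], 1e-12)) < 1.5:
        raise DegenerateShapeError("mask is not elongated; supply an orientation")
    axis = evecs[:, -1]
    t = centered @ axis
    lo, hi = t.min(), t.max()
    q = (hi - lo) / 4.0
    if (t <= lo + q).sum() < (t >= hi - q).sum():
        axis = -axis
    return axis


def subsegment_kmeans(subject: BinaryMask3D, seed: int = 0,
                      orientation=None) -> SubsegmentationResult:
    """k-means baseline: k=3 on foreground world coordinates.

    k-means++ initialization under the given seed, Lloyd iterations to
    convergence; clusters are relabeled head/body/tail by ascending
    projection of their centroids onto the head->tail orientation axis
    (principal axis with the bulky-end-first convention when not given).
    """
    if subject.n_foreground < 3:
        raise ValueError("k-means subsegmentation needs at least 3 foreground voxels")
    if orientation is None:
        axis = principal_orientation(subject)
    else:
        axis = np.asarray(orientation, dtype=float)
        axis = axis / np.linalg.norm(axis)

    fg_idx = np.argwhere(subject.voxels > 0)
    coords = subject.voxel_to_world(fg_idx)
    km = KMeans(n_clusters=3, init="k-means++", n_init=10, max_iter=300,
                tol=1e-10, random_state=int(seed), algorithm="lloyd")
    assignments = km.fit_predict(coords)

    order = np.argsort(km.cluster_centers_ @ axis)
    relabel = np.empty(3, dtype=np.uint8)
    relabel[order] = (1, 2, 3)
    labels = relabel[assignments]

    vol = np.zeros(subject.shape, dtype=np.uint8)
    vol[tuple(fg_idx.T)] = labels
    parts = PartsLabelMap(vol, subject.spacing.copy(), subject.affine.copy())
    assert check_partition(subject, parts)
    return SubsegmentationResult(
        parts=parts, warped_parts_coverage=1.0, method="kmeans",
        diagnostics={"inertia": float(km.inertia_), "n_iter": int(km.n_iter_),
                     "orientation": np.asarray(axis).tolist()})
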