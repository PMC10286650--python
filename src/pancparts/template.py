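"""Groupwise template construction, plane annotation and centerline tools.

Template construction follows the classical groupwise scheme: start from
the voxelwise mean of the centroid-aligned cohort, then iterate "register
every mask to the current average, re-average the warped masks".  The
probabilistic template is binarized at 0.5 (inclusive) and annotated into
head/body/tail by two boundary planes whose normals point from head toward
tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, label as cc_label
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .exceptions import AnnotationError, DegenerateShapeError
from .geometry import (BinaryMask3D, PartsLabelMap, Plane3D,
                       ProbabilisticTemplate, require_same_grid)
from .registration import RegistrationConfig, apply_transform, register

__all__ = ["PartsTemplate", "build_template", "binarize", "annotate_parts",
           "annotate_by_fraction", "compute_centerline",
           "midpoint_body_tail_boundary", "planes_from_centerline",
           "polyline_arclength"]


@dataclass
class PartsTemplate:
    """A binarized template with its head/body/tail annotation."""

    template_mask: BinaryMask3D
    parts: PartsLabelMap
    plane_hb: Plane3D
    plane_bt: Plane3D
    cohort_size: int = 0
    iterations: int = 0
    threshold: float = 0.5

    def __post_init__(self):
        require_same_grid(self.template_mask, self.parts, "template mask and parts")
        if not np.array_equal(self.parts.labels > 0, self.template_mask.voxels > 0):
            raise AnnotationError("parts must partition the template mask")
        for lab, name in ((1, "head"), (2, "body"), (3, "tail")):
            if not np.any(self.parts.labels == lab):
                raise AnnotationError(f"{name} label is empty")


def build_template(masks, n_iterations: int = 4,
                   config: RegistrationConfig | None = None):
    """Groupwise average of preprocessed masks.

    Parameters
    ----------
    masks : list of BinaryMask3D
        At least two masks on a common grid, already resampled and
        centroid-aligned.
    n_iterations : int
        Number of register-and-average rounds (the study used four).

    Returns
    -------
    template : ProbabilisticTemplate
    transforms : list of DiffeoTransform
        Final per-subject transform (mask -> template), one per input.
    """
    if len(masks) < 2:
        raise ValueError("template construction needs at least two masks")
    for i, m in enumerate(masks):
        if m.n_foreground == 0:
            raise ValueError(f"mask {i} is empty")
        require_same_grid(m, masks[0], f"mask {i} and mask 0")

    spacing, affine = masks[0].spacing, masks[0].affine
    average = np.mean([m.voxels.astype(float) for m in masks], axis=0)
    transforms = [None] * len(masks)
    for _ in range(n_iterations):
        target = ProbabilisticTemplate(average, spacing.copy(), affine.copy())
        warped = []
        for i, m in enumerate(masks):
            t = register(m, target, config)
            transforms[i] = t
            warped.append(_warp_probability(m, t))
        average = np.clip(np.mean(warped, axis=0), 0.0, 1.0)
    template = ProbabilisticTemplate(average, spacing.copy(), affine.copy())
    return template, transforms


def _warp_probability(mask: BinaryMask3D, transform) -> np.ndarray:
    """Warp a binary mask forward with linear interpolation, keeping the
    fractional values for averaging."""
    return np.clip(apply_transform(transform, mask.voxels.astype(float),
                                   direction="forward", interpolation="linear"),
                   0.0, 1.0)


def binarize(template: ProbabilisticTemplate, threshold: float = 0.5) -> BinaryMask3D:
    """Threshold a probabilistic template; foreground where value >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    return BinaryMask3D((template.values >= threshold).astype(np.uint8),
                        template.spacing.copy(), template.affine.copy())


def annotate_parts(template_mask: BinaryMask3D, plane_hb: Plane3D,
                   plane_bt: Plane3D, cohort_size: int = 0, iterations: int = 0,
                   threshold: float = 0.5) -> PartsTemplate:
    """Annotate a binarized template with two boundary planes.

    Both normals must point from head toward tail: the head is the
    foreground with negative signed distance to the head-body plane, the
    tail is the foreground with positive signed distance to the body-tail
    plane and the body is the remainder.
    """
    fg = np.argwhere(template_mask.voxels > 0)
    if len(fg) == 0:
        raise AnnotationError("template mask is empty")
    world = template_mask.voxel_to_world(fg)
    d_hb = plane_hb.signed_distance(world)
    d_bt = plane_bt.signed_distance(world)

    head = d_hb < 0
    tail = d_bt >= 0
    if np.any(head & tail):
        raise AnnotationError("inconsistent planes: head and tail regions overlap")
    labels = np.full(len(fg), 2, dtype=np.uint8)
    labels[head] = 1
    labels[tail] = 3
    for lab, name in ((1, "head"), (2, "body"), (3, "tail")):
        if not np.any(labels == lab):
            raise AnnotationError(f"annotation produced an empty {name}")

    vol = np.zeros(template_mask.shape, dtype=np.uint8)
    vol[tuple(fg.T)] = labels
    parts = PartsLabelMap(vol, template_mask.spacing.copy(), template_mask.affine.copy())
    return PartsTemplate(template_mask.copy(), parts, plane_hb, plane_bt,
                         cohort_size=cohort_size, iterations=iterations,
                         threshold=threshold)


# ---------------------------------------------------------------------------
# centerline


def polyline_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length (mm) along an ordered polyline."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _elongation_ratio(mask: BinaryMask3D) -> float:
    pts = mask.foreground_world()
    cov = np.cov((pts - pts.mean(axis=0)).T)
    ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
    return float(np.sqrt(ev[0] / max(ev[1], 1e-12)))


def compute_centerline(mask: BinaryMask3D, orientation: np.ndarray | None = None,
                       smooth_window: int = 5) -> np.ndarray:
    """Extract an ordered head-to-tail centerline of an elongated mask.

    The medial path is traced on the foreground voxel graph: the mask's
    two geodesic extremities are found by a double Dijkstra sweep, then the
    path between them is recomputed with edges penalized away from the
    distance-transform ridge so it runs along the medial axis rather than
    the surface.  The off-axis ramps near the two extremities are trimmed
    by one local radius, the path is smoothed with a moving average, and
    both ends are extended tangentially to the mask surface.  The head end
    is the end with the larger local cross-section (distance-transform
    radius); pass an ``orientation`` vector pointing head -> tail to
    override.

    Returns (n, 3) world points in mm ordered head to tail.
    """
    vox = mask.voxels.astype(bool)
    if not vox.any():
        raise ValueError("cannot compute the centerline of an empty mask")
    n_comp = cc_label(vox, structure=np.ones((3, 3, 3)))[1]
    if n_comp != 1:
        raise ValueError(f"mask must be a single connected component, found {n_comp}")
    if _elongation_ratio(mask) < 1.5:
        raise DegenerateShapeError("mask is not elongated enough for a centerline")

    pts = np.argwhere(vox)
    edt = distance_transform_edt(vox, sampling=mask.spacing)
    edt_max = float(edt.max())

    # 26-neighborhood graph with physical edge lengths; the weighted copy
    # multiplies each edge by a centrality factor that favors the EDT ridge
    index = -np.ones(vox.shape, dtype=int)
    index[tuple(pts.T)] = np.arange(len(pts))
    centrality = 0.02 + 0.98 * (1.0 - edt[tuple(pts.T)] / edt_max)
    offsets = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                        for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)])
    rows, cols, data, wdata = [], [], [], []
    for off in offsets:
        nb = pts + off
        ok = np.all((nb >= 0) & (nb < np.asarray(vox.shape)), axis=1)
        nb_idx = np.full(len(pts), -1)
        nb_idx[ok] = index[tuple(nb[ok].T)]
        valid = nb_idx >= 0
        src = np.arange(len(pts))[valid]
        dst = nb_idx[valid]
        length = np.linalg.norm(off * mask.spacing)
        rows.append(src)
        cols.append(dst)
        data.append(np.full(valid.sum(), length))
        wdata.append(length * 0.5 * (centrality[src] + centrality[dst]))
    rows, cols = np.concatenate(rows), np.concatenate(cols)
    graph = coo_matrix((np.concatenate(data), (rows, cols)),
                       shape=(len(pts), len(pts))).tocsr()
    wgraph = coo_matrix((np.concatenate(wdata), (rows, cols)),
                        shape=(len(pts), len(pts))).tocsr()

    # double sweep on true lengths: geodesic extremities of the mask
    d0 = dijkstra(graph, indices=0)
    a = int(np.argmax(np.where(np.isinf(d0), -1, d0)))
    da = dijkstra(graph, indices=a)
    b = int(np.argmax(np.where(np.isinf(da), -1, da)))
    # medial path between them on the centrality-weighted graph
    _, pred = dijkstra(wgraph, indices=a, return_predecessors=True)
    path = [b]
    while path[-1] != a:
        nxt = pred[path[-1]]
        if nxt < 0:
            raise ValueError("mask graph is disconnected")
        path.append(int(nxt))
    path_vox = pts[path[::-1]]

    # trim the off-axis ramp at each extremity (about one local radius)
    min_sp = float(np.min(mask.spacing))
    r_vals = edt[tuple(path_vox.T)]
    n = len(path_vox)
    t_head = int(np.ceil(r_vals[:max(2, n // 10)].max() / min_sp))
    t_tail = int(np.ceil(r_vals[-max(2, n // 10):].max() / min_sp))
    if n - t_head - t_tail >= max(4, smooth_window):
        path_vox = path_vox[t_head:n - t_tail]

    world = mask.voxel_to_world(path_vox)
    # extend both ends along their tangents to the mask surface so the
    # polyline spans the organ tip to tip
    world = _extend_to_surface(world, mask)
    if smooth_window > 1 and len(world) > smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(world, ((pad, pad), (0, 0)), mode="edge")
        world = np.column_stack([np.convolve(padded[:, d], kernel, mode="valid")
                                 for d in range(3)])

    # orient head first
    if orientation is not None:
        axis = np.asarray(orientation, dtype=float)
        if (world[-1] - world[0]) @ axis < 0:
            world = world[::-1]
    else:
        radius = distance_transform_edt(vox, sampling=mask.spacing)
        r_start = radius[tuple(path_vox[0])]
        r_end = radius[tuple(path_vox[-1])]
        if r_end > r_start:
            world = world[::-1]
    return world


def _extend_to_surface(world: np.ndarray, mask: BinaryMask3D) -> np.ndarray:
    """Prolong both polyline ends along their tangents while inside the mask."""
    vox = mask.voxels.astype(bool)
    shape = np.asarray(vox.shape)
    step = 0.5 * float(np.min(mask.spacing))

    def walk(start, direction):
        added = []
        p = start.copy()
        for _ in range(200):
            q = p + step * direction
            ijk = np.rint(mask.world_to_voxel(q)[0]).astype(int)
            if np.any(ijk < 0) or np.any(ijk >= shape) or not vox[tuple(ijk)]:
                break
            added.append(q)
            p = q
        return added

    k = min(6, len(world) - 1)
    t_end = world[-1] - world[-1 - k]
    t_start = world[0] - world[k]
    t_end /= np.linalg.norm(t_end)
    t_start /= np.linalg.norm(t_start)
    head_ext = walk(world[0], t_start)[::-1]
    tail_ext = walk(world[-1], t_end)
    parts = [np.asarray(p) for p in (head_ext, world, tail_ext) if len(p)]
    return np.vstack(parts)


def annotate_by_fraction(template_mask: BinaryMask3D, head_fraction: float,
                         smooth_window: int = 5) -> PartsTemplate:
    """Plane-annotate a template from its own centerline.

    Emulates the annotation protocol on shapes whose head is defined as a
    fraction of the organ's medial length: the head-body plane is placed
    orthogonal to the centerline at ``head_fraction`` of the medial arc
    (measured between the two end-cap centers, i.e. trimming one local
    radius off each end of the tip-to-tip centerline), and the body-tail
    plane follows the midpoint rule.
    """
    cl = compute_centerline(template_mask, smooth_window=smooth_window)
    arc = polyline_arclength(cl)
    radius = distance_transform_edt(template_mask.voxels.astype(bool),
                                    sampling=template_mask.spacing)
    ijk = np.clip(np.rint(template_mask.world_to_voxel(cl)).astype(int), 0,
                  np.asarray(template_mask.shape) - 1)
    r_along = radius[tuple(ijk.T)]
    n_end = max(2, len(cl) // 10)
    r_head = float(r_along[:n_end].max())
    r_tail = float(r_along[-n_end:].max())
    total = arc[-1]
    medial = max(total - r_head - r_tail, total * 0.5)
    s_hb = min(r_head + head_fraction * medial, 0.95 * total)
    plane_hb, plane_bt = planes_from_centerline(cl, s_hb)
    return annotate_parts(template_mask, plane_hb, plane_bt)


def _point_and_tangent_at(centerline: np.ndarray, arclength: float):
    arc = polyline_arclength(centerline)
    point = np.array([np.interp(arclength, arc, centerline[:, d]) for d in range(3)])
    i = int(np.searchsorted(arc, arclength))
    i = min(max(i, 1), len(centerline) - 1)
    tangent = centerline[i] - centerline[i - 1]
    return point, tangent / np.linalg.norm(tangent)


def planes_from_centerline(centerline: np.ndarray, head_body_arclength: float):
    """Boundary planes orthogonal to the centerline, normals head -> tail.

    The head-body plane sits at the given arc length; the body-tail plane
    follows the midpoint rule (halfway between the head-body boundary and
    the tail tip).  Returns (plane_hb, plane_bt).
    """
    bt_arc = midpoint_body_tail_boundary(centerline, head_body_arclength)
    p_hb, t_hb = _point_and_tangent_at(centerline, head_body_arclength)
    p_bt, t_bt = _point_and_tangent_at(centerline, bt_arc)
    return Plane3D(p_hb, t_hb), Plane3D(p_bt, t_bt)


def midpoint_body_tail_boundary(centerline: np.ndarray,
                                head_body_arclength: float) -> float:
    """Arc length (mm) of the body-tail boundary: the midpoint between the
    head-body boundary and the tail tip."""
    total = float(polyline_arclength(centerline)[-1])
    if not 0 <= head_body_arclength < total:
        raise ValueError(
            f"head-body arc length must lie in [0, {total}), got {head_body_arclength}")
    return head_body_arclength + (total - head_body_arclength) / 2.0
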