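"""Synthetic pancreas phantoms with known head/body/tail ground truth.

The phantom is a curved, tapering tube: a cubic-spline centerline through
five control points, a radius profile interpolating head -> body -> tail
radii along arc length, and a voxelization rule "foreground iff distance to
the centerline is below the local radius".  Ground-truth labels are
assigned by the arc length of the nearest centerline sample, so they stay
exact on curved tubes: the head spans the first ``head_fraction`` of the
length and the body-tail boundary sits at the midpoint of the remaining
length (the conventional anatomical definition).

Phantoms stand in for cohorts of real whole-pancreas segmentations: they
reproduce the elongated, curved, single-component geometry and its
inter-subject variation, not image intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .exceptions import GeometryError
from .geometry import BinaryMask3D, PartsLabelMap

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort"]

_N_CENTERLINE_SAMPLES = 1000  # dense polyline used for arc length / distance


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic pancreas.

    Defaults give a pancreas-like organ that fits the 64^3 grid of 2 mm
    isotropic voxels the pipeline works at: 80 mm long, gently curved, with
    a bulky head (9 mm radius) tapering to a slim tail (5 mm), the head
    occupying the first 40% of the length.  (A real pancreas is a further
    ~1.5x larger; the proportions, not the absolute size, are what the
    downstream geometry depends on.)
    """

    grid_shape: tuple = (64, 64, 64)
    spacing: float = 2.0              # mm, isotropic
    centerline_length: float = 80.0   # mm, chord-length target of the spline
    curvature_amplitude: float = 12.0  # mm, lateral bow of the centerline
    radius_head: float = 9.0          # mm
    radius_body: float = 7.0          # mm
    radius_tail: float = 5.0          # mm
    head_fraction: float = 0.40       # arc-length fraction at head-body boundary
    noise_sd: float = 2.0             # mm, Gaussian jitter of control points
    seed: int = 0

    def __post_init__(self):
        if min(self.radius_head, self.radius_body, self.radius_tail) <= 0:
            raise ValueError("radii must be strictly positive")
        if not 0 < self.head_fraction < 1:
            raise ValueError("head_fraction must lie strictly between 0 and 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


def _control_points(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Five control points: a bowed arc along x, centered in the grid."""
    shape = np.asarray(spec.grid_shape, dtype=float)
    center = (shape - 1) / 2.0 * spec.spacing
    t = np.linspace(-0.5, 0.5, 5)
    pts = np.zeros((5, 3))
    pts[:, 0] = center[0] + t * spec.centerline_length
    # C-shaped bow in y, slight tilt in z, echoing the pancreas arching
    # around the spine.
    pts[:, 1] = center[1] + spec.curvature_amplitude * np.cos(np.pi * t)
    pts[:, 2] = center[2] + 0.15 * spec.curvature_amplitude * np.sin(np.pi * t)
    if spec.noise_sd > 0:
        pts += rng.normal(0.0, spec.noise_sd, size=pts.shape)
    return pts


def _dense_centerline(ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample the spline densely; return (points, cumulative arc length)."""
    u = np.linspace(0.0, 1.0, len(ctrl))
    spline = CubicSpline(u, ctrl, axis=0)
    samples = spline(np.linspace(0.0, 1.0, _N_CENTERLINE_SAMPLES))
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return samples, arc


def _radius_profile(spec: PhantomSpec, arc: np.ndarray) -> np.ndarray:
    total = arc[-1]
    knots = np.array([0.0, spec.head_fraction * total, total])
    radii = np.array([spec.radius_head, spec.radius_body, spec.radius_tail])
    return np.interp(arc, knots, radii)


def generate_phantom(spec: PhantomSpec):
    """Build one phantom.

    Returns
    -------
    mask : BinaryMask3D
    labels : PartsLabelMap
        Ground-truth head/body/tail partition of the mask.
    centerline : (n, 3) ndarray
        The generating centerline samples in world mm, head to tail.
    """
    rng = np.random.default_rng(spec.seed)
    ctrl = _control_points(spec, rng)
    samples, arc = _dense_centerline(ctrl)
    radii = _radius_profile(spec, arc)
    total = arc[-1]

    shape = tuple(int(s) for s in spec.grid_shape)
    affine = np.diag([spec.spacing] * 3 + [1.0])
    spacing = np.full(3, float(spec.spacing))
    world_max = (np.asarray(shape) - 1) * spec.spacing

    # every centerline sample plus its radius and a 2-voxel margin must fit
    margin = radii[:, None] + 2.0 * spec.spacing
    bad = np.any((samples - margin < 0) | (samples + margin > world_max), axis=1)
    if np.any(bad):
        first = int(np.argmax(bad))
        ctrl_idx = int(np.rint(first / (_N_CENTERLINE_SAMPLES - 1) * (len(ctrl) - 1)))
        raise GeometryError(
            f"tube exits the grid near control point {ctrl_idx} at {ctrl[ctrl_idx]}")

    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    voxel_world = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) * spec.spacing
    dist, idx = cKDTree(samples).query(voxel_world, workers=1)
    inside = dist < radii[idx]

    hb = spec.head_fraction * total
    bt = hb + (total - hb) / 2.0  # midpoint of the remaining (body+tail) length
    arclen = arc[idx]
    lab = np.zeros(len(voxel_world), dtype=np.uint8)
    lab[inside & (arclen < hb)] = 1
    lab[inside & (arclen >= hb) & (arclen < bt)] = 2
    lab[inside & (arclen >= bt)] = 3

    mask = BinaryMask3D(inside.reshape(shape).astype(np.uint8), spacing, affine)
    labels = PartsLabelMap(lab.reshape(shape), spacing.copy(), affine.copy())
    return mask, labels, samples


def generate_cohort(base_spec: PhantomSpec, n: int, seed: int,
                    radius_jitter: float = 0.15):
    """Generate ``n`` independently perturbed phantoms.

    Radii are jittered multiplicatively by U(1-radius_jitter, 1+radius_jitter)
    and centerline control points by the spec's ``noise_sd``; everything is
    deterministic under ``seed``.  A draw whose jittered tube would leave
    the grid is redrawn (deterministically, from the same stream); after 20
    failed redraws for one phantom the geometry error propagates.
    """
    if n < 2:
        raise ValueError("a cohort needs n >= 2 phantoms")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        for attempt in range(20):
            f = rng.uniform(1.0 - radius_jitter, 1.0 + radius_jitter, size=3)
            child_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(
                base_spec,
                radius_head=base_spec.radius_head * f[0],
                radius_body=base_spec.radius_body * f[1],
                radius_tail=base_spec.radius_tail * f[2],
                seed=child_seed,
            )
            try:
                mask, labels, _ = generate_phantom(spec)
            except GeometryError:
                if attempt == 19:
                    raise
                continue
            out.append((mask, labels))
            break
    return out
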