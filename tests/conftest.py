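"""Shared fixtures: phantom cohorts and a prebuilt parts template.

Heavy objects are session-scoped so the registration-based tests share one
template build.
"""

import numpy as np
import pytest

import pancparts as pp
from pancparts.template import annotate_by_fraction


@pytest.fixture(scope="session")
def spec():
    return pp.PhantomSpec()


@pytest.fixture(scope="session")
def cohort12(spec):
    """Twelve jittered phantoms (masks + ground-truth labels)."""
    return pp.generate_cohort(spec, 12, seed=11)


@pytest.fixture(scope="session")
def cohort10(cohort12):
    """First ten phantoms of the shared cohort."""
    return cohort12[:10]


@pytest.fixture(scope="session")
def cohort50(spec):
    """Fifty jittered phantoms for the partition / volume-fraction suites."""
    return pp.generate_cohort(spec, 50, seed=123)


@pytest.fixture(scope="session")
def parts_template10(spec, cohort10):
    """Parts template built from the 10-phantom cohort (2 groupwise rounds)."""
    masks = [m for m, _ in cohort10]
    aligned, _ = pp.centroid_align(masks, 0)
    template, _ = pp.build_template(aligned, n_iterations=2)
    tmask = pp.binarize(template, 0.5)
    return annotate_by_fraction(tmask, spec.head_fraction)


def optimal_1d_3means_boundaries(xs):
    """Exact 1-D 3-means by dynamic programming over contiguous segments.

    Optimal 1-D k-means clusters are contiguous intervals, so an O(k n^2)
    DP over the sorted values is exact.  Returns the largest member of
    cluster 1 and of cluster 2.
    """
    xs = np.sort(np.asarray(xs, dtype=float))
    n = len(xs)
    pre = np.concatenate([[0.0], np.cumsum(xs)])
    pre2 = np.concatenate([[0.0], np.cumsum(xs ** 2)])

    def sse(i, j):  # cost of xs[i:j]
        m = j - i
        s = pre[j] - pre[i]
        return (pre2[j] - pre2[i]) - s * s / m

    best1 = np.array([sse(0, j) for j in range(1, n + 1)])
    best2 = np.full(n + 1, np.inf)
    cut1 = np.zeros(n + 1, dtype=int)
    for j in range(2, n + 1):
        for i in range(1, j):
            c = best1[i - 1] + sse(i, j)
            if c < best2[j]:
                best2[j], cut1[j] = c, i
    best3, cut2 = np.inf, 0
    for i in range(2, n):
        c = best2[i] + sse(i, n)
        if c < best3:
            best3, cut2 = c, i
    return xs[cut1[cut2] - 1], xs[cut2 - 1]


def make_ball(shape=(24, 24, 24), center=None, radius_mm=8.0, spacing=(2.0, 2.0, 2.0)):
    """Axis-aligned test ball as a BinaryMask3D."""
    spacing = np.asarray(spacing, dtype=float)
    if center is None:
        center = (np.asarray(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d = np.sqrt(sum(((g - c) * s) ** 2
                    for g, c, s in zip(grids, center, spacing)))
    affine = np.diag(list(spacing) + [1.0])
    return pp.BinaryMask3D((d < radius_mm).astype(np.uint8), spacing, affine)


def make_cylinder_x(shape=(64, 24, 24), x_range=(8, 56), center_yz=(11.5, 11.5),
                    radius_mm=8.0, spacing=2.0):
    """Straight cylinder along +x as a BinaryMask3D."""
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r = np.sqrt((jj - center_yz[0]) ** 2 + (kk - center_yz[1]) ** 2) * spacing
    vox = ((ii >= x_range[0]) & (ii < x_range[1]) & (r < radius_mm)).astype(np.uint8)
    affine = np.diag([spacing] * 3 + [1.0])
    return pp.BinaryMask3D(vox, [spacing] * 3, affine)
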