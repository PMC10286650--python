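"""Segmentation agreement metrics: Dice, 95% Hausdorff, volumes, Bland-Altman.

Conventions: boundary voxels are the 6-connectivity erosion difference;
boundary-to-boundary distances are measured in world mm (anisotropy-aware);
the 95th percentile is taken over the pooled symmetric set of directed
nearest distances with linear interpolation between order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu, wilcoxon  # thin pass-throughs

from .geometry import BinaryMask3D, PartsLabelMap, PART_NAMES, require_same_grid

__all__ = ["PartAgreement", "BlandAltman", "dice", "hd95", "volume_ml",
           "bland_altman", "compare_parts", "wilcoxon", "mannwhitneyu"]


@dataclass
class BlandAltman:
    """Bias and 1.96-SD limits of agreement of paired differences."""

    bias: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class PartAgreement:
    """Per-part agreement between two parts segmentations.

    Keys of the dict fields are part names ('head', 'body', 'tail') for
    parts non-empty in both inputs; parts empty in either are listed in
    ``absent`` and not scored.
    """

    dsc: dict = field(default_factory=dict)
    hd95_mm: dict = field(default_factory=dict)
    volume_delta_ml: dict = field(default_factory=dict)
    absent: list = field(default_factory=list)


def dice(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Two empty masks agree perfectly: returns 1 with a warning.
    """
    require_same_grid(a, b)
    na, nb = a.n_foreground, b.n_foreground
    if na + nb == 0:
        warnings.warn("Dice of two empty masks defined as 1", stacklevel=2)
        return 1.0
    inter = int(np.logical_and(a.voxels > 0, b.voxels > 0).sum())
    return 2.0 * inter / (na + nb)


def _boundary_world(mask: BinaryMask3D) -> np.ndarray:
    """World coordinates of boundary voxels (6-connectivity erosion diff)."""
    fg = mask.voxels.astype(bool)
    eroded = binary_erosion(fg, structure=generate_binary_structure(3, 1),
                            border_value=0)
    return mask.voxel_to_world(np.argwhere(fg & ~eroded))


def hd95(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """95th percentile Hausdorff distance in mm.

    Directed nearest-boundary distances from A to B and from B to A are
    pooled before taking the percentile.
    """
    require_same_grid(a, b)
    if a.n_foreground == 0 or b.n_foreground == 0:
        raise ValueError("95% Hausdorff distance needs two non-empty masks")
    pa, pb = _boundary_world(a), _boundary_world(b)
    d_ab = cKDTree(pb).query(pa, workers=1)[0]
    d_ba = cKDTree(pa).query(pb, workers=1)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def volume_ml(mask: BinaryMask3D) -> float:
    """Foreground volume in mL (voxel count x voxel volume)."""
    return float(mask.n_foreground * np.prod(mask.spacing) / 1000.0)


def bland_altman(pairs) -> BlandAltman:
    """Bland-Altman bias and limits of agreement of (a, b) pairs.

    bias = mean(a - b); LoA = bias ± 1.96 x sample SD (n-1 denominator).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("bland_altman needs at least two (a, b) pairs")
    diff = arr[:, 0] - arr[:, 1]
    bias = float(diff.mean())
    half = 1.96 * float(diff.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - half, loa_high=bias + half,
                       n=len(diff))


def compare_parts(a: PartsLabelMap, b: PartsLabelMap) -> PartAgreement:
    """Per-part Dice / 95%HD / volume delta (A - B, mL) for parts present
    in both label maps."""
    require_same_grid(a, b)
    out = PartAgreement()
    for lab, name in PART_NAMES.items():
        ma, mb = a.part_mask(lab), b.part_mask(lab)
        if ma.n_foreground == 0 or mb.n_foreground == 0:
            out.absent.append(name)
            continue
        out.dsc[name] = dice(ma, mb)
        out.hd95_mm[name] = hd95(ma, mb)
        out.volume_delta_ml[name] = volume_ml(ma) - volume_ml(mb)
    return out
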