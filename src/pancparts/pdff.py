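"""Regional PDFF quantification: 3D parts x 2D fat-fraction slice.

The 3D parts segmentation is resliced onto the 2D PDFF map through scanner
coordinates (each pixel center is mapped into the label volume and sampled
with the nearest-label rule), then each part's pixels pass a QC cascade in
this order: (1) raw resliced area must exceed 30 pixels, (2) pixels with
PDFF above 50% or missing are dropped (50.0% exactly is retained), (3) the
surviving part mask is opened with the discrete 3-pixel-diameter disk (the
3x3 cross).  A part emptied by opening is excluded; otherwise its median
PDFF (even counts: mean of the two central order statistics) is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_opening, generate_binary_structure

from .exceptions import GeometryError, GridError
from .geometry import PDFFSlice, PartsLabelMap, PART_NAMES

__all__ = ["PartPDFF", "RegionalPDFFReport", "reslice_labels", "regional_pdff",
           "whole_pancreas_pdff", "DISK_3PX"]

#: Discrete disk of 3-pixel diameter: the 4-connected 3x3 cross.
DISK_3PX = generate_binary_structure(2, 1)

#: QC thresholds
MIN_AREA_PX = 30          # raw resliced areas of <= this many pixels are excluded
MAX_PDFF_PERCENT = 50.0   # pixels strictly above this are excluded


@dataclass
class PartPDFF:
    """QC outcome for one part on the PDFF slice."""

    raw_pixels: int
    qc_pixels: int = 0
    median_pdff: float | None = None
    reason: str | None = None  # small_segment | emptied_by_qc | not_in_slice

    @property
    def included(self) -> bool:
        return self.reason is None


@dataclass
class RegionalPDFFReport:
    """Per-part and whole-pancreas QC'd median PDFF."""

    parts: dict = field(default_factory=dict)   # name -> PartPDFF
    whole: PartPDFF | None = None


def reslice_labels(parts: PartsLabelMap, slice_geom: PDFFSlice) -> np.ndarray:
    """Sample the 3D label volume at each 2D pixel center (nearest label).

    Pixel centers are mapped to world mm through the slice affine, then
    into the 3D voxel grid through the inverse of the volume affine; the
    nearest voxel's label is taken, background for pixels outside the
    volume.  Returns a 2D uint8 label grid on the slice's pixel grid.
    """
    try:
        inv3 = np.linalg.inv(parts.affine)
    except np.linalg.LinAlgError as exc:
        raise GeometryError("label volume affine is not invertible") from exc
    h, w = slice_geom.shape
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pix = np.column_stack([ii.ravel(), jj.ravel()])
    world = slice_geom.pixel_to_world(pix)
    ijk = world @ inv3[:3, :3].T + inv3[:3, 3]
    nearest = np.rint(ijk).astype(int)
    shape3 = np.asarray(parts.shape)
    inside = np.all((nearest >= 0) & (nearest < shape3), axis=1)
    out = np.zeros(h * w, dtype=np.uint8)
    out[inside] = parts.labels[tuple(nearest[inside].T)]
    return out.reshape(h, w)


def _qc_one(part_mask: np.ndarray, pdff: PDFFSlice) -> PartPDFF:
    raw = int(part_mask.sum())
    if raw == 0:
        return PartPDFF(raw_pixels=0, reason="not_in_slice")
    if raw <= MIN_AREA_PX:
        return PartPDFF(raw_pixels=raw, reason="small_segment")
    ok = part_mask & np.isfinite(pdff.values) & (pdff.values <= MAX_PDFF_PERCENT)
    opened = binary_opening(ok, structure=DISK_3PX)
    n = int(opened.sum())
    if n == 0:
        return PartPDFF(raw_pixels=raw, qc_pixels=0, reason="emptied_by_qc")
    return PartPDFF(raw_pixels=raw, qc_pixels=n,
                    median_pdff=float(np.median(pdff.values[opened])))


def _require_same_pixel_grid(labels2d: np.ndarray, pdff: PDFFSlice):
    if labels2d.shape != pdff.shape:
        raise GridError("2D labels and PDFF map must share the pixel grid")


def regional_pdff(labels2d: np.ndarray, pdff: PDFFSlice) -> RegionalPDFFReport:
    """QC'd median PDFF per part, plus the whole-pancreas value.

    ``labels2d`` is the output of :func:`reslice_labels` on the same pixel
    grid as the PDFF map.
    """
    _require_same_pixel_grid(labels2d, pdff)
    report = RegionalPDFFReport()
    for lab, name in PART_NAMES.items():
        report.parts[name] = _qc_one(labels2d == lab, pdff)
    report.whole = whole_pancreas_pdff(labels2d, pdff)
    return report


def whole_pancreas_pdff(labels2d: np.ndarray, pdff: PDFFSlice) -> PartPDFF:
    """All part labels merged into one 'whole' label, then the identical
    QC cascade and median."""
    _require_same_pixel_grid(labels2d, pdff)
    return _qc_one(labels2d > 0, pdff)
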