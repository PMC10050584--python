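"""Construction of the three analysis VOIs from the segmentation masks.

The feature pipeline reads each image inside three volumes of interest:
total lung minus GTV, ipsilateral lung minus GTV, and the PTV expanded by
a 2 cm isotropic margin.  Margin expansion uses a Euclidean distance
transform with the physical voxel spacing, so an "isotropic" millimetre
margin stays isotropic on anisotropic grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Mask3D, PatientCase

__all__ = ["VOI_NAMES", "VOISet", "isotropic_expand", "ipsilateral_lung", "build_vois"]

#: Fixed VOI identifiers used in feature-table column names and label maps.
VOI_NAMES = ("LUNG_TOTAL", "LUNG_IPSI", "PTV2CM")

#: Default PTV expansion margin, mm.
PTV_MARGIN_MM = 20.0


@dataclass(frozen=True)
class VOISet:
    """The three analysis VOIs of one case."""

    lung_total_minus_gtv: Mask3D
    lung_ipsi_minus_gtv: Mask3D
    ptv_plus_2cm: Mask3D

    def as_dict(self) -> dict:
        return {
            "LUNG_TOTAL": self.lung_total_minus_gtv,
            "LUNG_IPSI": self.lung_ipsi_minus_gtv,
            "PTV2CM": self.ptv_plus_2cm,
        }


def isotropic_expand(mask: Mask3D, margin_mm: float) -> Mask3D:
    """Expand ``mask`` by a Euclidean margin given in millimetres.

    A voxel belongs to the output iff the distance from its centre to the
    nearest voxel of the input set is <= ``margin_mm``.  The expansion is
    clipped at the grid bounds.
    """
    if mask.is_empty():
        raise ValueError("cannot expand an empty mask")
    if margin_mm < 0:
        raise ValueError(f"margin must be non-negative, got {margin_mm}")
    # distance of every background voxel to the mask, in mm
    dist = ndimage.distance_transform_edt(~mask.values, sampling=mask.spacing)
    return mask.with_values(dist <= margin_mm)


def ipsilateral_lung(lung_left: Mask3D, lung_right: Mask3D, gtv: Mask3D) -> Mask3D:
    """Select the tumor-bearing lung.

    The lung with the larger voxel overlap with the GTV wins; with zero
    overlap on both sides (central tumors) the lung whose centroid lies
    nearer the GTV centroid is returned.  Exact ties break toward the
    larger overlap *fraction* of the lung, then toward the left lung.
    """
    if gtv.is_empty():
        raise ValueError("GTV mask is empty")
    if lung_left.is_empty() and lung_right.is_empty():
        raise ValueError("both lung masks are empty")
    if lung_left.is_empty():
        return lung_right
    if lung_right.is_empty():
        return lung_left

    ov_l = int((gtv.values & lung_left.values).sum())
    ov_r = int((gtv.values & lung_right.values).sum())
    if ov_l != ov_r:
        return lung_left if ov_l > ov_r else lung_right
    if ov_l > 0:  # equal positive overlap: larger overlap fraction, then left
        frac_l = ov_l / lung_left.count()
        frac_r = ov_r / lung_right.count()
        return lung_right if frac_r > frac_l else lung_left
    # no overlap anywhere: physical centroid distance
    spacing = np.asarray(gtv.spacing)
    c_gtv = np.array(ndimage.center_of_mass(gtv.values)) * spacing
    c_l = np.array(ndimage.center_of_mass(lung_left.values)) * spacing
    c_r = np.array(ndimage.center_of_mass(lung_right.values)) * spacing
    d_l = float(np.linalg.norm(c_gtv - c_l))
    d_r = float(np.linalg.norm(c_gtv - c_r))
    return lung_right if d_r < d_l else lung_left


def build_vois(
    case: PatientCase,
    *,
    ptv_margin_mm: float = PTV_MARGIN_MM,
    intersect_ptv_with_lung: bool = False,
) -> VOISet:
    """Build the VOISet of one case.

    ``ptv_plus_2cm`` is by default not intersected with the lungs; pass
    ``intersect_ptv_with_lung=True`` for a sensitivity analysis restricted
    to lung tissue.
    """
    gtv = case.masks["gtv"]
    lungs = case.masks["lung_left"] | case.masks["lung_right"]
    lung_total = lungs - gtv
    ipsi = ipsilateral_lung(case.masks["lung_left"], case.masks["lung_right"], gtv) - gtv
    ptv2 = isotropic_expand(case.masks["ptv"], ptv_margin_mm)
    if intersect_ptv_with_lung:
        ptv2 = ptv2 & lungs
    for name, voi in (
        ("lung_total_minus_gtv", lung_total),
        ("lung_ipsi_minus_gtv", ipsi),
        ("ptv_plus_2cm", ptv2),
    ):
        if voi.is_empty():
            raise ValueError(f"VOI {name!r} is empty for case {case.case_id}")
    return VOISet(lung_total_minus_gtv=lung_total, lung_ipsi_minus_gtv=ipsi, ptv_plus_2cm=ptv2)
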