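"""Cohort-level feature extraction into a cases x features table.

For each case, each of the three VOIs and each requested modality
(CT, physical dose, EQD2 dose), the full 104-feature registry is
evaluated, yielding 312 columns per modality.  3D dose maps are treated
as images with Gy values as grey levels.  Columns are named
``MODALITY__VOI__family__name``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..core import Mask3D, PatientCase, Volume3D
from ..dose import eqd2_voxelwise
from ..roi import VOISet, build_vois
from .discretize import discretize
from .firstorder import first_order_features
from .matrices import matrix_features
from .registry import FAMILIES, REGISTRY_VERSION, feature_names
from .shape import shape_features

__all__ = [
    "MODALITIES",
    "DEFAULT_BIN_WIDTHS",
    "ExtractionSettings",
    "extract_case_features",
    "extract_feature_table",
]

log = logging.getLogger(__name__)

MODALITIES = ("CT", "DOSE_PHYS", "DOSE_EQD2")

#: Fixed-bin-width defaults: 25 HU for CT, 0.5 Gy for dose grids.
DEFAULT_BIN_WIDTHS = {"CT": 25.0, "DOSE_PHYS": 0.5, "DOSE_EQD2": 0.5}


@dataclass(frozen=True)
class ExtractionSettings:
    bin_widths: dict = None  # modality -> bin width
    families: tuple | None = None  # None = full registry
    alpha_beta: float = 3.0

    def __post_init__(self):
        if self.bin_widths is None:
            object.__setattr__(self, "bin_widths", dict(DEFAULT_BIN_WIDTHS))

    def provenance(self) -> dict:
        return {
            "registry_version": REGISTRY_VERSION,
            "bin_widths": dict(self.bin_widths),
            "families": list(self.families) if self.families else sorted(FAMILIES),
            "alpha_beta": self.alpha_beta,
        }


def _crop_to_bbox(volume: Volume3D, voi: Mask3D, pad: int = 1):
    """Restrict both grids to the VOI bounding box (plus a pad) — texture
    matrices only see in-VOI voxels, so this is a pure speed-up."""
    idx = np.argwhere(voi.values)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, voi.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    vol = Volume3D(volume.values[sl], volume.spacing, volume.origin)
    msk = Mask3D(voi.values[sl], voi.spacing, voi.origin)
    return vol, msk


def _voi_features(volume: Volume3D, voi: Mask3D, bin_width: float, families) -> dict:
    vol_c, voi_c = _crop_to_bbox(volume, voi)
    out: dict[str, float] = {}
    wanted = set(families) if families else set(FAMILIES)
    if "shape" in wanted:
        out.update({f"shape__{k}": v for k, v in shape_features(voi_c).items()})
    if "firstorder" in wanted:
        out.update(
            {f"firstorder__{k}": v for k, v in first_order_features(vol_c, voi_c, bin_width).items()}
        )
    matrix_wanted = wanted & {"glcm", "glrlm", "glszm", "gldm", "ngtdm"}
    if matrix_wanted:
        grid = discretize(vol_c, voi_c, bin_width)
        for key, value in matrix_features(grid).items():
            if key.split("__", 1)[0] in matrix_wanted:
                out[key] = value
    return out


def extract_case_features(
    case: PatientCase,
    vois: VOISet,
    modality: str,
    settings: ExtractionSettings | None = None,
) -> dict:
    """All registry features of one case for one modality."""
    settings = settings or ExtractionSettings()
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    if modality == "CT":
        volume = case.ct
    elif modality == "DOSE_PHYS":
        volume = case.dose
    else:
        volume = eqd2_voxelwise(case.dose, case.fractionation.n_fractions, settings.alpha_beta)
    bin_width = settings.bin_widths[modality]
    out = {}
    for voi_name, voi in vois.as_dict().items():
        feats = _voi_features(volume, voi, bin_width, settings.families)
        for key, value in feats.items():
            if not np.isfinite(value):  # degenerate-VOI policy: impute 0, warn
                warnings.warn(
                    f"non-finite feature {key} in VOI {voi_name} of case {case.case_id}; set to 0"
                )
                value = 0.0
            out[f"{modality}__{voi_name}__{key}"] = float(value)
    return out


def extract_feature_table(
    cohort: list,
    voisets: list,
    modality: str,
    settings: ExtractionSettings | None = None,
) -> pd.DataFrame:
    """Cohort feature table for one modality: one row per case, columns
    ``modality__voi__family__name`` (104 features x 3 VOIs = 312 columns
    with the full registry)."""
    settings = settings or ExtractionSettings()
    if len(cohort) != len(voisets):
        raise ValueError("cohort and voisets length mismatch")
    rows = {}
    for case, vois in zip(cohort, voisets):
        rows[case.case_id] = extract_case_features(case, vois, modality, settings)
    table = pd.DataFrame.from_dict(rows, orient="index")
    expected = [
        f"{modality}__{voi}__{feat}"
        for voi in ("LUNG_TOTAL", "LUNG_IPSI", "PTV2CM")
        for feat in feature_names(settings.families)
    ]
    table = table[expected]
    table.attrs["provenance"] = settings.provenance()
    return table
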