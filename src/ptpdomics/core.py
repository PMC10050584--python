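"""Core domain containers shared by every pipeline stage.

Volumes are axis-aligned scalar grids with physical voxel spacing in
millimetres; masks are binary grids tied to a reference volume geometry.
A :class:`PatientCase` bundles one subject's planning CT, 3D dose grid,
segmentation masks, fractionation scheme, clinical record and the binary
post-treatment pneumonitis (PTP) label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "Volume3D",
    "Mask3D",
    "FractionationScheme",
    "ClinicalRecord",
    "PatientCase",
    "GeometryError",
    "LOCATIONS",
]

#: Tumor location categories: the five lobes plus right/left central.
LOCATIONS = ("RUL", "RML", "RLL", "LUL", "LLL", "RC", "LC")

#: Spacing agreement tolerance between grids of one case, in mm.
SPACING_TOL_MM = 1e-3


class GeometryError(ValueError):
    """Grid geometry (shape/spacing/origin) mismatch or invalid mask content."""


@dataclass(frozen=True)
class Volume3D:
    """A 3D scalar grid (HU for CT, Gy for dose) with physical geometry.

    Parameters
    ----------
    values
        3D array, axis order (z, y, x).
    spacing
        Per-axis voxel spacing in mm, strictly positive, same axis order.
    origin
        Physical coordinate of the first voxel centre, in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise GeometryError(f"expected a 3D grid, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise GeometryError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "Volume3D | Mask3D", tol: float = SPACING_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def with_values(self, values: np.ndarray) -> "Volume3D":
        return replace(self, values=values)


@dataclass(frozen=True)
class Mask3D:
    """A binary VOI grid aligned to a reference :class:`Volume3D`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise GeometryError(f"expected a 3D mask, got ndim={values.ndim}")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise GeometryError(f"mask values must be binary, found {uniq[:10]}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "values", values.astype(bool))
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not bool(self.values.any())

    def same_geometry(self, other: "Volume3D | Mask3D", tol: float = SPACING_TOL_MM) -> bool:
        return Volume3D.same_geometry(self, other, tol)  # type: ignore[arg-type]

    def with_values(self, values: np.ndarray) -> "Mask3D":
        return replace(self, values=values)

    def __and__(self, other: "Mask3D") -> "Mask3D":
        return self.with_values(self.values & other.values)

    def __or__(self, other: "Mask3D") -> "Mask3D":
        return self.with_values(self.values | other.values)

    def __sub__(self, other: "Mask3D") -> "Mask3D":
        return self.with_values(self.values & ~other.values)

    def issubset(self, other: "Mask3D") -> bool:
        return bool(np.all(other.values[self.values]))


@dataclass(frozen=True)
class FractionationScheme:
    """Total prescription dose (Gy) delivered in ``n_fractions`` fractions."""

    n_fractions: int
    prescription_dose: float

    def __post_init__(self) -> None:
        if int(self.n_fractions) < 1:
            raise ValueError(f"n_fractions must be >= 1, got {self.n_fractions}")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be positive")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        object.__setattr__(self, "prescription_dose", float(self.prescription_dose))

    @property
    def fraction_dose(self) -> float:
        """Prescribed dose per fraction, Gy."""
        return self.prescription_dose / self.n_fractions


@dataclass(frozen=True)
class ClinicalRecord:
    """Pre-treatment clinical covariates of one subject."""

    age: float
    sex: str                 # "M" or "F"
    kpi: float               # Karnofsky performance index, percent
    tumor_size: float        # volume in mm^3
    location: str            # one of LOCATIONS
    ici: bool                # immune checkpoint inhibitor therapy
    prior_ctx: bool          # prior chemotherapy

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not 0 <= self.kpi <= 100:
            raise ValueError(f"KPI must lie in [0, 100], got {self.kpi}")
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}, got {self.location!r}")
        if self.tumor_size <= 0:
            raise ValueError("tumor_size must be positive")

    def as_dict(self) -> dict:
        return {
            "age": self.age,
            "sex": self.sex,
            "kpi": self.kpi,
            "tumor_size": self.tumor_size,
            "location": self.location,
            "ici": bool(self.ici),
            "prior_ctx": bool(self.prior_ctx),
        }


@dataclass(frozen=True)
class PatientCase:
    """One subject: images, segmentations, fractionation, clinic, PTP label."""

    case_id: str
    ct: Volume3D
    dose: Volume3D
    masks: Mapping[str, Mask3D]  # keys: gtv, ptv, lung_left, lung_right
    fractionation: FractionationScheme
    clinical: ClinicalRecord
    label: int

    REQUIRED_MASKS = ("gtv", "ptv", "lung_left", "lung_right")

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", int(self.label))
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")
        missing = [k for k in self.REQUIRED_MASKS if k not in self.masks]
        if missing:
            raise GeometryError(f"missing masks: {missing}")
        for name, mask in self.masks.items():
            if not self.ct.same_geometry(mask):
                raise GeometryError(f"mask {name!r} geometry differs from CT grid")
        if not self.ct.same_geometry(self.dose):
            raise GeometryError("dose grid geometry differs from CT grid")
        if np.any(self.dose.values < 0):
            raise ValueError("dose must be non-negative everywhere")

    def validate_anatomy(self) -> None:
        """Check GTV ⊆ PTV and GTV overlaps the lung union; raise otherwise."""
        gtv, ptv = self.masks["gtv"], self.masks["ptv"]
        if not gtv.issubset(ptv):
            raise ValueError(f"case {self.case_id}: GTV not contained in PTV")
        lungs = self.masks["lung_left"] | self.masks["lung_right"]
        if not bool((gtv.values & lungs.values).any()):
            raise ValueError(f"case {self.case_id}: GTV does not overlap the lungs")
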