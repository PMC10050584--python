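"""On-disk cohort representation: NIfTI volumes plus a CSV manifest.

Each case is a directory of NIfTI files (``ct``, ``dose`` and the four
masks); the cohort manifest holds one row per case with file paths,
fractionation, clinical columns and the outcome label.  Arrays use axis
order (z, y, x); the affine stores the voxel spacing on its diagonal.
Spacing mismatches up to 1e-3 mm between grids of one case are accepted.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    ClinicalRecord,
    FractionationScheme,
    GeometryError,
    Mask3D,
    PatientCase,
    Volume3D,
)

__all__ = ["write_case", "write_cohort", "read_case", "read_cohort", "MANIFEST_NAME"]

MANIFEST_NAME = "manifest.csv"
_MASK_KEYS = ("gtv", "ptv", "lung_left", "lung_right")


def _save(path: Path, values: np.ndarray, spacing) -> None:
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def _load(path: Path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in np.abs(np.diag(img.affine)[:3]))
    return np.asarray(img.get_fdata(), dtype=np.float64), spacing


def write_case(case: PatientCase, out_dir: str | Path) -> dict:
    """Write one case; returns its manifest row (paths relative to out_dir's parent)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    _save(out_dir / "ct.nii.gz", case.ct.values, case.ct.spacing)
    _save(out_dir / "dose.nii.gz", case.dose.values, case.dose.spacing)
    paths["ct_path"] = str(out_dir / "ct.nii.gz")
    paths["dose_path"] = str(out_dir / "dose.nii.gz")
    for key in _MASK_KEYS:
        p = out_dir / f"mask_{key}.nii.gz"
        _save(p, case.masks[key].values.astype(np.uint8), case.masks[key].spacing)
        paths[f"{key}_path"] = str(p)
    row = {"case_id": case.case_id, **paths}
    row.update(
        {
            "n_fractions": case.fractionation.n_fractions,
            "prescription_dose": case.fractionation.prescription_dose,
            **case.clinical.as_dict(),
            "label": case.label,
        }
    )
    return row


def write_cohort(cases: list, out_dir: str | Path) -> Path:
    """Write all cases plus the cohort manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = [write_case(case, out_dir / case.case_id) for case in cases]
    manifest = out_dir / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_case(row: dict | pd.Series) -> PatientCase:
    """Reconstruct and validate a PatientCase from one manifest row."""
    ct_values, ct_spacing = _load(Path(row["ct_path"]))
    ct = Volume3D(ct_values, ct_spacing)
    dose_values, dose_spacing = _load(Path(row["dose_path"]))
    dose = Volume3D(dose_values, dose_spacing)
    if not ct.same_geometry(dose):
        raise GeometryError(
            f"dose grid {row['dose_path']} does not match the CT geometry"
        )
    masks = {}
    for key in _MASK_KEYS:
        path = Path(row[f"{key}_path"])
        values, spacing = _load(path)
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise GeometryError(f"mask file {path} is not binary (values {uniq[:5]})")
        mask = Mask3D(values.astype(bool), spacing)
        if not ct.same_geometry(mask):
            raise GeometryError(f"mask file {path} does not match the CT geometry")
        masks[key] = mask
    clinical = ClinicalRecord(
        age=float(row["age"]),
        sex=str(row["sex"]),
        kpi=float(row["kpi"]),
        tumor_size=float(row["tumor_size"]),
        location=str(row["location"]),
        ici=bool(row["ici"]),
        prior_ctx=bool(row["prior_ctx"]),
    )
    case = PatientCase(
        case_id=str(row["case_id"]),
        ct=ct,
        dose=dose,
        masks=masks,
        fractionation=FractionationScheme(
            n_fractions=int(row["n_fractions"]),
            prescription_dose=float(row["prescription_dose"]),
        ),
        clinical=clinical,
        label=int(row["label"]),
    )
    case.validate_anatomy()
    return case


def read_cohort(manifest_path: str | Path) -> list:
    manifest = pd.read_csv(manifest_path)
    return [read_case(row) for _, row in manifest.iterrows()]
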