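"""End-to-end orchestration: cohort -> VOIs -> features -> selection ->
nested-CV benchmark -> run report.

Nine feature-set recipes are constructible: the four single sets
(radiomics, dosiomics, clinical, dvh) and the five combinations
(dosiomics+radiomics, dvh+clinical, radiomics+dvh+clinical,
dosiomics+dvh+clinical, all).  For combined recipes the per-group
preselected features are concatenated and fed through the same selection
procedure again.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balance import ResampleSpec
from .core import LOCATIONS, PatientCase
from .dose import dvh_metrics, eqd2_voxelwise
from .evaluate import default_grids, default_models, nested_cv_evaluate, rank_models, summarize
from .features import ExtractionSettings, extract_feature_table
from .io import read_cohort, write_cohort
from .roi import build_vois
from .selection import bootstrap_select, pearson_filter
from .synthetic import EffectSpec, PhantomParams, generate_cohort

__all__ = [
    "RunConfig",
    "FEATURE_SET_RECIPES",
    "clinical_table",
    "dvh_table",
    "assemble_feature_set",
    "run_pipeline",
]

log = logging.getLogger(__name__)

#: recipe -> constituent groups
FEATURE_SET_RECIPES = {
    "radiomics": ("radiomics",),
    "dosiomics": ("dosiomics",),
    "clinical": ("clinical",),
    "dvh": ("dvh",),
    "dosiomics+radiomics": ("dosiomics", "radiomics"),
    "dvh+clinical": ("dvh", "clinical"),
    "radiomics+dvh+clinical": ("radiomics", "dvh", "clinical"),
    "dosiomics+dvh+clinical": ("dosiomics", "dvh", "clinical"),
    "all": ("radiomics", "dosiomics", "dvh", "clinical"),
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    # cohort source: exactly one of the two
    manifest: str | None = None
    n_cases: int = 110
    n_events: int = 24
    effect: dict = field(default_factory=dict)       # EffectSpec fields
    phantom: dict = field(default_factory=dict)      # PhantomParams overrides

    dose_modality: str = "DOSE_PHYS"                 # or DOSE_EQD2
    feature_sets: tuple = ("dosiomics+radiomics",)
    selection: str = "bootstrap"                     # bootstrap | pearson | none
    n_boot: int = 1000
    smote: bool = True
    models: tuple = ("rf", "glmnet", "svmRadial", "logitBoost")
    n_iter: int = 100
    k_folds: int = 5
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        unknown = set(self.feature_sets) - set(FEATURE_SET_RECIPES)
        if unknown:
            raise ValueError(f"unknown feature set recipes: {sorted(unknown)}")
        if self.dose_modality not in ("DOSE_PHYS", "DOSE_EQD2"):
            raise ValueError(f"dose_modality must be DOSE_PHYS or DOSE_EQD2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data["feature_sets"] = tuple(data.get("feature_sets", ("dosiomics+radiomics",)))
        data["models"] = tuple(data.get("models", ("rf", "glmnet", "svmRadial", "logitBoost")))
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def clinical_table(cases: list) -> pd.DataFrame:
    """Encode clinical covariates: numeric age/KPI, binary sex/ICI/prior
    chemotherapy, log-transformed tumor size, one-hot tumor location."""
    rows = {}
    for case in cases:
        c = case.clinical
        row = {
            "clin__age": c.age,
            "clin__sex_male": 1.0 if c.sex == "M" else 0.0,
            "clin__kpi": c.kpi,
            "clin__log_tumor_size": float(np.log(c.tumor_size)),
            "clin__ici": float(c.ici),
            "clin__prior_ctx": float(c.prior_ctx),
        }
        for loc in LOCATIONS:
            row[f"clin__loc_{loc}"] = 1.0 if c.location == loc else 0.0
        rows[case.case_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def dvh_table(cases: list, voisets: list, modality: str = "DOSE_PHYS") -> pd.DataFrame:
    """DVH metrics (mean dose, V5..V50) of the total-lung-minus-GTV VOI."""
    rows = {}
    for case, vois in zip(cases, voisets):
        dose = case.dose
        if modality == "DOSE_EQD2":
            dose = eqd2_voxelwise(dose, case.fractionation.n_fractions)
        metrics = dvh_metrics(dose, vois.lung_total_minus_gtv)
        rows[case.case_id] = metrics.as_dict()
    return pd.DataFrame.from_dict(rows, orient="index")


def _select(table: pd.DataFrame, labels, config: RunConfig, seed: int):
    """Apply the configured reduction; returns (reduced table, report|None)."""
    if config.selection == "none" or table.shape[1] <= 2:
        return table, None
    if config.selection == "pearson":
        return pearson_filter(table), None
    report = bootstrap_select(table, labels, n_boot=config.n_boot, seed=seed)
    if not report.final_set:
        log.warning("selection produced an empty set; falling back to Pearson filter")
        return pearson_filter(table), report
    return table[report.final_set], report


def assemble_feature_set(
    recipe: str,
    group_tables: dict,
    labels,
    config: RunConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Build the input table of one recipe.

    Single-group recipes are reduced directly.  Combined recipes first
    reduce each constituent group, then concatenate the preselected
    columns and reduce again with the same procedure.
    """
    groups = FEATURE_SET_RECIPES[recipe]
    reports = {}
    if len(groups) == 1:
        reduced, report = _select(group_tables[groups[0]], labels, config, seed)
        reports[groups[0]] = report
        return reduced, reports
    parts = []
    for i, group in enumerate(groups):
        reduced, report = _select(group_tables[group], labels, config, seed + i)
        reports[group] = report
        parts.append(reduced)
    combined = pd.concat(parts, axis=1)
    reduced, report = _select(combined, labels, config, seed + len(groups))
    reports["combined"] = report
    return reduced, reports


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and persist the artifacts; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = config.seed

    # --- cohort
    if config.manifest:
        cases = read_cohort(config.manifest)
    else:
        cases = generate_cohort(
            config.n_cases,
            config.n_events,
            EffectSpec(**config.effect),
            seed=rng_seed,
            params=PhantomParams(**config.phantom),
        )
    labels = np.array([c.label for c in cases])
    for case in cases:
        case.validate_anatomy()

    # --- VOIs and tables
    voisets = [build_vois(c) for c in cases]
    settings = ExtractionSettings()
    group_tables = {
        "radiomics": extract_feature_table(cases, voisets, "CT", settings),
        "dosiomics": extract_feature_table(cases, voisets, config.dose_modality, settings),
        "clinical": clinical_table(cases),
        "dvh": dvh_table(cases, voisets, config.dose_modality),
    }
    for name, tbl in group_tables.items():
        tbl.to_csv(out / f"features_{name}.csv")
    with open(out / "provenance.json", "w") as fh:
        json.dump(settings.provenance(), fh, indent=2)

    # --- selection + nested CV per recipe
    models = {m: default_models()[m] for m in config.models}
    grids = {m: default_grids()[m] for m in config.models}
    resample = ResampleSpec() if config.smote else None
    all_records = []
    summaries = []
    selection_reports = {}
    for recipe in config.feature_sets:
        table, reports = assemble_feature_set(
            recipe, group_tables, labels, config, seed=rng_seed
        )
        selection_reports[recipe] = {
            k: (None if r is None else {"median_confirmed": r.median_confirmed,
                                        "final_set": r.final_set})
            for k, r in reports.items()
        }
        cv = nested_cv_evaluate(
            table,
            labels,
            models=models,
            grids=grids,
            n_iter=config.n_iter,
            k=config.k_folds,
            seed=rng_seed,
            resample=resample,
            feature_set=recipe,
        )
        all_records.append(cv.records)
        summaries.append(summarize(cv))

    records = pd.concat(all_records, ignore_index=True)
    records.to_csv(out / "cv_records.csv", index=False)
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(out / "cv_summary.csv", index=False)

    report = {
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_cases": len(cases),
        "prevalence": float(labels.mean()),
        "selection": selection_reports,
        "summary": summary.to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
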