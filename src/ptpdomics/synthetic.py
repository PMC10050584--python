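"""Synthetic thoracic phantom cohorts with planted outcome signal.

Each phantom has two ellipsoidal lungs inside a soft-tissue body, a
spherical GTV placed inside one lung, a PTV obtained by isotropic
expansion with a margin drawn in (0, 5] mm, a prescription-dose plateau
over the PTV with sigmoidal radial falloff, and CT/dose noise textures.

The outcome signal is planted through two per-case latent variables:
``z_dose`` scales the correlation length of the dose speckle texture
(coarser vs finer speckle; a histogram-preserving remap makes DVH
metrics exactly invariant to this dial) and ``z_ct`` scales the
amplitude of the CT texture in a peri-PTV lung shell.  A logistic utility on the latents
(plus optional clinical terms) ranks the cases; the top ``n_events``
cases are labelled positive, so prevalence is exact for every seed.
With an all-zero effect specification the ranking is pure logistic
noise and the labels are exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import ClinicalRecord, FractionationScheme, Mask3D, PatientCase, Volume3D
from .roi import isotropic_expand

__all__ = [
    "PhantomParams",
    "EffectSpec",
    "PlacementError",
    "generate_case",
    "generate_cohort",
]


class PlacementError(RuntimeError):
    """The GTV sphere could not be placed inside a lung."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and texture parameters of one phantom case.

    Defaults are desk-scale: a 64x64x48 voxel grid at 2x2x3 mm (axis
    order z, y, x -> shape (48, 64, 64)).
    """

    shape: tuple = (48, 64, 64)
    spacing: tuple = (3.0, 2.0, 2.0)  # mm, (z, y, x)

    # anatomy (mm semi-axes; centres as fractions of the field of view)
    lung_semiaxes: tuple = (55.0, 32.0, 22.0)
    lung_centers_frac: tuple = ((0.5, 0.5, 0.29), (0.5, 0.5, 0.71))
    body_semiaxes: tuple = (75.0, 55.0, 60.0)

    gtv_radius_range: tuple = (7.0, 13.0)   # mm
    ptv_margin_range: tuple = (0.0, 5.0)    # mm, open at 0

    # fractionation: per-fraction dose uniform in [5, 15] Gy
    fraction_dose_range: tuple = (5.0, 15.0)
    n_fractions_choices: tuple = (3, 5, 8)

    # dose model
    penumbra_mm: float = 7.0        # sigmoid falloff width
    penumbra_offset_mm: float = 14.0  # distance of the 50% isodose from the PTV surface
    dose_speckle_amp: float = 0.08  # relative speckle amplitude at scale 1
    dose_speckle_corr_mm: float = 4.0

    # CT model (HU)
    hu_air: float = -1000.0
    hu_body: float = 30.0
    hu_lung: float = -800.0
    hu_gtv: float = 20.0
    ct_noise_sd: float = 25.0       # global correlated noise
    ct_shell_sd: float = 60.0       # peri-PTV shell texture at scale 1
    ct_shell_width_mm: float = 15.0
    ct_corr_mm: float = 3.0

    # per-case texture dials (the planted-signal covariates):
    # dose_texture_scale multiplies the speckle correlation length,
    # ct_texture_scale multiplies the shell texture amplitude
    dose_texture_scale: float = 1.0
    ct_texture_scale: float = 1.0

    max_placement_attempts: int = 50


@dataclass(frozen=True)
class EffectSpec:
    """Logistic coefficients linking latents/clinical terms to the label."""

    beta_dose_texture: float = 0.0
    beta_ct_texture: float = 0.0
    beta_age: float = 0.0

    @classmethod
    def zero(cls) -> "EffectSpec":
        return cls()

    @classmethod
    def planted(cls) -> "EffectSpec":
        """Strong dose + CT texture signal used for recovery studies."""
        return cls(beta_dose_texture=2.5, beta_ct_texture=2.5)

    def is_zero(self) -> bool:
        return self.beta_dose_texture == self.beta_ct_texture == self.beta_age == 0.0


def _correlated_field(rng: np.random.Generator, shape, spacing, corr_mm: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with a physical
    correlation length."""
    white = rng.standard_normal(shape)
    sigmas = [max(corr_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigmas)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _ellipsoid(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center_mm, semiaxes_mm):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _sample_clinical(rng: np.random.Generator, side: str, gtv_volume_mm3: float) -> ClinicalRecord:
    age = float(np.clip(rng.normal(72.0, 10.5), 33.0, 90.0))
    sex = "M" if rng.random() < 0.627 else "F"
    kpi = float(rng.choice([80.0, 90.0, 100.0], p=[0.15, 0.35, 0.5]))
    if side == "right":
        location = str(rng.choice(["RUL", "RML", "RLL", "RC"], p=[0.50, 0.03, 0.42, 0.05]))
    else:
        location = str(rng.choice(["LUL", "LLL", "LC"], p=[0.72, 0.22, 0.06]))
    return ClinicalRecord(
        age=age,
        sex=sex,
        kpi=kpi,
        tumor_size=gtv_volume_mm3,
        location=location,
        ici=bool(rng.random() < 0.10),
        prior_ctx=bool(rng.random() < 0.045),
    )


def generate_case(params: PhantomParams, seed: int, case_id: str = "case") -> PatientCase:
    """Generate one phantom case (label 0; cohort assembly assigns labels)."""
    rng = np.random.default_rng(seed)
    shape, spacing = tuple(params.shape), tuple(params.spacing)
    fov = [n * s for n, s in zip(shape, spacing)]

    body = _ellipsoid(shape, spacing, [f * 0.5 for f in fov], params.body_semiaxes)
    lung_masks = []
    for frac in params.lung_centers_frac:
        center = [f * c for f, c in zip(fov, frac)]
        lung_masks.append(_ellipsoid(shape, spacing, center, params.lung_semiaxes) & body)
    lung_left_arr, lung_right_arr = lung_masks  # first centre is the left lung (low x)

    # --- GTV placement: sphere fully inside one lung, bounded attempts
    side = "left" if rng.random() < 0.5 else "right"
    lung_arr = lung_left_arr if side == "left" else lung_right_arr
    interior_mm = ndimage.distance_transform_edt(lung_arr, sampling=spacing)
    gtv_arr = None
    radius = 0.0
    for _ in range(params.max_placement_attempts):
        radius = float(rng.uniform(*params.gtv_radius_range))
        candidates = np.argwhere(interior_mm >= radius)
        if len(candidates) == 0:
            continue
        center_vox = candidates[rng.integers(len(candidates))]
        center_mm = center_vox * np.asarray(spacing)
        gtv_arr = _ellipsoid(shape, spacing, center_mm, (radius, radius, radius))
        if gtv_arr.any():
            break
        gtv_arr = None
    if gtv_arr is None:
        raise PlacementError(
            f"could not place a GTV of radius in {params.gtv_radius_range} mm "
            f"inside the {side} lung after {params.max_placement_attempts} attempts"
        )

    gtv = Mask3D(gtv_arr, spacing)
    lo, hi = params.ptv_margin_range
    if hi <= 0:
        raise ValueError("ptv_margin_range upper bound must be positive")
    margin = 0.0
    while margin <= lo:  # open lower bound: margin in (lo, hi]
        margin = float(rng.uniform(lo, hi))
    ptv = isotropic_expand(gtv, margin)

    # --- fractionation
    d_fx = float(rng.uniform(*params.fraction_dose_range))
    n_fx = int(rng.choice(params.n_fractions_choices))
    fractionation = FractionationScheme(n_fractions=n_fx, prescription_dose=d_fx * n_fx)

    # --- dose: prescription plateau over the PTV, sigmoid falloff outside
    outside = ndimage.distance_transform_edt(~ptv.values, sampling=spacing)
    inside = ndimage.distance_transform_edt(ptv.values, sampling=spacing)
    signed = outside - inside  # mm, negative inside the PTV
    falloff = 1.0 / (1.0 + np.exp((signed - params.penumbra_offset_mm) / params.penumbra_mm))
    dose_arr = fractionation.prescription_dose * falloff
    corr_mm = params.dose_speckle_corr_mm * params.dose_texture_scale
    speckle = _correlated_field(rng, shape, spacing, corr_mm)
    textured = dose_arr * (1.0 + params.dose_speckle_amp * speckle)
    # histogram-preserving remap, stratified by the DVH evaluation region
    # (lung minus GTV vs the rest): the textured field keeps its spatial
    # rank structure (the planted texture) but each stratum takes the
    # smooth falloff's exact value multiset, so lung DVH metrics are
    # invariant to the texture dials by construction
    dvh_region = (lung_left_arr | lung_right_arr) & ~gtv.values
    remapped = np.empty(shape)
    for region in (dvh_region, ~dvh_region):
        values = textured[region]
        order = np.argsort(values, kind="stable")
        slot = np.empty_like(values)
        slot[order] = np.sort(dose_arr[region])
        remapped[region] = slot
    dose_arr = remapped

    # --- CT: tissue bases + global correlated noise + peri-PTV shell texture
    ct_arr = np.full(shape, params.hu_air)
    ct_arr[body] = params.hu_body + rng.normal(0.0, 10.0)
    lungs_arr = lung_left_arr | lung_right_arr
    ct_arr[lungs_arr] = params.hu_lung + rng.normal(0.0, 15.0)
    ct_arr[gtv.values] = params.hu_gtv
    ct_arr = ct_arr + params.ct_noise_sd * _correlated_field(rng, shape, spacing, params.ct_corr_mm)
    shell = isotropic_expand(ptv, params.ct_shell_width_mm).values & ~ptv.values & lungs_arr
    shell_tex = _correlated_field(rng, shape, spacing, params.ct_corr_mm)
    ct_arr[shell] += params.ct_shell_sd * params.ct_texture_scale * shell_tex[shell]

    clinical = _sample_clinical(rng, side, gtv.count() * gtv.voxel_volume_mm3)
    return PatientCase(
        case_id=case_id,
        ct=Volume3D(ct_arr, spacing),
        dose=Volume3D(dose_arr, spacing),
        masks={
            "gtv": gtv,
            "ptv": ptv,
            "lung_left": Mask3D(lung_left_arr, spacing),
            "lung_right": Mask3D(lung_right_arr, spacing),
        },
        fractionation=fractionation,
        clinical=clinical,
        label=0,
    )


def generate_cohort(
    n: int,
    n_events: int,
    effect: EffectSpec | None = None,
    seed: int = 0,
    params: PhantomParams | None = None,
) -> list[PatientCase]:
    """Generate ``n`` cases with exactly ``n_events`` positive labels.

    Latent texture scales are drawn per case, injected into the phantom
    textures, and linked to the label through a noisy logistic utility;
    the ``n_events`` cases with the largest utilities become positive.
    """
    if not 0 <= n_events <= n:
        raise ValueError(f"n_events={n_events} infeasible for n={n}")
    effect = effect or EffectSpec.zero()
    params = params or PhantomParams()
    master = np.random.default_rng(seed)
    case_seeds = master.integers(0, 2**31 - 1, size=n)

    z_dose = master.standard_normal(n)
    z_ct = master.standard_normal(n)
    cases = []
    for i in range(n):
        p_i = replace(
            params,
            dose_texture_scale=params.dose_texture_scale * float(np.exp(0.35 * z_dose[i])),
            ct_texture_scale=params.ct_texture_scale * float(np.exp(0.5 * z_ct[i])),
        )
        cases.append(generate_case(p_i, int(case_seeds[i]), case_id=f"case{i:03d}"))

    ages = np.array([c.clinical.age for c in cases])
    z_age = (ages - ages.mean()) / ages.std() if ages.std() > 0 else np.zeros(n)
    utility = (
        effect.beta_dose_texture * z_dose
        + effect.beta_ct_texture * z_ct
        + effect.beta_age * z_age
        + master.logistic(size=n)
    )
    positive = np.argsort(-utility, kind="stable")[:n_events]
    labels = np.zeros(n, dtype=int)
    labels[positive] = 1
    return [replace(c, label=int(lab)) for c, lab in zip(cases, labels)]
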