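"""Radiobiological dose conversion and dose-volume-histogram metrics.

The linear-quadratic model expresses iso-effect between fractionation
schemes.  For a voxel that accumulated total dose ``D`` over ``n``
fractions (per-fraction dose ``d = D/n``) the equivalent dose in 2 Gy
fractions is

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)

with ``alpha/beta = 3 Gy`` the conventional value for late-responding
lung tissue.  At ``d = 2`` Gy the conversion is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Mask3D, Volume3D

__all__ = ["DEFAULT_ALPHA_BETA", "DVH_THRESHOLDS_GY", "DVHMetrics", "eqd2_voxelwise", "dvh_metrics"]

DEFAULT_ALPHA_BETA = 3.0
#: Vx thresholds reported for the total lung, Gy.
DVH_THRESHOLDS_GY = (5, 10, 15, 20, 30, 40, 50)


@dataclass(frozen=True)
class DVHMetrics:
    """Mean VOI dose plus Vx (percent of VOI volume receiving >= x Gy)."""

    mean_dose: float
    v_at: dict  # threshold Gy -> percent of VOI volume

    def as_dict(self) -> dict:
        out = {"dvh_mean": self.mean_dose}
        out.update({f"dvh_v{int(t)}": v for t, v in self.v_at.items()})
        return out


def eqd2_voxelwise(
    dose: Volume3D,
    n_fractions: int,
    alpha_beta: float = DEFAULT_ALPHA_BETA,
    *,
    fraction_dose: float | None = None,
) -> Volume3D:
    """Convert a total physical dose grid to EQD2, voxel by voxel.

    Parameters
    ----------
    dose
        Total physical dose over all fractions, Gy per voxel.
    n_fractions
        Number of fractions the dose was delivered in.
    alpha_beta
        Tissue sensitivity ratio in Gy (3 for lung).
    fraction_dose
        If given, use this uniform per-fraction dose ``d`` everywhere
        instead of the voxel-wise ``d = D / n_fractions``.  The voxel-wise
        convention is the default: each voxel's own accumulated dose is
        divided by the number of fractions.

    Returns
    -------
    Volume3D with identical geometry holding EQD2 values in Gy.
    """
    if int(n_fractions) < 1:
        raise ValueError(f"n_fractions must be >= 1, got {n_fractions}")
    if alpha_beta <= 0:
        raise ValueError(f"alpha/beta must be positive, got {alpha_beta}")
    total = dose.values
    if np.any(total < 0):
        raise ValueError("negative dose voxel encountered")
    if fraction_dose is None:
        d = total / float(n_fractions)
    else:
        if fraction_dose < 0:
            raise ValueError("fraction_dose must be non-negative")
        d = float(fraction_dose)
    eqd2 = total * (d + alpha_beta) / (2.0 + alpha_beta)
    return dose.with_values(eqd2)


def dvh_metrics(
    dose: Volume3D,
    voi: Mask3D,
    thresholds: tuple = DVH_THRESHOLDS_GY,
) -> DVHMetrics:
    """Mean dose and Vx metrics of ``dose`` restricted to ``voi``.

    Vx uses the inclusive convention ("receiving at least x Gy") and is
    expressed as percent of the VOI volume.
    """
    if voi.is_empty():
        raise ValueError("DVH metrics require a non-empty VOI")
    if not dose.same_geometry(voi):
        raise ValueError("VOI geometry does not match the dose grid")
    inside = dose.values[voi.values]
    n = inside.size
    v_at = {int(t): 100.0 * float(np.count_nonzero(inside >= t)) / n for t in thresholds}
    return DVHMetrics(mean_dose=float(inside.mean()), v_at=v_at)
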