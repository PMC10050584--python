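"""The frozen 104-feature registry.

The catalog mirrors the default feature set of the common open-source
radiomics engines: 13 shape, 18 first-order, 22 GLCM, 16 GLRLM, 16 GLSZM,
14 GLDM and 5 NGTDM features.  From the GLCM family, MCC (costly
eigen-decomposition) and SumAverage (equal to twice JointAverage for a
symmetric matrix) are excluded.  The registry is the source of truth for
feature-table column layout; its version string is written into every
provenance sidecar.
"""

from __future__ import annotations

from .firstorder import FIRSTORDER_NAMES
from .matrices import GLCM_NAMES, GLDM_NAMES, GLRLM_NAMES, GLSZM_NAMES, NGTDM_NAMES
from .shape import SHAPE_NAMES

__all__ = ["REGISTRY_VERSION", "FAMILIES", "N_FEATURES", "feature_names"]

REGISTRY_VERSION = "1.0"

FAMILIES: dict[str, tuple[str, ...]] = {
    "shape": SHAPE_NAMES,
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

#: Total registry size: 104 features per (modality, VOI) pair.
N_FEATURES = sum(len(v) for v in FAMILIES.values())


def feature_names(families: tuple[str, ...] | None = None) -> list[str]:
    """Flat ``family__name`` identifiers, optionally restricted to families."""
    selected = FAMILIES if families is None else {f: FAMILIES[f] for f in families}
    return [f"{family}__{name}" for family, names in selected.items() for name in names]


def _check() -> None:
    names = feature_names()
    assert len(names) == len(set(names)) == N_FEATURES == 104, N_FEATURES


_check()
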