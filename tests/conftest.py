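"""Shared fixtures: desk-scale phantom parameters and small cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ptpdomics.core import Mask3D, Volume3D
from ptpdomics.features.discretize import DiscretizedGrid
from ptpdomics.roi import build_vois
from ptpdomics.synthetic import EffectSpec, PhantomParams, generate_case, generate_cohort


def small_phantom_params(**overrides) -> PhantomParams:
    """Reduced 48x48x32-voxel phantom grid used throughout the tests."""
    defaults = dict(
        shape=(32, 48, 48),
        spacing=(3.0, 2.0, 2.0),
        lung_semiaxes=(45.0, 28.0, 18.0),
        lung_centers_frac=((0.5, 0.5, 0.28), (0.5, 0.5, 0.72)),
        body_semiaxes=(60.0, 46.0, 46.0),
        gtv_radius_range=(6.0, 11.0),
    )
    defaults.update(overrides)
    return PhantomParams(**defaults)


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    return small_phantom_params()


@pytest.fixture(scope="session")
def one_case(small_params):
    case = generate_case(small_params, seed=42, case_id="fixture")
    case.validate_anatomy()
    return case


@pytest.fixture(scope="session")
def one_voiset(one_case):
    return build_vois(one_case)


@pytest.fixture(scope="session")
def tiny_cohort(small_params):
    """Ten phantom cases with 3 events, shared across tests."""
    return generate_cohort(10, 3, EffectSpec.zero(), seed=7, params=small_params)


def random_level_grid(rng: np.random.Generator, max_side: int = 5, max_levels: int = 4):
    """Random discretized grid (levels 0..max_levels) for oracle checks."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    levels = rng.integers(0, max_levels + 1, size=shape)
    if not (levels > 0).any():
        levels.flat[0] = 1
    # relabel to contiguous 1..ng
    present = np.unique(levels[levels > 0])
    relabel = np.zeros(int(levels.max()) + 1, dtype=np.int64)
    for i, g in enumerate(present, start=1):
        relabel[g] = i
    levels = relabel[levels]
    return levels, len(present)


def as_discretized(levels: np.ndarray, ng: int, spacing=(1.0, 1.0, 1.0)) -> DiscretizedGrid:
    return DiscretizedGrid(levels=levels.astype(np.int64), n_levels=ng, bin_width=1.0, spacing=spacing)


def volume_and_mask(values: np.ndarray, mask: np.ndarray | None = None, spacing=(1.0, 1.0, 1.0)):
    vol = Volume3D(np.asarray(values, dtype=float), spacing)
    if mask is None:
        mask = np.ones_like(vol.values, dtype=bool)
    return vol, Mask3D(np.asarray(mask, dtype=bool), spacing)
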