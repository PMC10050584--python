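"""Grey-level discretization of a volume restricted to a VOI.

Fixed-bin-width binning referenced to the VOI minimum:

    g(v) = floor((x(v) - min_voi) / bin_width) + 1

Occupied bins are then relabelled to contiguous levels 1..Ng (empty bins
carry no voxels and would only pad the texture matrices).  A constant
region maps to the single level 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import Mask3D, Volume3D

__all__ = ["DiscretizedGrid", "discretize"]


@dataclass(frozen=True)
class DiscretizedGrid:
    """Integer grey-level grid: level 0 marks voxels outside the VOI."""

    levels: np.ndarray        # int grid, same shape as the input volume
    n_levels: int             # Ng, number of occupied levels
    bin_width: float
    spacing: tuple[float, float, float]

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


def discretize(volume: Volume3D, voi: Mask3D, bin_width: float) -> DiscretizedGrid:
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if voi.is_empty():
        raise ValueError("cannot discretize an empty VOI")
    if not volume.same_geometry(voi):
        raise ValueError("VOI geometry does not match the volume")
    values = volume.values[voi.values]
    raw = np.floor((values - values.min()) / bin_width).astype(np.int64) + 1
    # relabel occupied bins to contiguous 1..Ng, preserving order
    occupied = np.unique(raw)
    lookup = {b: i + 1 for i, b in enumerate(occupied)}
    contiguous = np.vectorize(lookup.__getitem__, otypes=[np.int64])(raw)
    levels = np.zeros(volume.shape, dtype=np.int64)
    levels[voi.values] = contiguous
    return DiscretizedGrid(
        levels=levels,
        n_levels=int(occupied.size),
        bin_width=float(bin_width),
        spacing=volume.spacing,
    )
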