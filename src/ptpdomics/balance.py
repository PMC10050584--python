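"""SMOTE with paired majority undersampling (the classic R-ecosystem
semantics): minority oversampling plus majority downsampling.

For each minority sample, ``perc_over/100`` synthetic points are placed
uniformly at random on the segment to one of its ``k`` nearest minority
neighbours (Euclidean distance on z-scored columns; synthetic points are
mapped back to the original scale).  The majority class is then
downsampled without replacement to ``perc_under/100`` times the number
of synthetic points (capped at the available majority count).  The
output stacks original minority + synthetic + retained majority rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["ResampleSpec", "smote_resample"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResampleSpec:
    k_neighbors: int = 3
    perc_over: int = 200
    perc_under: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.perc_over % 100 != 0 or self.perc_over < 100:
            raise ValueError("perc_over must be a positive multiple of 100")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.perc_under < 0:
            raise ValueError("perc_under must be non-negative")


def smote_resample(
    features: np.ndarray, labels: np.ndarray, spec: ResampleSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Resample an imbalanced binary training set.

    Returns the resampled ``(features, labels)``.  The minority class is
    the rarer label; ties make the label 1 class the minority.
    """
    spec = spec or ResampleSpec()
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_resample requires exactly two classes")
    if counts[0] == counts[1]:
        minority_label = classes[np.argmax(classes)]
    else:
        minority_label = classes[np.argmin(counts)]
    x_min = x[y == minority_label]
    x_maj = x[y != minority_label]
    majority_label = classes[classes != minority_label][0]
    n_min = len(x_min)
    if n_min < 2:
        raise ValueError("SMOTE requires at least 2 minority samples")
    k = spec.k_neighbors
    if n_min <= k:
        k = n_min - 1
        log.warning("minority count %d <= k; reducing k to %d", n_min, k)

    rng = np.random.default_rng(spec.seed)

    # neighbour search on z-scored columns (minority statistics)
    mu = x_min.mean(axis=0)
    sd = x_min.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x_min - mu) / sd
    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    neighbours = np.argsort(d2, axis=1)[:, :k]

    per_sample = spec.perc_over // 100
    synthetic = np.empty((n_min * per_sample, x.shape[1]))
    row = 0
    for i in range(n_min):
        for _ in range(per_sample):
            j = neighbours[i, rng.integers(k)]
            gap = rng.random()
            synthetic[row] = x_min[i] + gap * (x_min[j] - x_min[i])
            row += 1
    n_syn = row

    n_keep = min(int(round(spec.perc_under / 100 * n_syn)), len(x_maj))
    keep = rng.choice(len(x_maj), size=n_keep, replace=False)
    x_out = np.vstack([x_min, synthetic, x_maj[keep]])
    y_out = np.concatenate(
        [
            np.full(n_min + n_syn, minority_label),
            np.full(n_keep, majority_label),
        ]
    )
    return x_out, y_out
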