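"""Two-dimensional feature map of the segment profile.

Each read-depth segment becomes a point (x, y):

* x — the segment's RD ratio: its value divided by the genome-wide level
  (mean of all segment values).  Reflects copy-number status globally;
  gains sit above 1, losses below.
* y — the signed mean difference between the segment's ratio and its
  adjacent segments' ratios.  Reflects local contrast, which exposes small
  clusters of aberrant segments that are unremarkable globally.

Both dimensions are min-max scaled into [0, 1] before any distance is
computed, so neither dominates the Euclidean metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .segmentation import RDSProfile


@dataclass(frozen=True)
class FeatureObject:
    """One segment's coordinates in the 2-D feature space."""

    index: int
    x: float
    y: float
    scaled_x: float
    scaled_y: float

    @property
    def point(self) -> tuple[float, float]:
        return (self.scaled_x, self.scaled_y)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        # degenerate dimension: centre all objects
        return np.full(values.shape, 0.5)
    return (values - lo) / (hi - lo)


def to_feature_space(
    rds_profile: RDSProfile | Sequence[float],
    ratio_center: str = "mean",
    diff_mode: str = "signed",
) -> list[FeatureObject]:
    """Map segment values to scaled (ratio, adjacent-difference) points.

    ``ratio_center`` chooses the denominator of the RD ratio ("mean" or
    "median" of all segment values); ``diff_mode`` chooses signed or
    absolute neighbour differences.  Boundary segments use their single
    neighbour.
    """
    if isinstance(rds_profile, RDSProfile):
        values = rds_profile.values
    else:
        values = np.asarray(rds_profile, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError(f"feature map requires >= 2 segments, got {n}")
    center = float(np.mean(values) if ratio_center == "mean" else np.median(values))
    if center == 0:
        raise ValueError("all-zero segment profile: RD ratio undefined")

    x = values / center
    y = np.empty(n)
    for i in range(n):
        neigh = [j for j in (i - 1, i + 1) if 0 <= j < n]
        diffs = [x[i] - x[j] for j in neigh]
        if diff_mode == "abs":
            diffs = [abs(d) for d in diffs]
        y[i] = float(np.mean(diffs))

    sx, sy = _minmax(x), _minmax(y)
    return [
        FeatureObject(index=i, x=float(x[i]), y=float(y[i]),
                      scaled_x=float(sx[i]), scaled_y=float(sy[i]))
        for i in range(n)
    ]


def from_coordinates(pairs: Sequence[tuple[float, float]]) -> list[FeatureObject]:
    """Bypass mode: accept already-transformed (x, y) pairs verbatim.

    The coordinates are taken as both raw and scaled values, bit-exactly;
    used for fixtures whose points are already in the unit square.
    """
    return [
        FeatureObject(index=i, x=float(px), y=float(py),
                      scaled_x=float(px), scaled_y=float(py))
        for i, (px, py) in enumerate(pairs)
    ]
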