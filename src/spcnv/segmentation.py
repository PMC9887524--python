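"""Total-variation denoising of the RD profile and collapse into segments.

Sequencing noise (alignment errors, sampling variance) is removed with the
1-D total-variation (ROF / fused-lasso) model

    minimize_x  (1/2) * sum_i (x_i - rd_i)^2  +  penalty * sum_i |x_{i+1} - x_i|

whose minimizer is piecewise constant.  Maximal runs of equal denoised
values become read-depth segments (RDS); each segment's value is the mean
of the *original* GC-corrected RD values it covers, so denoising decides
the breakpoints but not the level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rd_preprocess import RDProfile

MERGE_TOL = 1e-8  # absolute; guards float noise only, the solver is exact


@dataclass(frozen=True)
class RDSegment:
    """A maximal run of bins sharing one denoised level.

    ``start_bin``/``end_bin`` index the RD profile (inclusive); ``value``
    is the mean original RD over the member bins.
    """

    start_bin: int
    end_bin: int
    value: float
    chrom: str
    start: int
    end: int

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass(frozen=True)
class RDSProfile:
    """Consecutive, non-overlapping read-depth segments."""

    segments: tuple[RDSegment, ...]
    tv_penalty: float

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def values(self) -> np.ndarray:
        return np.array([s.value for s in self.segments], dtype=float)


def tv_denoise(rd_values: Sequence[float], tv_penalty: float) -> np.ndarray:
    """Exact 1-D total-variation denoising (Condat's direct algorithm).

    Returns the unique minimizer of the fused-lasso objective, exact up to
    floating-point rounding (no iterative tolerance).  O(n) in practice.
    """
    y = np.asarray(rd_values, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("rd_values must be a non-empty 1-D sequence")
    if tv_penalty < 0:
        raise ValueError(f"tv_penalty must be non-negative, got {tv_penalty}")
    n = y.size
    if tv_penalty == 0 or n == 1:
        return y.copy()

    lam = float(tv_penalty)
    x = np.empty(n)
    k = k0 = km = kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        while k < n - 1:
            if y[k + 1] + umin < vmin - lam:
                # negative jump: flush the running minorant segment
                x[k0 : km + 1] = vmin
                k = k0 = km = kp = km + 1
                vmin = y[k]
                vmax = y[k] + 2 * lam
                umin = lam
                umax = -lam
            elif y[k + 1] + umax > vmax + lam:
                # positive jump: flush the running majorant segment
                x[k0 : kp + 1] = vmax
                k = k0 = km = kp = kp + 1
                vmin = y[k] - 2 * lam
                vmax = y[k]
                umin = lam
                umax = -lam
            else:
                k += 1
                umin += y[k] - vmin
                umax += y[k] - vmax
                if umin >= lam:
                    vmin += (umin - lam) / (k - k0 + 1)
                    umin = lam
                    km = k
                if umax <= -lam:
                    vmax += (umax + lam) / (k - k0 + 1)
                    umax = -lam
                    kp = k
        if umin < 0:
            x[k0 : km + 1] = vmin
            k = k0 = km = km + 1
            vmin = y[k]
            umin = lam
            umax = y[k] + lam - vmax
        elif umax > 0:
            x[k0 : kp + 1] = vmax
            k = k0 = kp = kp + 1
            vmax = y[k]
            umax = -lam
            umin = y[k] - lam - vmin
        else:
            x[k0:n] = vmin + umin / (k - k0 + 1)
            return x


def default_tv_penalty(rd_values: Sequence[float], c: float = 2.0) -> float:
    """Noise-adaptive penalty: ``c`` times a robust noise-level estimate.

    The noise sigma is estimated from first differences of the profile as
    ``median(|diff|) / (0.6745 * sqrt(2))`` — the normal-consistent MAD
    estimator, insensitive to the (sparse) true copy-number jumps.
    """
    y = np.asarray(rd_values, dtype=float)
    if y.size < 2:
        return 0.0
    sigma = float(np.median(np.abs(np.diff(y)))) / (0.6745 * np.sqrt(2.0))
    return c * sigma


def segment_rds(
    rd_profile: RDProfile,
    denoised_values: Sequence[float],
    merge_tol: float = MERGE_TOL,
    tv_penalty: float = float("nan"),
) -> RDSProfile:
    """Collapse runs of equal denoised values into read-depth segments.

    A new segment opens whenever consecutive denoised values differ by more
    than ``merge_tol`` or the chromosome changes.  Segment values are means
    of the original RD values.
    """
    den = np.asarray(denoised_values, dtype=float)
    if len(den) != len(rd_profile):
        raise ValueError(
            f"length mismatch: {len(rd_profile)} bins vs {len(den)} denoised values"
        )
    bins = rd_profile.bins
    raw = rd_profile.values

    segments: list[RDSegment] = []
    run_start = 0
    for i in range(1, len(den) + 1):
        new_run = (
            i == len(den)
            or abs(den[i] - den[i - 1]) > merge_tol
            or bins[i].chrom != bins[i - 1].chrom
        )
        if new_run:
            segments.append(
                RDSegment(
                    start_bin=run_start,
                    end_bin=i - 1,
                    value=float(np.mean(raw[run_start:i])),
                    chrom=bins[run_start].chrom,
                    start=bins[run_start].start,
                    end=bins[i - 1].end,
                )
            )
            run_start = i
    return RDSProfile(segments=tuple(segments), tv_penalty=float(tv_penalty))


def segment_profile(
    rd_profile: RDProfile,
    tv_penalty: float | None = None,
    penalty_scale: float = 2.0,
    merge_tol: float = MERGE_TOL,
) -> RDSProfile:
    """Denoise and segment an RD profile, one chromosome at a time.

    Segmentation never crosses a chromosome boundary.  When ``tv_penalty``
    is None the noise-adaptive default is estimated per chromosome.
    """
    chroms = rd_profile.chroms
    values = rd_profile.values
    denoised = np.empty_like(values)
    used_penalty = 0.0
    for chrom in pd_unique(chroms):
        mask = chroms == chrom
        lam = (
            default_tv_penalty(values[mask], c=penalty_scale)
            if tv_penalty is None
            else tv_penalty
        )
        denoised[mask] = tv_denoise(values[mask], lam)
        used_penalty = lam
    return segment_rds(rd_profile, denoised, merge_tol, tv_penalty=used_penalty)


def pd_unique(arr: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance (chromosome order)."""
    _, idx = np.unique(arr, return_index=True)
    return arr[np.sort(idx)]
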