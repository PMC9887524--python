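"""End-to-end detection: bins -> segments -> feature space -> scores -> calls."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calling import (
    CallThreshold,
    CNVCall,
    boxplot_threshold,
    classify_calls,
    flag_segments,
    merge_calls,
)
from .feature_space import to_feature_space
from .rd_preprocess import Bin, aggregate_bins, gc_correct, remove_n_bins
from .segmentation import RDSProfile, segment_profile
from .sp_score import ScoreProfile, rsps_scores


@dataclass(frozen=True)
class CallSet:
    """Full result of one detection run."""

    calls: tuple[CNVCall, ...]
    threshold: CallThreshold
    scores: ScoreProfile
    segments: RDSProfile


def detect_cnvs(
    bins: Sequence[Bin],
    k: int | None = None,
    lam: float = 1.5,
    tv_penalty: float | None = None,
    penalty_scale: float = 2.0,
    working_bin_size: int | None = 5000,
    ratio_center: str = "mean",
    diff_mode: str = "signed",
    min_stratum_size: int = 20,
    gc_correction: bool = True,
) -> CallSet:
    """Run the whole caller on a per-bin count collection.

    Steps: N-bin removal, median-method GC correction, aggregation of
    consecutive bins up to ``working_bin_size`` (low-coverage per-bin
    counts are Poisson-noisy; ~5 kb working bins temper that while still
    resolving 10 kb events — pass None to keep the input resolution),
    total-variation segmentation, the 2-D feature map, relative
    shortest-path scoring with ``k`` neighbours, boxplot thresholding at
    fence multiplier ``lam``, gain/loss typing against the normal
    baseline, and merging of adjacent same-type candidates.
    """
    clean = remove_n_bins(bins)
    if not clean:
        raise ValueError("no usable bins after N removal")
    if working_bin_size is not None:
        native = max(b.end - b.start for b in clean)
        factor = max(1, round(working_bin_size / native))
        clean = aggregate_bins(clean, factor)
    # GC correction runs at the working resolution: larger strata give
    # stabler stratum medians
    profile = gc_correct(
        clean,
        min_stratum_size=min_stratum_size if gc_correction else 10**9,
    )
    rds = segment_profile(profile, tv_penalty=tv_penalty, penalty_scale=penalty_scale)
    objects = to_feature_space(rds, ratio_center=ratio_center, diff_mode=diff_mode)
    scores = rsps_scores(objects, k=k)
    threshold = boxplot_threshold(scores.rsps, lam=lam)
    mask = flag_segments(scores.rsps, threshold)
    flagged = [s for s, f in zip(rds.segments, mask) if f]
    types = classify_calls(mask, rds.segments)
    flagged_scores = [float(r) for r, f in zip(scores.rsps, mask) if f]
    calls = merge_calls(flagged, types, flagged_scores)
    return CallSet(
        calls=tuple(calls), threshold=threshold, scores=scores, segments=rds
    )
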