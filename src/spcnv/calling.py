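"""CNV calling from the score profile and interval-level evaluation.

The RSPS profile is thresholded with a boxplot (Tukey) upper inner fence

    tau = Q3 + lam * (Q3 - Q1)

which adapts to each sample's score distribution without assuming a
parametric form.  Segments scoring above tau are CNV candidates; they are
typed gain or loss by comparing their RD to the mean RD of the unflagged
(normal) segments, and genomically adjacent candidates of one type merge
into a single call.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import RDSegment


@dataclass(frozen=True)
class CallThreshold:
    q1: float
    q3: float
    lam: float
    tau: float


@dataclass(frozen=True)
class CNVCall:
    """A merged CNV interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    type: str  # "gain" | "loss"
    score: float  # max member RSPS
    n_segments: int


@dataclass(frozen=True)
class EvalReport:
    recall: float | None
    precision: float | None
    f1: float | None
    n_truth: int
    n_calls: int
    n_correct_truth: int
    n_correct_calls: int


def boxplot_threshold(rsps_values: Sequence[float], lam: float = 1.5) -> CallThreshold:
    """Tukey upper-fence cutoff on the finite scores.

    Quartiles use linear interpolation (the common type-7 convention);
    infinite sentinel scores are excluded from the quantiles (they exceed
    any finite tau regardless).
    """
    finite = np.asarray([v for v in np.asarray(rsps_values, float) if math.isfinite(v)])
    if finite.size < 4:
        raise ValueError(f"need >= 4 finite scores for quartiles, got {finite.size}")
    q1 = float(np.quantile(finite, 0.25))
    q3 = float(np.quantile(finite, 0.75))
    return CallThreshold(q1=q1, q3=q3, lam=lam, tau=q3 + lam * (q3 - q1))


def flag_segments(rsps_values: Sequence[float], threshold: CallThreshold) -> np.ndarray:
    """Boolean mask: scores strictly above tau are CNV candidates."""
    return np.asarray(rsps_values, float) > threshold.tau


def classify_calls(
    flagged: Sequence[bool],
    segments: Sequence[RDSegment],
) -> list[str]:
    """Type each flagged segment by its RD against the normal baseline.

    The baseline is the mean segment RD over unflagged segments; a flagged
    segment at or above it is a gain, below it a loss.
    """
    flagged = np.asarray(flagged, bool)
    if len(flagged) != len(segments):
        raise ValueError("flag mask and segment list differ in length")
    if not flagged.any():
        return []
    normal = [s.value for s, f in zip(segments, flagged) if not f]
    if not normal:
        raise ValueError(
            "every segment is flagged: no normal baseline; raise lam"
        )
    mu = float(np.mean(normal))
    return [
        "gain" if s.value >= mu else "loss"
        for s, f in zip(segments, flagged)
        if f
    ]


def merge_calls(
    segments: Sequence[RDSegment],
    types: Sequence[str],
    scores: Sequence[float] | None = None,
) -> list[CNVCall]:
    """Merge genomically adjacent flagged segments of equal type.

    ``segments``/``types``/``scores`` are parallel over the *flagged*
    segments, in genomic order.  Adjacency means touching coordinates on
    one chromosome; a normal segment in between keeps calls apart.
    """
    if scores is None:
        scores = [math.nan] * len(segments)
    calls: list[CNVCall] = []
    for seg, typ, sc in zip(segments, types, scores):
        prev = calls[-1] if calls else None
        if (
            prev is not None
            and prev.chrom == seg.chrom
            and prev.type == typ
            and prev.end == seg.start
        ):
            calls[-1] = CNVCall(
                chrom=prev.chrom,
                start=prev.start,
                end=seg.end,
                type=typ,
                score=float(max(prev.score, sc)) if math.isfinite(sc) or math.isfinite(prev.score) else math.nan,
                n_segments=prev.n_segments + 1,
            )
        else:
            calls.append(
                CNVCall(seg.chrom, seg.start, seg.end, typ, float(sc), 1)
            )
    return calls


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _matches(call, truth, rule: str) -> bool:
    ov = _overlap(call.start, call.end, truth.start, truth.end)
    if call.chrom != truth.chrom or call.type != truth.type or ov <= 0:
        return False
    if rule == "any-overlap":
        return True
    if rule == "reciprocal-50":
        return (
            ov >= 0.5 * (call.end - call.start)
            and ov >= 0.5 * (truth.end - truth.start)
        )
    raise ValueError(f"unknown match rule {rule!r}")


def evaluate_calls(
    calls: Sequence[CNVCall],
    truth: Sequence[CNVCall],
    match_rule: str = "any-overlap",
) -> EvalReport:
    """Event-level recall, precision and F1 against ground-truth intervals.

    Recall = correctly detected truth events / all truth events;
    precision = correct calls / all calls; F1 their harmonic mean.
    Matching is type-aware: a loss call never credits a gain event.
    """
    n_correct_truth = sum(
        1 for t in truth if any(_matches(c, t, match_rule) for c in calls)
    )
    n_correct_calls = sum(
        1 for c in calls if any(_matches(c, t, match_rule) for t in truth)
    )
    recall = n_correct_truth / len(truth) if truth else None
    precision = n_correct_calls / len(calls) if calls else None
    if recall is None or precision is None:
        f1 = None if recall is None else 0.0
    elif recall + precision == 0:
        f1 = 0.0
    else:
        f1 = 2 * recall * precision / (recall + precision)
    if not calls and truth:
        f1 = 0.0
    return EvalReport(
        recall=recall,
        precision=precision,
        f1=f1,
        n_truth=len(truth),
        n_calls=len(calls),
        n_correct_truth=n_correct_truth,
        n_correct_calls=n_correct_calls,
    )


def counts_report(n_truth: int, n_calls: int, n_correct: int) -> EvalReport:
    """Metrics from bare event counts (correct calls == correct truths)."""
    recall = n_correct / n_truth if n_truth else None
    precision = n_correct / n_calls if n_calls else None
    if recall is None or precision is None:
        f1 = None if recall is None else 0.0
    elif recall + precision == 0:
        f1 = 0.0
    else:
        f1 = 2 * recall * precision / (recall + precision)
    return EvalReport(recall, precision, f1, n_truth, n_calls, n_correct, n_correct)


def write_calls_bed(calls: Sequence[CNVCall], path: str) -> None:
    """BED-like TSV: chrom, start (0-based), end, type, score, n_segments."""
    pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "type": c.type,
                "score": c.score,
                "n_segments": c.n_segments,
            }
            for c in calls
        ],
        columns=["chrom", "start", "end", "type", "score", "n_segments"],
    ).to_csv(path, sep="\t", index=False)


def read_truth_bed(path: str) -> list[CNVCall]:
    """Read ground-truth intervals: chrom, start, end, type (TSV, header)."""
    df = pd.read_csv(path, sep="\t")
    return [
        CNVCall(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            type=str(r.type),
            score=math.nan,
            n_segments=0,
        )
        for r in df.itertuples()
    ]


def write_run_summary(path: str, **fields) -> None:
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, default=float)
        fh.write("\n")
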