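"""Synthetic binned read-depth samples with embedded ground-truth CNVs.

Emulates the tumour-sample simulation design used to benchmark read-depth
CNV callers: a single synthetic chromosome at ~5x coverage carrying six
gains and eight losses of 10-50 kb each, diluted by tumour purity.  The
expected depth of a bin inside an event with copy number CN is

    base_coverage * (purity * CN / 2 + (1 - purity))

i.e. a purity-weighted mixture of the aberrant tumour fraction and the
diploid normal fraction.  Per-bin counts are negative-binomial (real read
depth is overdispersed relative to Poisson); an optional unimodal GC bias
curve, peaking at 45% GC, multiplies the expectation so the median-method
corrector can be exercised.  Events are placed at arbitrary base-pair
positions; bins partially covered by an event get the coverage-weighted
mixture of copy numbers across the bin.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .calling import CNVCall
from .rd_preprocess import Bin, write_bins_tsv

_PLACEMENT_RETRIES = 1000


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults reproduce the benchmark design."""

    n_bins: int = 10_000
    bin_size: int = 1000
    base_coverage: float = 5.0  # mean rc at CN = 2
    purity: float = 0.6
    n_gains: int = 6
    n_losses: int = 8
    length_range: tuple[int, int] = (10_000, 50_000)
    gain_cn: int = 3
    loss_cn: int = 1
    noise_dispersion: float = 0.1  # NB: var = mu + dispersion * mu^2
    gc_bias_strength: float = 0.0
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must be in [0,1], got {self.purity}")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range lower bound exceeds upper bound")
        total = (self.n_gains + self.n_losses) * self.length_range[1]
        if total >= self.n_bins * self.bin_size:
            raise ValueError("events cannot fit on the synthetic chromosome")


@dataclass(frozen=True)
class SimSample:
    bins: tuple[Bin, ...]
    truth: tuple[CNVCall, ...]
    config: SimConfig


def _place_events(cfg: SimConfig, rng: np.random.Generator) -> list[CNVCall]:
    genome_len = cfg.n_bins * cfg.bin_size
    types = ["gain"] * cfg.n_gains + ["loss"] * cfg.n_losses
    rng.shuffle(types)
    events: list[CNVCall] = []
    for typ in types:
        placed = False
        for _ in range(_PLACEMENT_RETRIES):
            length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            start = int(rng.integers(0, genome_len - length))
            end = start + length
            # keep one bin of clearance so adjacent events stay distinct
            if all(
                end + cfg.bin_size <= e.start or start >= e.end + cfg.bin_size
                for e in events
            ):
                cn = cfg.gain_cn if typ == "gain" else cfg.loss_cn
                events.append(
                    CNVCall(cfg.chrom, start, end, typ, float(cn), 0)
                )
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place non-overlapping events; enlarge n_bins or "
                "shrink length_range"
            )
    events.sort(key=lambda e: e.start)
    return events


def _gc_bias_factor(gc: np.ndarray, strength: float) -> np.ndarray:
    # unimodal multiplicative curve peaking at 45% GC
    bump = np.exp(-0.5 * ((gc - 0.45) / 0.15) ** 2)
    return (1.0 - strength) + strength * bump


def simulate_sample(config: SimConfig) -> SimSample:
    """Draw one binned sample plus its ground-truth event list.

    Fully reproducible from ``config.seed``: identical configs produce
    byte-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    events = _place_events(cfg, rng)

    starts = np.arange(cfg.n_bins, dtype=np.int64) * cfg.bin_size
    ends = starts + cfg.bin_size

    # per-bin effective copy number: coverage-weighted over event overlaps
    cn = np.full(cfg.n_bins, 2.0)
    for ev in events:
        ev_cn = cfg.gain_cn if ev.type == "gain" else cfg.loss_cn
        lo = max(0, ev.start // cfg.bin_size)
        hi = min(cfg.n_bins, -(-ev.end // cfg.bin_size))
        for i in range(lo, hi):
            ov = min(ends[i], ev.end) - max(starts[i], ev.start)
            frac = ov / cfg.bin_size
            cn[i] += frac * (ev_cn - 2.0)

    # smooth GC landscape in a realistic range
    t = np.linspace(0, 6 * math.pi, cfg.n_bins)
    gc = 0.45 + 0.12 * np.sin(t) + rng.normal(0, 0.02, cfg.n_bins)
    gc = np.clip(gc, 0.2, 0.75)

    mixture = cfg.purity * cn / 2.0 + (1.0 - cfg.purity)
    mu = cfg.base_coverage * mixture * _gc_bias_factor(gc, cfg.gc_bias_strength)

    alpha = cfg.noise_dispersion
    if alpha > 0:
        r = 1.0 / alpha
        p = r / (r + mu)
        counts = np.where(mu > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
    else:
        counts = rng.poisson(mu)

    bins = tuple(
        Bin(
            chrom=cfg.chrom,
            start=int(starts[i]),
            end=int(ends[i]),
            gc=float(round(gc[i], 4)),
            has_n=False,
            rc=float(counts[i]),
        )
        for i in range(cfg.n_bins)
    )
    return SimSample(bins=bins, truth=tuple(events), config=cfg)


def write_sample(sample: SimSample, out_prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.bins.tsv`` and ``<prefix>.truth.bed``.

    The bins TSV follows the preprocessing entry-point contract and
    round-trips losslessly through :func:`spcnv.rd_preprocess.read_bins_tsv`.
    """
    out_dir = os.path.dirname(out_prefix)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    bins_path = out_prefix + ".bins.tsv"
    truth_path = out_prefix + ".truth.bed"
    write_bins_tsv(sample.bins, bins_path)
    with open(truth_path, "w") as fh:
        fh.write("chrom\tstart\tend\ttype\n")
        for ev in sample.truth:
            fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\t{ev.type}\n")
    return bins_path, truth_path


def config_from_file(path: str) -> SimConfig:
    """Flat key=value (or key: value) config file mirroring SimConfig."""
    fields = {}
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.replace(":", "=", 1).partition("=")
        fields[key.strip()] = val.strip()
    kwargs: dict = {}
    defaults = SimConfig()
    for key, val in fields.items():
        if not hasattr(defaults, key):
            raise ValueError(f"unknown simulation setting {key!r}")
        current = getattr(defaults, key)
        if key == "length_range":
            lo, hi = val.replace(",", " ").split()
            kwargs[key] = (int(lo), int(hi))
        elif isinstance(current, bool):
            kwargs[key] = val.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            kwargs[key] = int(val)
        elif isinstance(current, float):
            kwargs[key] = float(val)
        else:
            kwargs[key] = val
    return SimConfig(**kwargs)
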