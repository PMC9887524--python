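"""Read-depth profile construction: binning, N-bin removal, GC correction.

The read-depth (RD) method rests on the proportionality between local copy
number and the number of reads aligned to a locus.  This module turns an
indexed alignment file (BAM) plus reference genome, or a pre-binned count
table, into a clean RD profile: one mean read count per fixed-width genomic
bin, with bins overlapping reference ``N`` runs removed and GC-content bias
calibrated by the median method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("spcnv")

TSV_COLUMNS = ["chrom", "start", "end", "rc", "gc", "has_n"]


@dataclass(frozen=True)
class Bin:
    """A fixed-width genomic window with its mean per-base read count.

    Coordinates are 0-based half-open.  ``rc`` is the read-depth value of
    the bin: mean read count per base (or read starts per base, depending
    on the counting convention used upstream).  ``gc`` is the GC fraction
    of the reference slice; ``has_n`` flags any ambiguous base in it.
    """

    chrom: str
    start: int
    end: int
    gc: float
    has_n: bool
    rc: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"bin end must exceed start: {self.start}..{self.end}")
        if self.rc < 0:
            raise ValueError(f"negative read count {self.rc}")


@dataclass(frozen=True)
class RDProfile:
    """An ordered, N-free, GC-corrected read-depth profile."""

    bins: tuple[Bin, ...]
    bin_size: int

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def values(self) -> np.ndarray:
        return np.array([b.rc for b in self.bins], dtype=float)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([b.chrom for b in self.bins])


def extract_binned_counts(
    alignment_source: str,
    reference: str,
    bin_size: int = 1000,
    chrom: str | None = None,
    counting: str = "coverage",
) -> list[Bin]:
    """Tile a chromosome with ``bin_size`` windows and count reads per bin.

    Parameters
    ----------
    alignment_source
        Path to a coordinate-sorted, indexed BAM file.
    reference
        Path to the (indexed) FASTA reference; supplies bin GC content and
        the N flag.
    bin_size
        Window width in base pairs.
    chrom
        Chromosome to bin.  Required when the BAM holds several.
    counting
        ``"coverage"`` (default): per-base coverage summed over the bin and
        divided by bin width — the mean read count per base.  ``"starts"``:
        aligned read start positions in the bin divided by bin width.
    """
    import pysam
    from pyfaidx import Fasta

    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if counting not in ("coverage", "starts"):
        raise ValueError(f"unknown counting convention {counting!r}")

    fasta = Fasta(reference, one_based_attributes=False)
    with pysam.AlignmentFile(alignment_source, "rb") as bam:
        if not bam.has_index():
            raise ValueError(f"alignment file {alignment_source} is not indexed")
        if chrom is None:
            if len(bam.references) != 1:
                raise ValueError("chrom is required for multi-chromosome BAMs")
            chrom = bam.references[0]
        if chrom not in fasta:
            raise ValueError(f"chromosome {chrom!r} missing from reference {reference}")
        chrom_len = len(fasta[chrom])

        bins: list[Bin] = []
        for start in range(0, chrom_len, bin_size):
            end = min(start + bin_size, chrom_len)
            width = end - start
            seq = fasta[chrom][start:end].seq.upper()
            gc = (seq.count("G") + seq.count("C")) / width
            has_n = "N" in seq
            if counting == "coverage":
                cov = bam.count_coverage(chrom, start, end, quality_threshold=0)
                total = int(sum(np.sum(c) for c in cov))
            else:
                total = sum(
                    1
                    for read in bam.fetch(chrom, start, end)
                    if not read.is_unmapped and start <= read.reference_start < end
                )
            bins.append(Bin(chrom, start, end, gc, has_n, total / width))
    return bins


def read_bins_tsv(path: str) -> list[Bin]:
    """Read the per-bin count table (tab-separated, header required).

    This is the alternative entry point bypassing alignment parsing; it is
    also the format the synthetic-data generator emits.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bins TSV {path} lacks columns {missing}")
    return [
        Bin(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            gc=float(r.gc),
            has_n=bool(r.has_n),
            rc=float(r.rc),
        )
        for r in df.itertuples()
    ]


def write_bins_tsv(bins: Iterable[Bin], path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "start": b.start,
                "end": b.end,
                "rc": b.rc,
                "gc": b.gc,
                "has_n": int(b.has_n),
            }
            for b in bins
        ],
        columns=TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def aggregate_bins(bins: Sequence[Bin], factor: int) -> list[Bin]:
    """Combine runs of ``factor`` consecutive same-chromosome bins.

    Produces a coarser working resolution: the aggregated bin spans its
    members, its ``rc`` and ``gc`` are their means, and ``has_n`` is their
    disjunction.  A short leftover run at a chromosome end becomes one
    (narrower) bin.  ``factor`` 1 is the identity.
    """
    if factor < 1:
        raise ValueError(f"aggregation factor must be >= 1, got {factor}")
    if factor == 1:
        return list(bins)
    out: list[Bin] = []
    group: list[Bin] = []

    def flush() -> None:
        if group:
            out.append(
                Bin(
                    chrom=group[0].chrom,
                    start=group[0].start,
                    end=group[-1].end,
                    gc=float(np.mean([b.gc for b in group])),
                    has_n=any(b.has_n for b in group),
                    rc=float(np.mean([b.rc for b in group])),
                )
            )
            group.clear()

    for b in bins:
        if group and (b.chrom != group[0].chrom or len(group) == factor):
            flush()
        group.append(b)
    flush()
    return out


def remove_n_bins(bins: Sequence[Bin]) -> list[Bin]:
    """Drop every bin whose reference slice contains an ambiguous base.

    Reads do not align to N runs, so such bins would show zero depth and be
    mistaken for deletions.  Order is preserved; the operation is idempotent.
    """
    kept = [b for b in bins if not b.has_n]
    if bins and not kept:
        logger.warning("all %d bins contained N positions; profile is empty", len(bins))
    return kept


def gc_correct(
    bins: Sequence[Bin],
    bin_size: int | None = None,
    min_stratum_size: int = 20,
) -> RDProfile:
    """Calibrate GC-content bias with the median method.

    Bins are stratified by GC rounded to the nearest integer percent.  Each
    bin's count is rescaled by ``m / m_g`` where ``m`` is the global median
    count and ``m_g`` the stratum median, so every (sufficiently populated)
    stratum ends up with median ``m``.  Strata with fewer than
    ``min_stratum_size`` bins borrow the global median (their counts are
    left unchanged), as do strata whose median is zero.
    """
    if not bins:
        raise ValueError("gc_correct requires a non-empty bin collection")
    if any(b.has_n for b in bins):
        raise ValueError("remove N bins before GC correction")
    if bin_size is None:
        bin_size = max(b.end - b.start for b in bins)

    rc = np.array([b.rc for b in bins], dtype=float)
    strata = np.array([int(round(b.gc * 100)) for b in bins])
    m = float(np.median(rc))

    factors = np.ones(len(bins))
    for g in np.unique(strata):
        mask = strata == g
        if mask.sum() < min_stratum_size:
            continue
        m_g = float(np.median(rc[mask]))
        if m_g == 0:
            logger.info("GC stratum %d%% has zero median; left uncorrected", g)
            continue
        factors[mask] = m / m_g

    corrected = tuple(
        replace(b, rc=b.rc * f) for b, f in zip(bins, factors)
    )
    return RDProfile(bins=corrected, bin_size=bin_size)
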