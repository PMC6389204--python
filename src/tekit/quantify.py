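"""Alignment filtering, read counting on genes/TE integrants, coverage profiles.

RNA-seq counting follows the conventions of the upstream tools it replaces:
multi-mappers are removed with the ``NH == 1`` rule, genes are counted
reverse-stranded on exon unions with a MAPQ floor, and TE integrants are
counted split-aware and same-stranded with multicov semantics (a read
overlapping k features increments each of them).  Coverage profiles normalize
per-base signal to reads per 100 million mapped reads, resample every feature
to a common number of bins (strand-flipped for minus-strand features), and
report the per-bin mean with a normal-approximation 95% confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .intervals import GenomicInterval

__all__ = [
    "AlignmentRecord",
    "CountMatrix",
    "CoverageProfile",
    "read_sam",
    "filter_unique",
    "count_on_features",
    "build_count_matrix",
    "low_count_filter",
    "coverage_profile",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentRecord:
    """A mapped read; split alignments carry one block per aligned segment."""

    query_name: str
    chrom: str
    strand: str
    mapq: int
    nh: int
    blocks: tuple[tuple[int, int], ...]  # 0-based half-open, ordered

    def __post_init__(self) -> None:
        if self.nh < 1:
            raise ValueError("nh must be >= 1")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError("blocks must be ordered and non-overlapping")

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


@dataclass
class CountMatrix:
    """Features x samples integer counts with per-sample library sizes."""

    counts: pd.DataFrame  # int, features x samples
    lib_sizes: pd.Series  # per sample, > 0

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.lib_sizes.index):
            raise ValueError("lib_sizes index must match count columns")
        if (self.lib_sizes <= 0).any():
            raise ValueError("lib_sizes must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# lib_sizes\t" + "\t".join(str(int(v)) for v in self.lib_sizes) + "\n")
            self.counts.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        with open(path) as fh:
            first = fh.readline()
            libs = [int(v) for v in first.rstrip("\n").split("\t")[1:]]
            counts = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(counts=counts, lib_sizes=pd.Series(libs, index=counts.columns))


@dataclass
class CoverageProfile:
    """Per-bin mean signal with 95% CI, in reads per 100 million mapped reads."""

    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_features: int

    @property
    def n_bins(self) -> int:
        return len(self.mean)


# ---------------------------------------------------------------------------
# SAM input
# ---------------------------------------------------------------------------

def read_sam(path: str) -> list[AlignmentRecord]:
    """Read mapped reads from SAM/BAM into :class:`AlignmentRecord` objects.

    Aligned segments come from the CIGAR (N gaps split the read into blocks);
    an absent NH tag is treated as 1 and logged once.
    """
    records: list[AlignmentRecord] = []
    warned = False
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            try:
                nh = aln.get_tag("NH")
            except KeyError:
                nh = 1
                if not warned:
                    log.warning("NH tag absent; treating reads as uniquely mapped (NH=1)")
                    warned = True
            blocks = tuple((int(s), int(e)) for s, e in aln.get_blocks())
            merged: list[tuple[int, int]] = []
            for s, e in blocks:  # adjacent M ops split by I/D collapse to one block
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            records.append(
                AlignmentRecord(
                    query_name=aln.query_name,
                    chrom=aln.reference_name,
                    strand="-" if aln.is_reverse else "+",
                    mapq=aln.mapping_quality,
                    nh=int(nh),
                    blocks=tuple(merged),
                )
            )
    return records


def filter_unique(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep only uniquely mapped reads (NH == 1)."""
    return [r for r in records if r.nh == 1]


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _strand_ok(feature: GenomicInterval, record: AlignmentRecord, strandedness: str) -> bool:
    if strandedness == "unstranded" or feature.strand is None:
        return True
    if strandedness == "same":
        return feature.strand == record.strand
    if strandedness == "reverse":
        return feature.strand != record.strand
    raise ValueError(f"unknown strandedness {strandedness!r}")


def count_on_features(
    records: Iterable[AlignmentRecord],
    features: Sequence[GenomicInterval],
    strandedness: str = "unstranded",
    split_aware: bool = False,
    mapq_min: int = 0,
    multimap_mode: str = "unique_only",
) -> pd.Series:
    """Count reads per feature with multicov semantics.

    A record counts toward a feature when at least 1 bp of its aligned span
    (or of any block when ``split_aware``) overlaps the feature and the strand
    rule holds; a record overlapping k features increments each of them.  In
    ``unique_only`` mode records with NH > 1 are skipped; in ``all_alignments``
    every reported alignment is counted.
    """
    if mapq_min < 0:
        raise ValueError("mapq_min must be >= 0")
    if multimap_mode not in ("unique_only", "all_alignments"):
        raise ValueError(f"unknown multimap_mode {multimap_mode!r}")

    ids = [f.name or f"{f.chrom}:{f.start}-{f.end}" for f in features]
    trees: dict[str, IntervalTree] = {}
    for idx, f in enumerate(features):
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, idx)
    counts = np.zeros(len(features), dtype=np.int64)
    for rec in records:
        if rec.mapq < mapq_min:
            continue
        if multimap_mode == "unique_only" and rec.nh != 1:
            continue
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        segs = rec.blocks if split_aware else (rec.span,)
        hit: set[int] = set()
        for s, e in segs:
            for node in tree.overlap(s, e):
                hit.add(node.data)
        for idx in hit:
            if _strand_ok(features[idx], rec, strandedness):
                counts[idx] += 1
    return pd.Series(counts, index=pd.Index(ids, name="feature_id"), name="count")


def build_count_matrix(
    per_sample_records: Mapping[str, Iterable[AlignmentRecord]],
    features: Sequence[GenomicInterval],
    lib_sizes: Mapping[str, int] | None = None,
    **count_kwargs,
) -> CountMatrix:
    """Count every sample on the same features and assemble a CountMatrix.

    When ``lib_sizes`` is not supplied, each sample's library size defaults to
    its total counted reads (the per-column sum).
    """
    cols = {s: count_on_features(recs, features, **count_kwargs) for s, recs in per_sample_records.items()}
    counts = pd.DataFrame(cols)
    if lib_sizes is None:
        sizes = counts.sum(axis=0).astype(int)
        log.info("lib_sizes not supplied; using per-sample counted-read totals")
    else:
        sizes = pd.Series({s: int(lib_sizes[s]) for s in counts.columns})
    return CountMatrix(counts=counts, lib_sizes=sizes)


def low_count_filter(matrix: CountMatrix) -> CountMatrix:
    """Keep features with at least as many reads (row sum) as there are samples."""
    n = matrix.counts.shape[1]
    keep = matrix.counts.sum(axis=1) >= n
    return CountMatrix(counts=matrix.counts.loc[keep], lib_sizes=matrix.lib_sizes)


# ---------------------------------------------------------------------------
# coverage profiles
# ---------------------------------------------------------------------------

def coverage_profile(
    signal: Mapping[str, np.ndarray],
    features: Sequence[GenomicInterval],
    n_bins: int,
    mapped_reads_total: float,
) -> CoverageProfile:
    """Length-normalized average signal profile over a set of features.

    Each feature's per-base signal is scaled to reads per 100 million mapped
    reads, reversed for minus-strand features, linearly resampled onto
    ``n_bins`` bin midpoints, and averaged across features; the band is the
    normal-approximation 95% CI (mean +/- 1.96 SEM).  With a single feature
    the CI width collapses to 0 (logged).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if mapped_reads_total <= 0:
        raise ValueError("mapped_reads_total must be positive")
    scale = 1e8 / mapped_reads_total
    rows = np.empty((len(features), n_bins))
    tgt = (np.arange(n_bins) + 0.5) / n_bins
    for i, f in enumerate(features):
        if f.length < 1:
            raise ValueError(f"feature {f.name!r} shorter than 1 bp")
        vals = np.asarray(signal[f.chrom][f.start : f.end], dtype=float) * scale
        if f.strand == "-":
            vals = vals[::-1]
        if len(vals) == 1:
            rows[i] = vals[0]
        else:
            src = (np.arange(len(vals)) + 0.5) / len(vals)
            rows[i] = np.interp(tgt, src, vals)
    mean = rows.mean(axis=0)
    if len(features) > 1:
        sem = rows.std(axis=0, ddof=1) / np.sqrt(len(features))
    else:
        sem = np.zeros(n_bins)
        log.info("single feature: confidence band collapses to the point estimate")
    return CoverageProfile(
        mean=mean, ci_low=mean - 1.96 * sem, ci_high=mean + 1.96 * sem, n_features=len(features)
    )
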