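"""Occupancy classification and coverage/distance statistics on genomic intervals.

Features (TE integrants, ICRs, genes) are classified by overlap with peak
sets: KRAB/KAP1 ChIP peaks use a 25% reciprocal-overlap criterion by default,
while broad histone-mark domains (H3K9me3, H3K4me3, H3K27me3) use the 1-bp
"any overlap" default.  All intervals are 0-based half-open; touching
intervals (a.end == b.start) overlap 0 bp and lie at distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "OverlapMode",
    "reciprocal_overlap",
    "classify_features",
    "genome_coverage_fraction",
    "distance_to_nearest",
    "read_bed",
    "write_flag_table",
    "read_chrom_sizes",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OverlapMode:
    """How a peak set flags a feature.

    ``kind='any'`` flags on >= 1 bp of shared sequence; ``kind='reciprocal'``
    requires the overlap to cover at least ``fraction`` of BOTH intervals.
    """

    kind: str = "any"
    fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("any", "reciprocal"):
            raise ValueError(f"unknown overlap mode {self.kind!r}")
        if self.kind == "reciprocal" and not (0 < self.fraction <= 1):
            raise ValueError("reciprocal fraction must be in (0, 1]")


def _overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval, fraction: float) -> bool:
    """True iff the shared length covers >= ``fraction`` of both intervals.

    Strand is ignored; intervals on different chromosomes simply do not
    overlap.  Symmetric in its two arguments.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    ovl = _overlap_len(a, b)
    return ovl >= fraction * a.length and ovl >= fraction * b.length


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def classify_features(
    features: Sequence[GenomicInterval],
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
    modes: Mapping[str, OverlapMode] | None = None,
) -> pd.DataFrame:
    """Flag each feature by occupancy in every named peak set.

    A feature is flagged for a set if ANY peak in the set satisfies that
    set's overlap mode.  Unnamed sets default to any-overlap except names
    containing ``kap1`` (case-insensitive), which default to reciprocal 25%,
    matching the convention for KAP1 binding-site attribution.

    Returns a boolean DataFrame indexed by feature name (or ``chrom:start-end``
    when unnamed), one column per peak set.  Adding peaks can only set flags,
    never unset them.
    """
    modes = dict(modes or {})
    for set_name in peak_sets:
        if set_name not in modes:
            modes[set_name] = (
                OverlapMode("reciprocal", 0.25) if "kap1" in set_name.lower() else OverlapMode("any")
            )

    ids = [f.name or f"{f.chrom}:{f.start}-{f.end}" for f in features]
    out = pd.DataFrame(False, index=pd.Index(ids, name="feature_id"), columns=list(peak_sets))
    for set_name, peaks in peak_sets.items():
        mode = modes[set_name]
        trees = _build_trees(peaks)
        flags = np.zeros(len(features), dtype=bool)
        for i, f in enumerate(features):
            tree = trees.get(f.chrom)
            if tree is None:
                continue
            for node in tree.overlap(f.start, f.end):
                if mode.kind == "any":
                    flags[i] = True
                    break
                if reciprocal_overlap(f, node.data, mode.fraction):
                    flags[i] = True
                    break
        out[set_name] = flags
    return out


def genome_coverage_fraction(
    intervals: Sequence[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> float:
    """Fraction of the genome covered by the union of the intervals.

    Mirrors ``bedtools genomecov``: overlapping intervals are merged before
    counting.  Intervals beyond their chromosome bound raise.
    """
    total = sum(chrom_sizes.values())
    if total <= 0:
        raise ValueError("empty genome")
    covered = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        size = chrom_sizes.get(iv.chrom)
        if size is None:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > size:
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chrom size {size}")
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
        covered += cur_e - cur_s
    return covered / total


def distance_to_nearest(
    features: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> pd.Series:
    """Edge-to-edge distance from each feature to its nearest target.

    Overlapping or touching intervals are at distance 0.  Features on a
    chromosome with no target get NaN.
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {t.chrom for t in targets}:
        tv = sorted((t.start, t.end) for t in targets if t.chrom == chrom)
        starts[chrom] = np.array([s for s, _ in tv])
        # prefix max of ends aligned to start-sorted order
        ends[chrom] = np.maximum.accumulate(np.array([e for _, e in tv]))
    ids = [f.name or f"{f.chrom}:{f.start}-{f.end}" for f in features]
    dist = np.full(len(features), np.nan)
    for i, f in enumerate(features):
        if f.chrom not in starts:
            continue
        ts, te = starts[f.chrom], ends[f.chrom]
        best = np.inf
        # nearest target starting at/after feature end
        j = np.searchsorted(ts, f.end, side="left")
        if j < len(ts):
            best = min(best, ts[j] - f.end)
        # targets starting before feature end: overlap or end before feature
        if j > 0:
            best = min(best, max(0, f.start - te[j - 1]))
        dist[i] = max(0.0, best)
    return pd.Series(dist, index=pd.Index(ids, name="feature_id"), name="distance_bp")


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_bed(stream: TextIO | Iterable[str]) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (half-open, as BED is)."""
    out = []
    for line in stream:
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append(
            GenomicInterval(
                chrom=f[0],
                start=int(f[1]),
                end=int(f[2]),
                name=f[3] if len(f) > 3 else "",
                score=float(f[4]) if len(f) > 4 and f[4] != "." else None,
                strand=f[5] if len(f) > 5 and f[5] in ("+", "-") else None,
            )
        )
    return out


def write_flag_table(flags: pd.DataFrame, stream: TextIO) -> None:
    flags.astype(int).to_csv(stream, sep="\t")


def read_chrom_sizes(stream: TextIO | Iterable[str]) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for line in stream:
        if not line.strip():
            continue
        chrom, size = line.split()[:2]
        sizes[chrom] = int(size)
    return sizes
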