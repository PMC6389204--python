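"""RepeatMasker parsing and integrant-level merging of LTR retroelements.

RepeatMasker annotates an endogenous retrovirus as several separate hits:
an internal coding fragment (e.g. ``IAPEz-int``) plus flanking long terminal
repeats (e.g. ``IAPLTR1a_Mm``), often interrupted by small gaps or nested
insertions.  Analyses at the level of individual genomic copies ("integrants")
require these fragments to be re-assembled.  This module merges homonymous
internal fragments with their attributed LTRs whenever compatible hits lie
within a configurable gap (default 400 bp), producing one annotation per
integrant with its ordered sub-parts labelled LTR5 / INTERNAL / LTR3, and
LTR_SOLO for solitary LTRs left behind by recombination.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

__all__ = [
    "RepeatHit",
    "Subpart",
    "TEIntegrant",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "merge_integrants",
    "write_integrants_bed",
    "read_integrants_bed",
    "internal_stem",
    "read_pairing_table",
]

_INTERNAL_SUFFIXES = ("-int", "_I", "_int", "-I")


@dataclass(frozen=True)
class RepeatHit:
    """One RepeatMasker alignment row; coordinates 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class_family: str
    sw_score: int
    hit_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"hit {self.hit_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"hit {self.hit_id}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Subpart:
    """A merged sub-interval of an integrant; 0-based half-open."""

    start: int
    end: int
    role: str  # LTR5 | INTERNAL | LTR3 | LTR_SOLO
    hit_ids: tuple[str, ...]
    repeat_name: str


@dataclass
class TEIntegrant:
    """A merged repeat locus; 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    family_name: str
    subparts: list[Subpart] = field(default_factory=list)
    integrant_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("integrant must have positive length")
        if not self.subparts:
            raise ValueError("integrant needs at least one subpart")
        for a, b in zip(self.subparts, self.subparts[1:]):
            if b.start < a.end:
                raise ValueError("subparts must be ordered and non-overlapping")

    @property
    def length(self) -> int:
        return self.end - self.start

    def hit_ids(self) -> set[str]:
        return {h for sp in self.subparts for h in sp.hit_ids}


def internal_stem(name: str) -> str | None:
    """Base name of an internal fragment, or None if *name* is not internal.

    ``IAPEz-int`` -> ``IAPEz``; ``MMERVK10C_I`` -> ``MMERVK10C``.
    """
    for suf in _INTERNAL_SUFFIXES:
        if name.endswith(suf) and len(name) > len(suf):
            return name[: -len(suf)]
    return None


# ---------------------------------------------------------------------------
# RepeatMasker .out I/O
# ---------------------------------------------------------------------------

def parse_repeatmasker_out(stream: TextIO | Iterable[str]) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` file into :class:`RepeatHit` records.

    The dialect is three header lines followed by whitespace-delimited rows
    with at least 15 columns.  Orientation ``C`` (complement) maps to strand
    ``-``.  Coordinates are kept 1-based inclusive, as printed by RepeatMasker;
    conversion to 0-based half-open happens once, at integrant construction.
    """
    hits: list[RepeatHit] = []
    seen_ids: set[str] = set()
    for lineno, line in enumerate(stream, start=1):
        if lineno <= 3:  # two header rows + blank line
            continue
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 15:
            raise ValueError(
                f"line {lineno}: expected >= 15 whitespace-delimited columns, got {len(fields)}"
            )
        try:
            sw_score = int(fields[0])
            chrom = fields[4]
            start = int(fields[5])
            end = int(fields[6])
            orient = fields[8]
            repeat_name = fields[9]
            class_family = fields[10]
            hit_id = fields[14]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed row ({exc})") from exc
        if orient == "C":
            strand = "-"
        elif orient == "+":
            strand = "+"
        else:
            raise ValueError(f"line {lineno}: unknown orientation {orient!r}")
        if hit_id in seen_ids:
            raise ValueError(f"line {lineno}: duplicate hit id {hit_id!r}")
        seen_ids.add(hit_id)
        hits.append(
            RepeatHit(
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                repeat_name=repeat_name,
                repeat_class_family=class_family,
                sw_score=sw_score,
                hit_id=hit_id,
            )
        )
    return hits


_OUT_HEADER = (
    "   SW   perc perc perc  query     position in query         matching"
    "    repeat           position in repeat\n"
    "score   div. del. ins.  sequence  begin end      (left)   repeat"
    "    class/family   begin  end    (left)  ID\n"
    "\n"
)


def write_repeatmasker_out(hits: Sequence[RepeatHit], stream: TextIO) -> None:
    """Write hits back out in the RepeatMasker ``.out`` dialect."""
    stream.write(_OUT_HEADER)
    for h in hits:
        orient = "C" if h.strand == "-" else "+"
        rep_len = h.end - h.start + 1
        stream.write(
            f"{h.sw_score:5d}  1.0  0.0  0.0  {h.chrom}  {h.start}  {h.end}  (0)  "
            f"{orient}  {h.repeat_name}  {h.repeat_class_family}  1  {rep_len}  (0)  {h.hit_id}\n"
        )


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def read_pairing_table(stream: TextIO | Iterable[str]) -> dict[str, set[str]]:
    """Read a two-column TSV ``internal_name<TAB>ltr_name`` pairing table."""
    pairing: dict[str, set[str]] = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"\t|\s{2,}", line)
        if len(parts) < 2:
            raise ValueError(f"pairing table row needs 2 columns: {line!r}")
        pairing.setdefault(parts[0], set()).add(parts[1])
    _check_pairing_acyclic(pairing)
    return pairing


def _check_pairing_acyclic(pairing: Mapping[str, set[str]]) -> None:
    # An LTR name that is itself an internal key would let attribution chain
    # indefinitely (A -> B -> A ...); reject such tables outright.
    for internal, ltrs in pairing.items():
        for ltr in ltrs:
            if ltr in pairing:
                raise ValueError(
                    f"pairing cycle: {ltr!r} appears both as an LTR of {internal!r} "
                    "and as an internal name"
                )


def _compatible(internal: RepeatHit, ltr: RepeatHit, pairing: Mapping[str, set[str]] | None) -> bool:
    """Homonymy rule: stem of the internal name prefixes the LTR name and the
    class/family matches, or the pair is listed in a user pairing table."""
    stem = internal_stem(internal.repeat_name)
    if stem is None:
        return False
    if pairing and ltr.repeat_name in pairing.get(internal.repeat_name, ()):
        return True
    return (
        ltr.repeat_name.startswith(stem)
        and internal.repeat_class_family == ltr.repeat_class_family
    )


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _gap(left: RepeatHit, right: RepeatHit) -> int:
    """Gap in bp between two 1-based inclusive hits; <= 0 when they touch/overlap."""
    if left.start > right.start:
        left, right = right, left
    return right.start - left.end - 1


def _chainable(a: RepeatHit, b: RepeatHit, max_gap: int, pairing) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if _gap(a, b) > max_gap:
        return False
    a_int = internal_stem(a.repeat_name) is not None
    b_int = internal_stem(b.repeat_name) is not None
    if a_int and b_int:
        return a.repeat_name == b.repeat_name
    if a_int and not b_int:
        return _compatible(a, b, pairing)
    if b_int and not a_int:
        return _compatible(b, a, pairing)
    return False  # two LTRs never chain directly


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _union_same_name(hits: list[RepeatHit]) -> list[tuple[RepeatHit, tuple[str, ...]]]:
    """Union nested/overlapping (or touching) same-name, same-strand hits.

    Returns synthetic hits carrying the ids of everything they absorbed; the
    representative keeps the best Smith-Waterman score.
    """
    order = sorted(
        range(len(hits)),
        key=lambda i: (hits[i].chrom, hits[i].strand, hits[i].repeat_name, hits[i].start, hits[i].hit_id),
    )
    merged: list[tuple[RepeatHit, tuple[str, ...]]] = []
    for idx in order:
        h = hits[idx]
        if merged:
            prev, ids = merged[-1]
            same = (
                prev.chrom == h.chrom
                and prev.strand == h.strand
                and prev.repeat_name == h.repeat_name
            )
            if same and h.start <= prev.end:  # genuine overlap/nesting only
                merged[-1] = (
                    RepeatHit(
                        chrom=prev.chrom,
                        start=prev.start,
                        end=max(prev.end, h.end),
                        strand=prev.strand,
                        repeat_name=prev.repeat_name,
                        repeat_class_family=prev.repeat_class_family,
                        sw_score=max(prev.sw_score, h.sw_score),
                        hit_id=prev.hit_id,
                    ),
                    ids + (h.hit_id,),
                )
                continue
        merged.append((h, (h.hit_id,)))
    merged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[0].hit_id))
    return merged


def merge_integrants(
    hits: Sequence[RepeatHit],
    max_gap: int = 400,
    pairing: Mapping[str, set[str]] | None = None,
) -> list[TEIntegrant]:
    """Merge RepeatMasker hits into integrant-level annotations.

    Same-chromosome, same-strand hits chain when the gap between them is
    ``max_gap`` bp or less and their names are compatible: internal fragments
    of identical name chain with each other, and an internal chains with an
    LTR attributed to it by homonymy (shared name stem and class/family) or by
    an explicit pairing table.  Chaining is transitive, so a full provirus
    LTR5-INTERNAL-LTR3 merges through the internal block even though its two
    LTRs never touch.  LTRs with no internal within reach become single-part
    LTR_SOLO integrants.

    Parameters
    ----------
    hits:
        RepeatMasker hits, 1-based inclusive (any order).
    max_gap:
        Largest allowed gap in bp between chained hits; a gap of exactly
        ``max_gap`` still chains, ``max_gap + 1`` does not.
    pairing:
        Optional explicit map internal_name -> allowed LTR names, extending
        the default homonymy rule.

    Returns
    -------
    list of :class:`TEIntegrant`, sorted by (chrom, start), coordinates
    converted once to 0-based half-open.
    """
    if pairing:
        _check_pairing_acyclic(pairing)
    pre = _union_same_name(list(hits))
    n = len(pre)
    uf = _UnionFind(n)
    # sweep: hits sorted by (chrom, start); a pair can chain only while
    # candidate.end >= current.start - max_gap - 1
    active: list[int] = []
    for j in range(n):
        hj = pre[j][0]
        active = [
            i
            for i in active
            if pre[i][0].chrom == hj.chrom and pre[i][0].end >= hj.start - max_gap - 1
        ]
        for i in active:
            if _chainable(pre[i][0], hj, max_gap, pairing):
                uf.union(i, j)
        active.append(j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)

    integrants: list[TEIntegrant] = []
    for members in components.values():
        members.sort(key=lambda i: (pre[i][0].start, pre[i][0].end, pre[i][0].hit_id))
        integrants.append(_build_integrant([pre[i] for i in members]))
    integrants.sort(key=lambda t: (t.chrom, t.start, t.end, t.family_name))
    for k, t in enumerate(integrants, start=1):
        t.integrant_id = f"TE{k:05d}"
    return integrants


def _build_integrant(members: list[tuple[RepeatHit, tuple[str, ...]]]) -> TEIntegrant:
    chrom = members[0][0].chrom
    strand = members[0][0].strand
    internals = [m for m in members if internal_stem(m[0].repeat_name) is not None]
    if internals:
        # family label = stem of the internal contributing the most bases
        best = max(internals, key=lambda m: (m[0].length, m[0].hit_id))
        family = internal_stem(best[0].repeat_name) or best[0].repeat_name
        int_start = min(m[0].start for m in internals)
        int_end = max(m[0].end for m in internals)
    else:
        family = members[0][0].repeat_name
        int_start = int_end = None

    subparts: list[Subpart] = []
    for h, ids in members:
        if internal_stem(h.repeat_name) is not None:
            role = "INTERNAL"
        elif int_start is None:
            role = "LTR_SOLO"
        else:
            upstream = h.end <= int_start or (h.start < int_start and h.end < int_end)
            # 5' side depends on the strand of the provirus
            if strand == "+":
                role = "LTR5" if upstream else "LTR3"
            else:
                role = "LTR3" if upstream else "LTR5"
        subparts.append(
            Subpart(start=h.start - 1, end=h.end, role=role, hit_ids=ids, repeat_name=h.repeat_name)
        )
    subparts = _resolve_subpart_overlaps(subparts)
    return TEIntegrant(
        chrom=chrom,
        start=min(s.start for s in subparts),
        end=max(s.end for s in subparts),
        strand=strand,
        family_name=family,
        subparts=subparts,
    )


def _resolve_subpart_overlaps(subparts: list[Subpart]) -> list[Subpart]:
    """Union subparts whose intervals overlap (different-name hits can overlap
    after same-name pre-union); keeps the invariant of ordered disjoint parts."""
    subparts = sorted(subparts, key=lambda s: (s.start, s.end))
    out: list[Subpart] = []
    for sp in subparts:
        if out and sp.start < out[-1].end:
            prev = out[-1]
            role = "INTERNAL" if "INTERNAL" in (prev.role, sp.role) else prev.role
            name = prev.repeat_name if prev.role == role else sp.repeat_name
            out[-1] = Subpart(
                start=prev.start,
                end=max(prev.end, sp.end),
                role=role,
                hit_ids=prev.hit_ids + sp.hit_ids,
                repeat_name=name,
            )
        else:
            out.append(sp)
    return out


# ---------------------------------------------------------------------------
# BED12 I/O
# ---------------------------------------------------------------------------

def write_integrants_bed(integrants: Sequence[TEIntegrant], stream: TextIO) -> None:
    """Write integrants as BED12; blocks are the merged sub-parts."""
    for t in sorted(integrants, key=lambda t: (t.chrom, t.start, t.end, t.integrant_id)):
        starts = ",".join(str(sp.start - t.start) for sp in t.subparts)
        sizes = ",".join(str(sp.end - sp.start) for sp in t.subparts)
        name = f"{t.family_name}:{t.integrant_id}"
        stream.write(
            f"{t.chrom}\t{t.start}\t{t.end}\t{name}\t0\t{t.strand}\t"
            f"{t.start}\t{t.end}\t0\t{len(t.subparts)}\t{sizes},\t{starts},\n"
        )


def read_integrants_bed(stream: TextIO | Iterable[str]) -> list[TEIntegrant]:
    """Read integrants back from the BED12 written by :func:`write_integrants_bed`.

    Sub-part roles are reconstructed positionally (single block -> LTR_SOLO is
    not distinguishable from a lone internal, so roles are stored in the name
    field only through family identity; round-trips preserve coordinates)."""
    out: list[TEIntegrant] = []
    for line in stream:
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.rstrip("\n").split("\t")
        chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        family, _, tid = name.partition(":")
        subparts = [
            Subpart(start=start + bs, end=start + bs + sz, role="INTERNAL", hit_ids=(), repeat_name=family)
            for bs, sz in zip(starts, sizes)
        ]
        out.append(
            TEIntegrant(
                chrom=chrom, start=start, end=end, strand=strand,
                family_name=family, subparts=subparts, integrant_id=tid,
            )
        )
    return out
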