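"""RepeatMasker parsing and integrant merging."""

import io

import pytest

from tekit.repeats import (
    RepeatHit,
    merge_integrants,
    parse_repeatmasker_out,
    read_integrants_bed,
    read_pairing_table,
    write_integrants_bed,
    write_repeatmasker_out,
    internal_stem,
)
from tekit.simulate import SimConfig, simulate_repeat_hits

from conftest import random_hits

HEADER = "h1\nh2\n\n"


def row(sw, chrom, start, end, orient, name, cls, hid):
    return f"{sw} 1.0 0.0 0.0 {chrom} {start} {end} (0) {orient} {name} {cls} 1 100 (0) {hid}\n"


class TestParse:
    def test_plus_orientation_maps_to_plus_strand(self):
        hits = parse_repeatmasker_out(io.StringIO(HEADER + row(100, "chr1", 10, 99, "+", "IAPEz-int", "LTR/ERVK", "a")))
        assert len(hits) == 1
        h = hits[0]
        assert (h.chrom, h.start, h.end, h.strand) == ("chr1", 10, 99, "+")
        assert h.repeat_name == "IAPEz-int" and h.sw_score == 100

    def test_complement_orientation_maps_to_minus_strand(self):
        hits = parse_repeatmasker_out(io.StringIO(HEADER + row(100, "chr1", 10, 99, "C", "IAPLTR1", "LTR/ERVK", "a")))
        assert hits[0].strand == "-"

    def test_malformed_row_names_line_number(self):
        with pytest.raises(ValueError, match="line 5"):
            parse_repeatmasker_out(io.StringIO(HEADER + row(1, "chr1", 1, 2, "+", "x", "y", "a") + "bad row\n"))

    def test_empty_after_headers_gives_empty_list(self):
        assert parse_repeatmasker_out(io.StringIO(HEADER)) == []

    def test_duplicate_hit_id_rejected(self):
        text = HEADER + row(1, "chr1", 1, 50, "+", "x", "y", "a") + row(1, "chr1", 100, 150, "+", "x", "y", "a")
        with pytest.raises(ValueError, match="duplicate"):
            parse_repeatmasker_out(io.StringIO(text))

    def test_simulated_fixture_round_trips(self):
        hits, _, _ = simulate_repeat_hits(SimConfig(seed=4, n_integrants_per_family=100))
        assert len(hits) >= 1000
        buf = io.StringIO()
        write_repeatmasker_out(hits, buf)
        buf.seek(0)
        assert parse_repeatmasker_out(buf) == hits


def brute_force_merge_groups(hits, max_gap=400, pairing=None):
    """Independent O(n^2) oracle: transitive closure of the pairwise
    chainable relation, via repeated sweeps until a fixed point."""

    def compatible(a, b):
        sa, sb = internal_stem(a.repeat_name), internal_stem(b.repeat_name)
        if sa is not None and sb is not None:
            return a.repeat_name == b.repeat_name
        if sa is None and sb is None:
            return False
        internal, ltr = (a, b) if sa is not None else (b, a)
        stem = internal_stem(internal.repeat_name)
        if pairing and ltr.repeat_name in pairing.get(internal.repeat_name, set()):
            return True
        return ltr.repeat_name.startswith(stem) and internal.repeat_class_family == ltr.repeat_class_family

    def gap(a, b):
        lo, hi = (a, b) if a.start <= b.start else (b, a)
        return hi.start - lo.end - 1

    def chain(a, b):
        return a.chrom == b.chrom and a.strand == b.strand and gap(a, b) <= max_gap and compatible(a, b)

    groups = [{h.hit_id} for h in hits]
    changed = True
    while changed:
        changed = False
        for i, a in enumerate(hits):
            for j, b in enumerate(hits):
                if j <= i or not chain(a, b):
                    continue
                ga = next(g for g in groups if a.hit_id in g)
                gb = next(g for g in groups if b.hit_id in g)
                if ga is not gb:
                    ga |= gb
                    groups.remove(gb)
                    changed = True
    return {frozenset(g) for g in groups}


class TestMerge:
    def make(self, start, end, name, strand="+", hid=None, cls="LTR/ERVK"):
        return RepeatHit(chrom="chr1", start=start, end=end, strand=strand, repeat_name=name,
                         repeat_class_family=cls, sw_score=1000, hit_id=hid or f"{name}:{start}")

    def test_internal_plus_ltr_within_gap_merges_with_roles(self):
        hits = [self.make(1001, 3000, "IAP-int"), self.make(3101, 3450, "IAPLTR1")]
        out = merge_integrants(hits)
        assert len(out) == 1
        t = out[0]
        assert (t.start, t.end) == (1000, 3450)  # converted to 0-based half-open
        assert [sp.role for sp in t.subparts] == ["INTERNAL", "LTR3"]
        assert t.family_name == "IAP"

    def test_gap_of_exactly_400_merges_401_does_not(self):
        base = [self.make(1001, 3000, "IAP-int")]
        assert len(merge_integrants(base + [self.make(3401, 3700, "IAPLTR1")])) == 1
        assert len(merge_integrants(base + [self.make(3402, 3700, "IAPLTR1")])) == 2

    def test_upstream_ltr_is_ltr5_on_plus_and_ltr3_on_minus(self):
        for strand, first_role in (("+", "LTR5"), ("-", "LTR3")):
            hits = [self.make(500, 840, "IAPLTR1", strand), self.make(900, 3000, "IAP-int", strand)]
            t = merge_integrants(hits)[0]
            assert [sp.role for sp in t.subparts] == [first_role, "INTERNAL"]

    def test_full_provirus_gets_both_ltr_roles(self):
        hits = [
            self.make(500, 840, "IAPLTR1"),
            self.make(900, 3000, "IAP-int"),
            self.make(3100, 3440, "IAPLTR1", hid="right"),
        ]
        t = merge_integrants(hits)[0]
        assert [sp.role for sp in t.subparts] == ["LTR5", "INTERNAL", "LTR3"]

    def test_lone_ltr_becomes_single_part_solo(self):
        t = merge_integrants([self.make(100, 440, "IAPLTR1")])[0]
        assert [sp.role for sp in t.subparts] == ["LTR_SOLO"]
        assert t.family_name == "IAPLTR1"

    def test_two_nearby_solo_ltrs_stay_separate(self):
        # LTR-LTR hits never chain directly
        out = merge_integrants([self.make(100, 440, "IAPLTR1"), self.make(500, 840, "IAPLTR1", hid="b")])
        assert len(out) == 2
        assert all(sp.role == "LTR_SOLO" for t in out for sp in t.subparts)

    def test_incompatible_family_does_not_merge(self):
        out = merge_integrants([self.make(1001, 3000, "IAP-int"), self.make(3101, 3450, "MTLTR")])
        assert len(out) == 2

    def test_pairing_table_extends_homonymy(self):
        hits = [self.make(1001, 3000, "MERVL-int", cls="LTR/ERVL"),
                self.make(3101, 3450, "MT2_Mm", cls="LTR/ERVL")]
        assert len(merge_integrants(hits)) == 2  # stem "MERVL" does not prefix "MT2_Mm"
        assert len(merge_integrants(hits, pairing={"MERVL-int": {"MT2_Mm"}})) == 1

    def test_pairing_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            merge_integrants([], pairing={"A-int": {"B-int"}, "B-int": {"A-int"}})

    def test_nested_same_name_hits_union_into_one_subpart(self):
        hits = [self.make(1001, 5000, "IAP-int"), self.make(2000, 3000, "IAP-int", hid="nested")]
        t = merge_integrants(hits)[0]
        assert len(t.subparts) == 1
        assert set(t.subparts[0].hit_ids) == {"IAP-int:1001", "nested"}

    def test_matches_transitive_closure_oracle_on_random_sets(self, rng):
        for _ in range(40):
            hits = random_hits(rng, int(rng.integers(5, 40)))
            got = {frozenset(t.hit_ids()) for t in merge_integrants(hits)}
            assert got == brute_force_merge_groups(hits)

    def test_merge_is_idempotent_on_degenerate_refeed(self, rng):
        hits = random_hits(rng, 60)
        first = merge_integrants(hits)
        refeed = [
            RepeatHit(chrom=t.chrom, start=t.start + 1, end=t.end, strand=t.strand,
                      repeat_name=t.family_name, repeat_class_family="LTR/ERVK",
                      sw_score=1, hit_id=t.integrant_id)
            for t in first
        ]
        second = merge_integrants(refeed)
        assert [(t.chrom, t.start, t.end) for t in second] == [(t.chrom, t.start, t.end) for t in first]

    def test_same_family_outputs_never_overlap_on_one_strand(self, rng):
        out = merge_integrants(random_hits(rng, 200))
        by_key = {}
        for t in out:
            by_key.setdefault((t.chrom, t.strand, t.family_name), []).append((t.start, t.end))
        for spans in by_key.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 >= e1

    def test_merging_never_loses_covered_bases(self, rng):
        hits = random_hits(rng, 150)
        out = merge_integrants(hits)
        for h in hits:
            covering = [t for t in out if t.chrom == h.chrom and t.start <= h.start - 1 and t.end >= h.end]
            assert covering, f"hit {h.hit_id} not covered by any integrant"


class TestBed:
    def test_single_part_integrant_writes_one_block(self):
        t = merge_integrants([RepeatHit(chrom="chr1", start=101, end=400, strand="+",
                                        repeat_name="IAPLTR1", repeat_class_family="LTR/ERVK",
                                        sw_score=5, hit_id="x")])[0]
        buf = io.StringIO()
        write_integrants_bed([t], buf)
        fields = buf.getvalue().strip().split("\t")
        assert fields[9] == "1" and fields[10] == "300,"

    def test_three_part_integrant_writes_blocks_in_coordinate_order(self):
        hits = [
            RepeatHit(chrom="chr1", start=s, end=e, strand="+", repeat_name=n,
                      repeat_class_family="LTR/ERVK", sw_score=5, hit_id=f"h{s}")
            for s, e, n in [(500, 840, "IAPLTR1"), (900, 3000, "IAP-int"), (3100, 3440, "IAPLTR1")]
        ]
        buf = io.StringIO()
        write_integrants_bed(merge_integrants(hits), buf)
        fields = buf.getvalue().strip().split("\t")
        assert fields[9] == "3"
        assert fields[11] == "0,400,2600,"

    def test_write_read_round_trip_preserves_coordinates(self, rng):
        hits, pairing, _ = simulate_repeat_hits(SimConfig(seed=6, n_integrants_per_family=90))
        integrants = merge_integrants(hits, pairing=pairing)
        assert len(integrants) >= 300
        buf = io.StringIO()
        write_integrants_bed(integrants, buf)
        buf.seek(0)
        back = read_integrants_bed(buf)
        assert [(t.chrom, t.start, t.end, t.strand, [(s.start, s.end) for s in t.subparts]) for t in back] == [
            (t.chrom, t.start, t.end, t.strand, [(s.start, s.end) for s in t.subparts]) for t in integrants
        ]


def test_pairing_table_reader_detects_cycles():
    assert read_pairing_table(io.StringIO("IAPEz-int\tIAPLTR1a_Mm\n")) == {"IAPEz-int": {"IAPLTR1a_Mm"}}
    with pytest.raises(ValueError, match="cycle"):
        read_pairing_table(io.StringIO("A-int\tB-int\nB-int\tC\n"))


def test_strand_validation_in_hit_type():
    with pytest.raises(ValueError, match="strand"):
        RepeatHit(chrom="chr1", start=1, end=5, strand="*", repeat_name="x",
                  repeat_class_family="y", sw_score=1, hit_id="a")
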