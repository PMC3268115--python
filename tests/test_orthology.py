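"""Reciprocal-best-hit inference against hand-worked and brute-force oracles."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciliaprofile import HitRecord, HitTable, best_hit, parse_hits, rbb_pairs, reciprocal_best
from ciliaprofile.errors import ConfigError, HitParseError


def hit(q, s, e, bits=100.0):
    return HitRecord(q, s, 90.0, 100, 5, 0, 1, 100, 1, 100, e, bits)


def table(source, target, records):
    return HitTable(source=source, target=target, records=list(records))


class TestParseHits:
    def test_empty_stream_gives_empty_table(self):
        t = parse_hits(io.StringIO(""), "ref", "sp")
        assert len(t) == 0 and t.source == "ref" and t.target == "sp"

    def test_single_line_parsed_bit_exactly(self):
        line = "q1\ts1\t90.0\t100\t5\t0\t1\t100\t1\t100\t1e-40\t200\n"
        t = parse_hits(io.StringIO(line), "ref", "sp")
        (rec,) = t.records
        assert rec.query_id == "q1" and rec.subject_id == "s1"
        assert rec.e_value == 1e-40 and rec.bit_score == 200.0
        assert rec.percent_identity == 90.0 and rec.aln_length == 100

    def test_parsing_does_not_filter_weak_hits(self):
        line = "q1\ts1\t90.0\t100\t5\t0\t1\t100\t1\t100\t1e-3\t50"
        assert len(parse_hits(io.StringIO(line), "r", "s")) == 1

    def test_comments_and_blank_lines_skipped(self):
        text = "# comment\n\nq1\ts1\t90\t100\t5\t0\t1\t100\t1\t100\t1e-40\t200\n"
        assert len(parse_hits(io.StringIO(text), "r", "s")) == 1

    @pytest.mark.parametrize(
        "bad", ["q1\ts1\tonly-three", "q1\ts1\tx\t100\t5\t0\t1\t100\t1\t100\t1e-40\t200"]
    )
    def test_malformed_line_names_line_number(self, bad):
        stream = io.StringIO("q1\ts1\t90\t100\t5\t0\t1\t100\t1\t100\t1e-40\t200\n" + bad)
        with pytest.raises(HitParseError, match="line 2"):
            parse_hits(stream, "r", "s")


class TestBestHit:
    def test_minimum_evalue_wins(self):
        t = table("r", "s", [hit("q1", "s1", 1e-10), hit("q1", "s2", 1e-20)])
        assert best_hit(t, "q1", 1e-5).subject_id == "s2"

    def test_threshold_is_strict(self):
        t = table("r", "s", [hit("q1", "s1", 1e-4)])
        assert best_hit(t, "q1", 1e-5) is None
        assert best_hit(t, "q1", 1.0001e-4).subject_id == "s1"

    def test_evalue_tie_broken_by_bit_score_then_subject_id(self):
        t = table("r", "s", [hit("q1", "s1", 1e-30, bits=100), hit("q1", "s2", 1e-30, bits=200)])
        assert best_hit(t, "q1", 1e-5).subject_id == "s2"
        t = table("r", "s", [hit("q1", "sB", 1e-30), hit("q1", "sA", 1e-30)])
        assert best_hit(t, "q1", 1e-5).subject_id == "sA"

    def test_duplicate_pair_lines_collapse_to_lowest_evalue(self):
        t = table("r", "s", [hit("q1", "s1", 1e-10, bits=500), hit("q1", "s1", 1e-40, bits=90),
                             hit("q1", "s2", 1e-20)])
        assert best_hit(t, "q1", 1e-5).subject_id == "s1"

    def test_self_hits_ignored(self):
        t = table("r", "r", [hit("q1", "q1", 0.0, bits=999), hit("q1", "s1", 1e-30)])
        assert best_hit(t, "q1", 1e-5).subject_id == "s1"

    def test_zero_evalue_passes_any_positive_threshold(self):
        t = table("r", "s", [hit("q1", "s1", 0.0)])
        assert best_hit(t, "q1", 1e-300).subject_id == "s1"


class TestReciprocalBest:
    def test_mutual_top_hits_make_a_pair(self):
        fwd = table("ref", "sp", [hit("q1", "s1", 1e-30)])
        rev = table("sp", "ref", [hit("s1", "q1", 1e-30)])
        pair = reciprocal_best(fwd, rev, "q1")
        assert (pair.query_protein, pair.target_protein, pair.target_species) == ("q1", "s1", "sp")

    def test_non_reciprocating_top_hit_discarded(self):
        fwd = table("ref", "sp", [hit("q1", "s1", 1e-30)])
        rev = table("sp", "ref", [hit("s1", "q2", 1e-40), hit("s1", "q1", 1e-30)])
        assert reciprocal_best(fwd, rev, "q1") is None

    def test_no_forward_hit_under_threshold(self):
        fwd = table("ref", "sp", [hit("q1", "s1", 1e-3)])
        rev = table("sp", "ref", [hit("s1", "q1", 1e-30)])
        assert reciprocal_best(fwd, rev, "q1") is None

    def test_mismatched_pair_labels_rejected(self):
        fwd = table("ref", "spA", [])
        rev = table("spB", "ref", [])
        with pytest.raises(ConfigError):
            reciprocal_best(fwd, rev, "q1")

    def test_at_most_one_pair_per_query(self):
        fwd = table("ref", "sp", [hit("q1", "s1", 1e-30), hit("q1", "s2", 1e-50)])
        rev = table("sp", "ref", [hit("s1", "q1", 1e-30), hit("s2", "q1", 1e-50)])
        pairs = rbb_pairs(fwd, rev, ["q1"])
        assert len(pairs) == 1 and pairs[0].target_protein == "s2"


# ---- randomised instances vs an exhaustive mutual-top-hit oracle -----------

EVALUES = [0.0, 1e-50, 1e-30, 1e-20, 1e-10, 1e-6, 1e-4, 1e-2]
BITS = [50.0, 100.0, 200.0]


@st.composite
def two_proteome_instance(draw):
    n_q = draw(st.integers(1, 10))
    n_s = draw(st.integers(1, 10))
    queries = [f"q{i}" for i in range(n_q)]
    subjects = [f"s{i}" for i in range(n_s)]
    def hits(qs, ss):
        n = draw(st.integers(0, 25))
        return [
            hit(draw(st.sampled_from(qs)), draw(st.sampled_from(ss)),
                draw(st.sampled_from(EVALUES)), draw(st.sampled_from(BITS)))
            for _ in range(n)
        ]
    fwd = table("ref", "sp", hits(queries, subjects))
    rev = table("sp", "ref", hits(subjects, queries))
    return fwd, rev, queries, subjects


def oracle_mutual_top(fwd, rev, queries, subjects, thr=1e-5):
    """Exhaustive enumeration: (q, s) is a pair iff each is the other's top hit."""

    def collapse(records):
        best = {}
        for r in records:
            if r.query_id == r.subject_id or not r.e_value < thr:
                continue
            key = (r.query_id, r.subject_id)
            cur = best.get(key)
            if cur is None or (r.e_value, -r.bit_score) < (cur.e_value, -cur.bit_score):
                best[key] = r
        return best

    def is_top(best, q, s, others):
        if (q, s) not in best:
            return False
        rs = best[(q, s)]
        for o in others:
            if o == s or (q, o) not in best:
                continue
            ro = best[(q, o)]
            if (ro.e_value, -ro.bit_score, ro.subject_id) < (rs.e_value, -rs.bit_score, rs.subject_id):
                return False
        return True

    bf, br = collapse(fwd.records), collapse(rev.records)
    return {
        (q, s)
        for q in queries
        for s in subjects
        if is_top(bf, q, s, subjects) and is_top(br, s, q, queries)
    }


@settings(max_examples=200, derandomize=True, deadline=None)
@given(two_proteome_instance())
def test_rbb_matches_exhaustive_oracle(instance):
    fwd, rev, queries, subjects = instance
    pairs = {(p.query_protein, p.target_protein) for p in rbb_pairs(fwd, rev, queries)}
    assert pairs == oracle_mutual_top(fwd, rev, queries, subjects)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(two_proteome_instance())
def test_reciprocity_is_symmetric(instance):
    """Swapping which table is 'forward' yields the same unordered pair set."""
    fwd, rev, queries, subjects = instance
    from_ref = {(p.query_protein, p.target_protein) for p in rbb_pairs(fwd, rev, queries)}
    from_sp = {(p.target_protein, p.query_protein) for p in rbb_pairs(rev, fwd, subjects)}
    assert from_ref == from_sp


@settings(max_examples=100, derandomize=True, deadline=None)
@given(two_proteome_instance(), st.sampled_from([1e-4, 1e-5, 1e-8, 1e-25]))
def test_tightening_threshold_never_adds_pairs(instance, tighter):
    fwd, rev, queries, _ = instance
    loose = {(p.query_protein, p.target_protein) for p in rbb_pairs(fwd, rev, queries, 1e-2)}
    tight = {(p.query_protein, p.target_protein) for p in rbb_pairs(fwd, rev, queries, tighter)}
    assert tight <= loose
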