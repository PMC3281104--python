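"""Motif parsing, anchored matching, terminal classification, census,
kinase fingerprint and conservation profiles."""

import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seloscan.motifs import (
    ABSENT,
    AMINO_ACIDS,
    Fixed,
    InnerClass,
    MotifParseError,
    OuterClass,
    Range,
    Wildcard,
    annotate_kinase_fingerprint,
    census,
    classify_terminus,
    column_conservation,
    matches,
    parse_pattern,
    render_pattern,
)
from seloscan.io import SequenceRecord


def pattern_to_regex(p):
    """Independent matching oracle: translate to a regex and let the regex
    engine enumerate all range assignments."""
    parts = []
    for e in p.elements:
        if isinstance(e, Wildcard):
            parts.append(".")
        elif isinstance(e, Range):
            parts.append(".{%d,%d}" % (e.min, e.max))
        else:
            parts.append("[%s]" % "".join(sorted(e.residues)))
    body = "".join(parts)
    return re.compile(body + "$") if p.anchored else re.compile(body)


class TestParse:
    def test_cxxcuxx_structure(self):
        p = parse_pattern("C-x-x-[CU]-x-x>")
        assert p.anchored
        assert p.elements == (
            Fixed(frozenset("C")),
            Wildcard(),
            Wildcard(),
            Fixed(frozenset("CU")),
            Wildcard(),
            Wildcard(),
        )

    def test_single_wildcard_matches_any_nonempty(self):
        p = parse_pattern("x>")
        assert matches(p, "M")
        assert matches(p, "ACDEFG")

    @pytest.mark.parametrize("bad", ["C-x(5,3)>", "", "  ", "C-[>", "C-[]-x>", "B-x>", "x(a,b)>"])
    def test_parse_errors(self, bad):
        with pytest.raises(MotifParseError):
            parse_pattern(bad)

    @pytest.mark.parametrize(
        "text",
        ["C-x-x-[CU]-x-x>", "x>", "C-x(3,10)-[CU]-x-x>", "GxxGxG", "[HQ]-G-[VNS]", "D-[YF]-G", "U-x-x>", "x(2)-C>"],
    )
    def test_render_parse_roundtrip(self, text):
        p = parse_pattern(text)
        canon = render_pattern(p)
        assert parse_pattern(canon) == p
        assert render_pattern(parse_pattern(canon)) == canon


class TestMatches:
    def test_human_terminus(self):
        assert matches(parse_pattern("C-x-x-[CU]-x-x>"), "MKLNACVTUSS")

    def test_no_match(self):
        assert not matches(parse_pattern("Cxx>"), "AAAAAA")

    def test_residue_outside_alphabet(self):
        with pytest.raises(ValueError):
            matches(parse_pattern("x>"), "AB1A")

    def test_u_does_not_satisfy_bare_c(self):
        assert not matches(parse_pattern("C-x-x>"), "AAAAAAUAA")
        assert matches(parse_pattern("[CU]-x-x>"), "AAAAAAUAA")

    def test_random_patterns_agree_with_regex_oracle(self, rng):
        elements_pool = ["C", "x", "[CU]", "G", "[HQ]", "x(0,2)", "x(1,3)", "x(2,5)"]
        n_checked = 0
        for trial in range(400):
            k = int(rng.integers(1, 6))
            toks = [elements_pool[i] for i in rng.integers(0, len(elements_pool), k)]
            anchored = bool(rng.integers(0, 2))
            p = parse_pattern("-".join(toks) + (">" if anchored else ""))
            if p.max_span > 15:
                continue
            s = "".join("ACGHUX"[i] for i in rng.integers(0, 5, int(rng.integers(1, 15))))
            oracle = pattern_to_regex(p)
            assert matches(p, s) == bool(oracle.search(s)), (render_pattern(p), s)
            n_checked += 1
        assert n_checked > 200


class TestClassifyTerminus:
    def test_human_selo_terminus(self):
        tc = classify_terminus("MAAAAAACVTUSS")
        assert tc.inner is InnerClass.U_TERM
        assert tc.outer is OuterClass.CXXC

    def test_no_cys_or_sec(self):
        tc = classify_terminus("MKLVHGWAADEFG")
        assert tc.inner is InnerClass.NONE and tc.outer is OuterClass.NONE

    def test_gap4_range_class(self):
        # C, gap of 4, then Cxx terminus: inner Cys, outer ranged pattern
        tc = classify_terminus("AAAAAA" + "C" + "AAAA" + "CTS")
        assert tc.inner is InnerClass.C_TERM
        assert tc.outer is OuterClass.CX_RANGE_C
        assert matches(parse_pattern("C-x(3,10)-[CU]-x-x>"), "AAAAAACAAAACTS")

    def test_smallest_gap_wins_precedence(self):
        # both -6 and -8 cysteines present: CXXC beats CX_RANGE_C
        tc = classify_terminus("AAAAAC" + "AC" + "AA" + "CTS")
        assert tc.outer is OuterClass.CXXC

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            classify_terminus("ACVTUSS")

    def test_outer_requires_inner(self):
        # upstream CxxC spacing but no C/U at -3
        tc = classify_terminus("AAAAAAAC" + "AA" + "A" + "TS")
        assert tc.inner is InnerClass.NONE and tc.outer is OuterClass.NONE

    @given(st.text(alphabet=AMINO_ACIDS + "U", min_size=14, max_size=40), st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_depends_only_on_final_window(self, seq, data):
        prefix = data.draw(st.text(alphabet=AMINO_ACIDS, min_size=0, max_size=10))
        assert classify_terminus(seq) == classify_terminus(prefix + seq[-14:])


class TestCensus:
    def test_planted_family_counts(self, family_census_fixture):
        records, truth = family_census_fixture
        c = census(records)
        assert c.n == 143
        assert c.k("C-x-x-[CU]-x-x>") == 12
        assert c.k("[CU]-x-x>") == 111
        assert c.inner_counts["C_TERM"] == 111
        assert sum(c.inner_counts.values()) == c.n

    def test_forced_inner_planting(self, no_cys_freqs):
        from seloscan import synth

        cfg = synth.SimProteomeConfig(
            n_seqs=10, terminal_spec={"Cxx>": 1.0}, residue_freqs=no_cys_freqs, seed=1
        )
        records, _ = synth.gen_proteome(cfg)
        c = census(records)
        assert c.inner_counts["C_TERM"] == 10

    def test_empty_input(self):
        c = census([])
        assert c.n == 0
        assert all(v == 0 for v in c.pattern_counts.values())

    def test_permutation_invariance_and_additivity(self, family_census_fixture, rng):
        records, _ = family_census_fixture
        shuffled = [records[i] for i in rng.permutation(len(records))]
        assert census(shuffled).pattern_counts == census(records).pattern_counts
        half = len(records) // 2
        c1, c2, c_all = census(records[:half]), census(records[half:]), census(records)
        for pat in c_all.pattern_counts:
            assert c1.pattern_counts[pat] + c2.pattern_counts[pat] == c_all.pattern_counts[pat]

    def test_unclassifiable_ids_reported(self):
        with pytest.raises(ValueError, match="shorty"):
            census([SequenceRecord("shorty", "ACD")])


class TestFingerprint:
    def test_constructed_domain_places_all_slots(self):
        seq = (
            "MAAAA" + "GAAGAG"  # G-loop
            + "LLLL" + "K" + "PPPP" + "E" + "WWWW"
            + "HGV" + "SSSS" + "N" + "TTTT" + "DYG" + "AAAAAAAAAAAA"
        )
        rep = annotate_kinase_fingerprint(seq)
        assert all(h is not ABSENT for h in rep.hits.values())
        pos = rep.positions()
        assert pos == sorted(pos) and len(set(pos)) == len(pos)
        assert seq[rep.hits["G_LOOP"][0] - 1] == "G"
        assert seq[rep.hits["DFG"][0] - 1 : rep.hits["DFG"][1]] == "DYG"

    def test_missing_dfg_absent(self):
        seq = "GAAGAG" + "K" + "E" + "HGV" + "N" + "A" * 50
        rep = annotate_kinase_fingerprint(seq)
        assert rep.hits["DFG"] is ABSENT

    def test_out_of_order_slots_absent(self):
        # a D[YF]G occurring before its predecessors cannot fill the slot
        for seq in (
            "GAAGAG" + "K" + "E" + "DYG" + "HGV" + "N" + "A" * 50,
            "DYG" + "GAAGAG" + "K" + "E" + "HGV" + "N" + "A" * 50,
        ):
            rep = annotate_kinase_fingerprint(seq)
            assert rep.hits["DFG"] is ABSENT
            assert rep.hits["MG_N"] is not ABSENT


class TestConservation:
    def test_invariant_column_is_max_ic(self):
        prof = column_conservation(["C", "C", "C", "C"])
        assert prof.information_bits[0] == pytest.approx(math.log2(20), abs=1e-12)

    def test_uniform_column_is_zero(self):
        prof = column_conservation([a for a in AMINO_ACIDS])
        assert prof.information_bits[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_residue_even_column(self):
        prof = column_conservation(["C", "C", "S", "S"])
        assert prof.information_bits[0] == pytest.approx(math.log2(20) - 1.0, abs=1e-12)

    def test_frequencies_sum_to_one_and_gap_flagging(self):
        prof = column_conservation(["C-", "C-", "S-", "-A"])
        assert sum(prof.frequencies[0].values()) == pytest.approx(1.0)
        assert prof.flagged_gappy[1]
        assert not prof.flagged_gappy[0]

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            column_conservation(["AC", "ACD"])
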