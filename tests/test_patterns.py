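"""Motif pattern compilation, matching (vs a brute-force oracle), and the
family keep/reject rule."""

from itertools import product

import pytest

from cngckit import patterns
from cngckit.patterns import (CNGC_CONSENSUS, IQ_MOTIF, PatternError,
                              classify_candidate, compile_pattern,
                              find_matches)
from cngckit.seqio import AMINO_ACIDS, DomainAnnotation, SequenceRecord

BOTH_DOMAINS = frozenset({patterns.CNBD_LABEL, patterns.ION_TRANSPORT_LABEL})


def prot(seq, pid="p"):
    return SequenceRecord(pid, seq, "protein")


class TestCompile:
    def test_iq_motif_fixed_length(self):
        p = compile_pattern(IQ_MOTIF, "IQ")
        assert len(p.elements) == 10
        assert p.min_length == p.max_length == 10

    def test_variable_wildcard_bounds(self):
        p = compile_pattern("X(10,20)")
        assert (p.min_length, p.max_length) == (10, 20)

    def test_empty_class_is_parse_error(self):
        with pytest.raises(PatternError, match="position 0"):
            compile_pattern("[]-A")

    def test_reversed_count_is_parse_error(self):
        with pytest.raises(PatternError, match="m > n"):
            compile_pattern("A-X(5,2)")

    def test_optional_class(self):
        p = compile_pattern("[FY](0,1)-A")
        assert (p.min_length, p.max_length) == (1, 2)

    def test_consensus_length_bounds(self):
        p = compile_pattern(CNGC_CONSENSUS)
        assert (p.min_length, p.max_length) == (41, 52)


class TestFindMatches:
    def test_iq_match_position(self):
        p = compile_pattern(IQ_MOTIF, "IQ")
        hits = find_matches(p, prot("MIQSAWRSSYKAA"))
        assert [(h.start, h.end, h.matched_span) for h in hits] == \
            [(2, 11, "IQSAWRSSYK")]

    def test_consensus_whole_string_shortest_expansion(self):
        p = compile_pattern(CNGC_CONSENSUS)
        s = "LAAGAVAGDLLAWAL" + "A" * 10 + "SAS" + "A" * 7 + "VEAFAL"
        hits = find_matches(p, prot(s))
        assert len(hits) == 1 and (hits[0].start, hits[0].end) == (1, 41)

    def test_no_match_returns_empty(self):
        p = compile_pattern(IQ_MOTIF)
        assert find_matches(p, prot("AAAA")) == []

    def test_subject_x_matches_nothing(self):
        p = compile_pattern("A-X-A")
        assert find_matches(p, prot("AXA")) == []
        assert find_matches(p, prot("ACA"))


def oracle_matches(pattern, seq):
    """Independent matcher: recursive enumeration of every element-expansion
    assignment; reports the shortest end per start."""
    seq = seq.upper()
    hits = []
    for start in range(len(seq)):
        ends = set()

        def walk(pos, idx):
            if idx == len(pattern.elements):
                ends.add(pos)
                return
            el = pattern.elements[idx]
            for count in range(el.min_count, el.max_count + 1):
                if pos + count > len(seq):
                    break
                chunk = seq[pos:pos + count]
                if el.residues is None:
                    if any(c not in AMINO_ACIDS for c in chunk):
                        continue
                elif any(c not in el.residues for c in chunk):
                    continue
                walk(pos + count, idx + 1)

        walk(start, 0)
        if ends:
            hits.append((start + 1, min(ends)))
    return hits


class TestOracleEquivalence:
    PATTERN = "[AC]-X(1,3)-D-[CD](0,1)"

    @pytest.mark.parametrize("pattern_text", [PATTERN, "A-X(0,2)-[CD]-A"])
    def test_hypothesis_strings_match_oracle(self, pattern_text):
        from hypothesis import given, settings, strategies as st

        p = compile_pattern(pattern_text)

        @settings(max_examples=200, deadline=None, derandomize=True)
        @given(st.text(alphabet="ACDE", min_size=1, max_size=14))
        def check(s):
            got = [(h.start, h.end) for h in find_matches(p, prot(s))]
            assert got == oracle_matches(p, s)

        check()

    def test_exhaustive_small_alphabet(self):
        p = compile_pattern(self.PATTERN)
        for n in range(1, 8):
            for letters in product("ACDE", repeat=n):
                s = "".join(letters)
                got = [(h.start, h.end)
                       for h in find_matches(p, prot(s))]
                assert got == oracle_matches(p, s), s

    def test_random_60mers_with_variable_gaps(self, rng):
        p = compile_pattern("[LI]-X(2,6)-G-X(0,2)-[DE]-L")
        for _ in range(50):
            s = "".join(rng.choice(list("LIGDEAX"), 60))
            got = [(h.start, h.end) for h in find_matches(p, prot(s))]
            assert got == oracle_matches(p, s), s

    def test_spans_within_pattern_bounds(self, rng):
        p = compile_pattern("[LI]-X(2,6)-G")
        for _ in range(30):
            s = "".join(rng.choice(list("LIGA"), 40))
            for h in find_matches(p, prot(s)):
                assert p.min_length <= h.end - h.start + 1 <= p.max_length
                assert h.end <= len(s)


def motif_bearing(rng, length=450):
    from cngckit.simulate import _motif_instance
    pat = compile_pattern(CNGC_CONSENSUS)
    motif = _motif_instance(pat, rng)
    body = "".join(rng.choice(list("ASDFGHKLQWERTY"), length - len(motif)))
    return body[:100] + motif + body[100:]


class TestClassification:
    def test_accepted_with_domains_and_motif(self, rng):
        r = classify_candidate(prot(motif_bearing(rng)),
                               DomainAnnotation("p", BOTH_DOMAINS))
        assert r.verdict == "accepted" and r.reasons == ()

    def test_missing_motif_only_reason(self, rng):
        s = "".join(rng.choice(list("ASDFGHKNQR"), 450))
        r = classify_candidate(prot(s), DomainAnnotation("p", BOTH_DOMAINS))
        assert r.verdict == "rejected"
        assert r.reasons == ("missing_CNGC_motif",)

    def test_all_reasons_enumerated(self):
        r = classify_candidate(prot("A" * 100), None)
        assert set(r.reasons) == {"missing_CNBD", "missing_ion_transport",
                                  "missing_CNGC_motif", "truncated"}

    def test_absent_annotation_row_means_no_domains(self, rng):
        r = classify_candidate(prot(motif_bearing(rng)), None)
        assert "missing_CNBD" in r.reasons

    def test_monotone_in_domain_labels(self, rng):
        # adding a domain label can only remove reasons, never flip
        # accepted -> rejected
        seqs = [motif_bearing(rng), "".join(rng.choice(list("ANQR"), 450))]
        for s in seqs:
            subsets = [frozenset(), frozenset({patterns.CNBD_LABEL}),
                       BOTH_DOMAINS]
            verdicts = [classify_candidate(
                prot(s), DomainAnnotation("p", labels)).reasons
                for labels in subsets]
            for smaller, larger in zip(verdicts[1:], verdicts):
                assert set(smaller) <= set(larger)

    def test_unknown_annotation_id_error(self, rng):
        with pytest.raises(KeyError, match="ghost"):
            patterns.classify_family(
                [prot("A" * 500)],
                {"ghost": DomainAnnotation("ghost", BOTH_DOMAINS)})
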