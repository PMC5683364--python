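"""Alignment vs exhaustive enumeration, Nei-Gojobori against hand-enumerated
site counts, omega sign recovery, and duplication/fractionation rules."""

import math

import pandas as pd
import pytest

from cngckit import evolution
from cngckit.evolution import (EvolutionError, call_tandem,
                               codon_backtranslate, global_protein_align,
                               nei_gojobori, summarize_fractionation,
                               tandem_clusters)
from cngckit.seqio import GeneModel, SequenceRecord
from cngckit.simulate import SimulationConfig, simulate_codon_pairs


def prot(seq, pid="p"):
    return SequenceRecord(pid, seq, "protein")


def codons(cds):
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


# ---------------------------------------------------------------------------
# Needleman-Wunsch
# ---------------------------------------------------------------------------

def brute_force_best_score(a, b, matrix, gap):
    """Enumerate every global alignment recursively; return the best score."""
    best = [-math.inf]

    def go(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, score + matrix[a[i], b[j]])
        if i < len(a):
            go(i + 1, j, score - gap)
        if j < len(b):
            go(i, j + 1, score - gap)

    go(0, 0, 0.0)
    return best[0]


class TestGlobalAlign:
    def test_identical_gapless(self):
        a, b, score = global_protein_align(prot("ACDEF"), prot("ACDEF"))
        assert a == b == "ACDEF"
        m = evolution._BLOSUM62
        assert score == sum(m[c, c] for c in "ACDEF")

    def test_single_gap(self):
        a, b, _ = global_protein_align(prot("ACD"), prot("AD"))
        assert a == "ACD" and b == "A-D"

    def test_deterministic_traceback(self):
        # same inputs always give the identical alignment
        res1 = global_protein_align(prot("AACD"), prot("ACD"))
        res2 = global_protein_align(prot("AACD"), prot("ACD"))
        assert res1 == res2

    def test_score_equals_brute_force(self, rng):
        m = evolution._BLOSUM62
        for _ in range(15):
            a = "".join(rng.choice(list("ACDEFGHIK"),
                                   int(rng.integers(1, 7))))
            b = "".join(rng.choice(list("ACDEFGHIK"),
                                   int(rng.integers(1, 7))))
            _, _, score = global_protein_align(prot(a), prot(b))
            assert score == pytest.approx(
                brute_force_best_score(a, b, m, 8.0))


# ---------------------------------------------------------------------------
# Codon back-translation
# ---------------------------------------------------------------------------

class TestBacktranslate:
    def test_gapless_concatenation(self):
        ca, cb = codon_backtranslate("MK", "MK", "ATGAAA", "ATGAAG")
        assert ca == ["ATG", "AAA"] and cb == ["ATG", "AAG"]

    def test_gap_becomes_triple_dash(self):
        ca, cb = codon_backtranslate("MK", "M-", "ATGAAA", "ATG")
        assert cb == ["ATG", "---"]

    def test_length_not_divisible_error(self):
        with pytest.raises(EvolutionError, match="divisible"):
            codon_backtranslate("MK", "MK", "ATGAA", "ATGAAA")

    def test_translation_mismatch_names_codon(self):
        with pytest.raises(EvolutionError, match="codon index 1"):
            codon_backtranslate("MK", "MK", "ATGCCC", "ATGAAA")

    def test_terminal_stop_dropped(self):
        ca, _ = codon_backtranslate("MK", "MK", "ATGAAATAA", "ATGAAA")
        assert ca == ["ATG", "AAA"]


# ---------------------------------------------------------------------------
# Nei-Gojobori
# ---------------------------------------------------------------------------

class TestNeiGojobori:
    def test_identical_pair_undefined(self):
        r = nei_gojobori(codons("ATGAAA"), codons("ATGAAA"))
        assert r.Ka == 0 and r.Ks == 0
        assert r.selection_class == "undefined" and r.ratio is None

    def test_hand_enumerated_two_codons(self):
        # ATG has no synonymous changes; AAA and AAC each offer one
        # synonymous change among their third-position alternatives
        r = nei_gojobori(codons("ATGAAA"), codons("ATGAAC"))
        assert r.S == pytest.approx(1 / 3)
        assert r.N == pytest.approx(17 / 3)
        assert (r.Sd, r.Nd) == (0.0, 1.0)
        assert r.Ks == 0.0
        assert r.Ka == pytest.approx(0.2012, abs=2e-4)

    def test_site_counts_sum_to_three_per_codon(self, rng):
        sense = sorted(evolution.CODON_TABLE)
        for _ in range(10):
            cds = "".join(sense[i] for i in rng.integers(0, 61, 20))
            r = nei_gojobori(codons(cds), codons(cds))
            assert r.S + r.N == pytest.approx(3 * 20)

    def test_symmetric_under_swap(self):
        a, b = codons("ATGAAATTGGCC"), codons("ATGAACCTGGGC")
        r1, r2 = nei_gojobori(a, b), nei_gojobori(b, a)
        assert (r1.Ka, r1.Ks) == (r2.Ka, r2.Ks)

    def test_gap_and_stop_columns_excluded(self):
        r = nei_gojobori(["ATG", "---", "TAA", "AAA"],
                         ["ATG", "AAA", "TAC", "AAA"])
        assert r.S + r.N == pytest.approx(6)  # two comparable codons

    def test_saturation_flagged_undefined(self):
        # force pn >= 3/4 via maximally different codons
        r = nei_gojobori(codons("TGGTGGTGG"), codons("CAACAACAA"))
        assert r.selection_class == "undefined"

    def test_omega_sign_recovery_quick(self):
        cfg = SimulationConfig(seed=11)
        pairs = simulate_codon_pairs(cfg, n_pairs_per_omega=5)
        for r in pairs.itertuples():
            res = nei_gojobori(codons(r.cds_a), codons(r.cds_b))
            assert (res.ratio > 1) == (r.omega > 1)


# ---------------------------------------------------------------------------
# Duplication and fractionation
# ---------------------------------------------------------------------------

def gene(gid, chrom, start, end):
    return GeneModel(gid, chrom, "+", start, end, [(start, end)],
                     family_id="F")


class TestTandem:
    def test_pair_under_50kb(self):
        calls = call_tandem([gene("a", "C1", 100_000, 105_000),
                             gene("b", "C1", 130_000, 136_000)], "F")
        assert calls[0].kind == "tandem" and calls[0].distance_bp == 25_000

    def test_different_chromosomes_none(self):
        calls = call_tandem([gene("a", "C1", 1, 1000),
                             gene("b", "C2", 1, 1000)], "F")
        assert calls[0].kind == "none" and calls[0].distance_bp is None

    def test_overlap_distance_zero(self):
        calls = call_tandem([gene("a", "C1", 100, 5000),
                             gene("b", "C1", 4000, 9000)], "F")
        assert calls[0].distance_bp == 0

    def test_transitive_three_gene_cluster(self):
        # A-B 40 kb, B-C 40 kb, A-C 85 kb: one cluster of three
        a = gene("a", "C1", 100_000, 102_000)
        b = gene("b", "C1", 142_000, 147_000)
        c = gene("c", "C1", 187_000, 190_000)
        clusters = tandem_clusters(call_tandem([a, b, c], "F"))
        assert clusters == [frozenset({"a", "b", "c"})]

    def test_invariant_under_relabel_and_translation(self):
        models = [gene("x", "C1", 10_000, 12_000),
                  gene("y", "C1", 50_000, 52_000)]
        shifted = [gene("u", "C9", 1_010_000, 1_012_000),
                   gene("v", "C9", 1_050_000, 1_052_000)]
        k1 = [c.kind for c in call_tandem(models, "F")]
        k2 = [c.kind for c in call_tandem(shifted, "F")]
        assert k1 == k2 == ["tandem"]


class TestFractionation:
    def test_study_counts(self):
        table = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(26)],
            "subgenome": ["LF"] * 14 + ["MF-I"] * 10 + ["MF-II"] * 2})
        assert summarize_fractionation(table) == \
            {"LF": 14, "MF-I": 10, "MF-II": 2}

    def test_empty_all_zero(self):
        assert summarize_fractionation({}) == \
            {"LF": 0, "MF-I": 0, "MF-II": 0}

    def test_unknown_label_error(self):
        with pytest.raises(EvolutionError, match="bogus"):
            summarize_fractionation({"g1": "bogus"})
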