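"""Genetic code, translation, start/stop classes, codon counts and RSCU."""

import math
import random
from collections import Counter

import pytest
from Bio.Data import CodonTable
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from mitochar import (ARTHROPOD_VARIANT, INVERTEBRATE_MITO, aa_frequencies, build_usage,
                      classify_start_codon, classify_stop_codon, codon_counts, rscu,
                      translate_cds)
from mitochar.codons import ALL_CODONS


class TestGeneticCodes:
    def test_invertebrate_code_reassignments(self):
        c = INVERTEBRATE_MITO.codon_to_aa
        assert c["AGA"] == "S" and c["AGG"] == "S"
        assert c["ATA"] == "M" and c["TGA"] == "W"
        assert c["TAA"] == "*" and c["TAG"] == "*"

    def test_leu_and_ser_family_sizes(self):
        fams = INVERTEBRATE_MITO.families()
        assert len(fams["L"]) == 6  # TTR + CTN
        assert len(fams["S"]) == 8  # TCN + AGN

    def test_arthropod_variant_moves_agg_to_lysine(self):
        assert ARTHROPOD_VARIANT.codon_to_aa["AGG"] == "K"
        assert ARTHROPOD_VARIANT.codon_to_aa["AGA"] == "S"


class TestStartCodon:
    @pytest.mark.parametrize("cds,cls,triplet", [
        ("ATGAAATAA", "ATN", "ATG"),
        ("ATTAAATAA", "ATN", "ATT"),
        ("ATAAAATAA", "ATN", "ATA"),
        ("ATCAAATAA", "ATN", "ATC"),
        ("CGAGCATAA", "CGA", "CGA"),
        ("TTGAAATAA", "other", "TTG"),
    ])
    def test_classification(self, cds, cls, triplet):
        assert classify_start_codon(cds) == (cls, triplet)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            classify_start_codon("AT")


class TestStopCodon:
    def test_rule_table_exhaustive_over_all_short_suffixes(self):
        """Every 1-3 nt suffix appended to a codon-aligned body follows the rule table."""
        body = "ATGAAA"
        for k in (1, 2, 3):
            for i in range(4 ** k):
                suffix = "".join("ACGT"[(i // 4 ** j) % 4] for j in range(k))
                got = classify_stop_codon(body + suffix)
                if k == 3:
                    expected = {"TAA": "complete_TAA", "TAG": "complete_TAG"}.get(suffix, "other")
                elif k == 1:
                    expected = "incomplete_T" if suffix == "T" else "other"
                else:
                    expected = "incomplete_TA" if suffix == "TA" else "other"
                assert got == expected, (suffix, got, expected)

    def test_complete_stop_implies_codon_multiple(self):
        for cds in ("ATGAAATAA", "ATGAAAT", "ATGAAATA"):
            cls = classify_stop_codon(cds)
            if cls.startswith("complete"):
                assert len(cds) % 3 == 0


class TestTranslate:
    def test_tga_is_tryptophan(self):
        t = translate_cds("ATGTGATAA")
        assert t.peptide == "MW" and t.internal_stops == ()

    def test_aga_agg_are_serine(self):
        assert translate_cds("AGAAGG").peptide == "SS"

    def test_internal_stop_flagged_not_fatal(self):
        t = translate_cds("ATGTAAATG")
        assert t.peptide == "M*M" and t.internal_stops == (1,)

    def test_incomplete_terminal_codon_dropped_and_flagged(self):
        t = translate_cds("ATGAAAT")
        assert t.peptide == "MK" and t.trailing_bases == 1

    def test_matches_independent_table_lookup_on_random_sequences(self):
        rng = random.Random(42)
        table = CodonTable.unambiguous_dna_by_id[5]
        for _ in range(5):
            cds = "".join(rng.choice("ACGT") for _ in range(300 * 3))
            expected = []
            for i in range(0, len(cds), 3):
                codon = cds[i : i + 3]
                expected.append("*" if codon in table.stop_codons
                                else table.forward_table[codon])
            if expected[-1] == "*":
                expected.pop()
            assert translate_cds(cds).peptide == "".join(expected)

    def test_agrees_with_biopython_translate(self):
        rng = random.Random(7)
        cds = "".join(rng.choice("ACGT") for _ in range(120 * 3))
        ours = translate_cds(cds).peptide
        theirs = str(Seq(cds).translate(table=5)).rstrip("*")
        assert ours == theirs


class TestCodonCounts:
    def test_terminal_stop_excluded(self):
        t = codon_counts(["ATGTAA"])
        assert t.counts["ATG"] == 1 and t.counts["TAA"] == 0 and t.n_codons == 1

    def test_counts_accumulate_across_cds(self):
        t = codon_counts(["ATGATGTAA", "ATGTAA"])
        assert t.counts["ATG"] == 3

    def test_incomplete_terminal_codon_excluded(self):
        t = codon_counts(["ATGAAAT"])
        assert t.n_codons == 2  # ATG + AAA, trailing T dropped

    def test_ambiguous_codons_skipped_and_tallied(self):
        t = codon_counts(["ATGANATAA"])
        assert t.skipped_ambiguous == 1 and t.n_codons == 1

    def test_order_invariance(self):
        a = codon_counts(["ATGTTTTAA", "CGACCCTAA"])
        b = codon_counts(["CGACCCTAA", "ATGTTTTAA"])
        assert a.counts == b.counts


class TestRscu:
    def test_uniform_family_gives_unity(self):
        t = codon_counts(["TTTTTC"])  # Phe family TTT:1 TTC:1
        t = rscu(t)
        assert t.rscu["TTT"] == 1.0 and t.rscu["TTC"] == 1.0

    def test_skewed_two_codon_family(self):
        t = codon_counts(["TTTTTT"])
        t = rscu(t)
        assert t.rscu["TTT"] == 2.0 and t.rscu["TTC"] == 0.0

    def test_matches_independent_counting_pass_on_random_codons(self):
        rng = random.Random(11)
        cds = "".join(rng.choice(ALL_CODONS) for _ in range(500))
        table = rscu(codon_counts([cds]))
        # independent oracle: recount with Biopython's table directly
        ncbi = CodonTable.unambiguous_dna_by_id[5]
        counts = Counter(cds[i : i + 3] for i in range(0, len(cds), 3))
        if cds[-3:] in ncbi.stop_codons:
            counts[cds[-3:]] -= 1
        fams = {}
        for codon, aa in ncbi.forward_table.items():
            fams.setdefault(aa, []).append(codon)
        for aa, fam in fams.items():
            total = sum(counts[c] for c in fam)
            for c in fam:
                expected = counts[c] * len(fam) / total if total else 0.0
                assert math.isclose(table.rscu[c], expected, abs_tol=1e-12), c

    @given(st.lists(st.sampled_from(ALL_CODONS), min_size=1, max_size=300))
    @settings(max_examples=40, deadline=None)
    def test_family_sums_equal_family_size(self, codons):
        table = rscu(codon_counts(["".join(codons) + "TAA"]))
        for aa, fam in INVERTEBRATE_MITO.families().items():
            total = sum(table.counts[c] for c in fam)
            if total:
                assert math.isclose(sum(table.rscu[c] for c in fam), len(fam),
                                    abs_tol=1e-9), aa


class TestAaFrequencies:
    def test_single_codon(self):
        assert aa_frequencies(["ATGTAA"]) == {"M": 100.0}

    def test_percentages_sum_to_100(self):
        rng = random.Random(5)
        cds = "".join(rng.choice(ALL_CODONS) for _ in range(400))
        freqs = aa_frequencies([cds])
        assert math.isclose(sum(freqs.values()), 100.0, abs_tol=1e-9)

    def test_uniform_codons_approach_family_size_expectation(self):
        rng = random.Random(13)
        sense = [c for c in ALL_CODONS if INVERTEBRATE_MITO.codon_to_aa[c] != "*"]
        cds = "".join(rng.choice(sense) for _ in range(20000))
        freqs = aa_frequencies([cds])
        for aa, fam in INVERTEBRATE_MITO.families().items():
            expected = 100.0 * len(fam) / len(sense)
            assert abs(freqs[aa] - expected) < 1.5 * math.sqrt(expected)


def test_build_usage_on_default_genome_excludes_sampler_codons(default_genome):
    from mitochar import extract_feature_sequence
    cds = [extract_feature_sequence(default_genome, f)
           for f in default_genome.features_of_kind("PCG")]
    usage = build_usage(cds)
    assert usage.counts["AGG"] == 0
    assert usage.counts["CTG"] == 0
    assert usage.counts["CCG"] == 0
    assert usage.n_codons > 3000
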