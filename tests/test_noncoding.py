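"""Spacers, overlaps, repeats, tracts, motifs and alignment identity."""

import random

import pytest

from mitochar import (AnnotatedMitogenome, GeneFeature, catalog_spacers_overlaps,
                      circle_accounting, find_motif, find_poly_tracts,
                      find_tandem_repeats, global_identity, spacer_origin_scan)
from mitochar.noncoding import DEFAULT_MIN_COPIES, _is_primitive, _least_rotation


def _genome(seq, spans):
    feats = [GeneFeature(f"g{i}", "PCG", s, e, st) for i, (s, e, st) in enumerate(spans)]
    return AnnotatedMitogenome("t", seq, feats)


class TestSpacersOverlaps:
    def test_abutting_genes_produce_neither(self):
        g = _genome("ACGTACGTACGTACGTACGT", [(0, 10, "J"), (10, 20, "J")])
        spacers, overlaps = catalog_spacers_overlaps(g)
        assert spacers.total_count == 0 and overlaps.total_count == 0

    def test_seven_bp_overlap(self):
        g = _genome("ACGTACGTACGTACGTACGT", [(0, 12, "J"), (5, 20, "J")])
        spacers, overlaps = catalog_spacers_overlaps(g)
        assert overlaps.total_count == 1
        o = overlaps.entries[0]
        assert o.length == 7 and o.sequence == g.sequence[5:12]

    def test_origin_spanning_spacer(self):
        g = _genome("ACGTACGTACGTACGTACGT", [(2, 10, "J"), (12, 18, "J")])
        spacers, _ = catalog_spacers_overlaps(g)
        wrap = spacers.between("g1", "g0")
        assert wrap is not None and wrap.length == 4
        assert wrap.sequence == g.sequence[18:] + g.sequence[:2]

    def test_contained_feature_excluded_with_warning(self):
        g = _genome("ACGTACGTACGTACGTACGT", [(0, 15, "J"), (3, 8, "J"), (15, 20, "J")])
        with pytest.warns(UserWarning, match="contained"):
            spacers, overlaps = catalog_spacers_overlaps(g)
        assert overlaps.containments == [("g1", "g0")]
        assert spacers.total_count == 0 and overlaps.total_count == 0

    def test_circle_accounting_identity_on_default_genome(self, default_genome):
        acc = circle_accounting(default_genome)
        assert acc["residual"] == 0

    def test_planted_junction_lengths(self, default_genome, default_truth):
        spacers, overlaps = catalog_spacers_overlaps(default_genome)
        s1 = spacers.between("trnQ", "nad2")
        assert s1.length == 61 and abs(s1.at_percent - 96.72) < 0.01
        assert spacers.between("trnS2", "nad1").length == 16
        assert overlaps.between("atp8", "atp6").length == 7
        assert overlaps.between("atp8", "atp6").sequence == "ATGATAA"
        assert overlaps.between("trnW", "trnC").length == 8
        assert overlaps.total_bp == 35 and overlaps.total_count == 8


def brute_force_repeats(seq, max_unit=6):
    """O(n^2) direct-extension scan, independent of the library's run-based finder."""
    hits = set()
    n = len(seq)
    for u in range(1, max_unit + 1):
        for i in range(n - u):
            # extend right while the period holds
            j = i + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            if j == i + u:
                continue
            # maximal on the left?
            if i > 0 and i - 1 + u < n and seq[i - 1] == seq[i - 1 + u]:
                continue
            unit = seq[i : i + u]
            if not _is_primitive(unit):
                continue
            copies = (j - i) / u
            if copies >= DEFAULT_MIN_COPIES.get(u, 3):
                hits.add((i, j))
    # identical region under several unit sizes: keep the smallest unit
    dedup = {}
    for (i, j) in sorted(hits):
        dedup.setdefault((i, j), (i, j))
    return set(dedup)


class TestTandemRepeats:
    def test_dinucleotide_array(self):
        hits = find_tandem_repeats("TATATATATA")
        assert len(hits) == 1
        h = hits[0]
        assert h.unit == "TA" and h.copies == 5.0 and (h.start, h.end) == (0, 10)
        assert h.canonical_unit == "AT"

    def test_tetranucleotide_array(self):
        hits = find_tandem_repeats("TTATTTATTTAT")
        assert len(hits) == 1
        h = hits[0]
        assert h.copies == 3.0 and h.canonical_unit == _least_rotation("TTAT") == "ATTT"

    def test_fractional_trailing_copy(self):
        (h,) = find_tandem_repeats("CCTATATATATAGG", min_copies={2: 4})
        assert h.copies == 5.0 and (h.start, h.end) == (2, 12)
        (h,) = find_tandem_repeats("CCTATATATATGG", min_copies={2: 4})
        assert h.copies == 4.5

    def test_non_primitive_units_not_duplicated(self):
        hits = find_tandem_repeats("TATATATATATA")
        assert [h.unit for h in hits] == ["TA"]

    def test_equals_brute_force_on_random_sequences(self):
        rng = random.Random(17)
        for trial in range(3):
            seq = "".join(rng.choices("ACGT", weights=[4, 1, 1, 4], k=2000))
            ours = {(h.start, h.end) for h in find_tandem_repeats(seq)}
            assert ours == brute_force_repeats(seq), trial


class TestPolyTracts:
    def test_single_long_run(self):
        (h,) = find_poly_tracts("TTTTTTTTTT", "T", 8)
        assert h.length == 10 and (h.start, h.end) == (0, 10)

    def test_interrupted_runs_below_threshold(self):
        assert find_poly_tracts("TTTTATTTT", "T", 5) == []

    def test_min_length_floor(self):
        with pytest.raises(ValueError):
            find_poly_tracts("TTTTT", "T", 3)


class TestMotifs:
    def test_one_mismatch_hit(self):
        hits = find_motif("GGATACTATGG", "ATACTAA", 1)
        assert len(hits) == 1 and hits[0].position == 2 and hits[0].mismatches == 1

    def test_exact_absent(self):
        assert find_motif("GGATACTATGG", "ATACTAA", 0) == []

    def test_reverse_strand_scan(self):
        seq = "CC" + "TTAGTAT" + "CC"  # revcomp(ATACTAA)
        hits = find_motif(seq, "ATACTAA", 0, both_strands=True)
        assert [h.strand for h in hits] == ["N"] and hits[0].position == 2


class TestGlobalIdentity:
    def test_identical_sequences(self):
        r = global_identity("ACGTACGTAC" * 5, "ACGTACGTAC" * 5)
        assert r.identity == 100.0 and r.matches == r.columns == 50

    def test_single_substitution(self):
        r = global_identity("ACGT", "ACGA")
        assert r.identity == 75.0 and r.matches == 3 and r.columns == 4

    def test_identity_100_iff_identical(self):
        rng = random.Random(23)
        for _ in range(30):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 20)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 20)))
            r = global_identity(a, b)
            assert (r.identity == 100.0) == (a == b)

    def test_symmetry(self):
        rng = random.Random(29)
        for _ in range(40):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 25)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 25)))
            assert global_identity(a, b).score == global_identity(b, a).score
            assert global_identity(a, b).identity == global_identity(b, a).identity

    def test_score_equals_exhaustive_alignment_enumeration(self):
        def all_alignment_scores(a, b):
            # enumerate every global alignment recursively
            if not a and not b:
                return [0]
            out = []
            if a and b:
                sub = 1 if a[0] == b[0] else -1
                out += [sub + s for s in all_alignment_scores(a[1:], b[1:])]
            if a:
                out += [-2 + s for s in all_alignment_scores(a[1:], b)]
            if b:
                out += [-2 + s for s in all_alignment_scores(a, b[1:])]
            return out

        rng = random.Random(31)
        for _ in range(8):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 7)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 7)))
            assert global_identity(a, b).score == max(all_alignment_scores(a, b))

    def test_score_matches_biopython_aligner(self):
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.match_score, aligner.mismatch_score = 1, -1
        aligner.open_gap_score = aligner.extend_gap_score = -2
        rng = random.Random(37)
        for _ in range(25):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 60)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 60)))
            assert global_identity(a, b).score == aligner.score(a, b)


class TestSpacerOriginScan:
    def test_exact_substring_found_at_offset(self):
        rng = random.Random(41)
        gene = "".join(rng.choice("ACGT") for _ in range(300))
        off, res = spacer_origin_scan(gene[100:140], gene)
        assert res.identity == 100.0 and off == 100

    def test_degraded_duplicate_recovered(self):
        rng = random.Random(43)
        gene = "".join(rng.choice("ACGT") for _ in range(400))
        spacer = list(gene[200:260])
        for p in rng.sample(range(60), 6):  # 10% substitutions
            spacer[p] = rng.choice([c for c in "ACGT" if c != spacer[p]])
        off, res = spacer_origin_scan("".join(spacer), gene)
        assert off == 200 and 85.0 <= res.identity < 100.0

    def test_unrelated_spacer_below_shuffled_null(self):
        rng = random.Random(47)
        gene = "".join(rng.choices("ACGT", weights=[4, 1, 1, 4], k=400))
        true_spacer = list(gene[150:200])
        for p in rng.sample(range(50), 5):
            true_spacer[p] = rng.choice([c for c in "ACGT" if c != true_spacer[p]])
        true_id = spacer_origin_scan("".join(true_spacer), gene)[1].identity
        null = []
        for _ in range(19):
            shuffled = true_spacer[:]
            rng.shuffle(shuffled)
            null.append(spacer_origin_scan("".join(shuffled), gene)[1].identity)
        assert true_id > max(null)  # above the ~95th percentile of the null
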