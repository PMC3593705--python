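"""Cloverleaf folding: planted-structure recovery, brute-force oracle, census."""

import random

import pytest

from mitochar import (census_mismatches, fold_cloverleaf, generate_trna,
                      pairs_from_dot_bracket, to_dot_bracket)


def brute_force_best_score(seq: str) -> int:
    """Independent exhaustive enumeration of all legal cloverleaf boundary
    assignments, scoring WC+GU pairs directly.  Recursive formulation, kept
    deliberately separate from the library's search."""
    L = len(seq)
    good = {"AT", "TA", "GC", "CG", "GT", "TG"}

    def stem_score(i5, i3_end, n):
        # pairs (i5+k, i3_end-1-k)
        return sum(1 for k in range(n) if seq[i5 + k] + seq[i3_end - 1 - k] in good)

    best = -1
    for s1 in range(0, 4):
        for dlen in (3, 4):
            for dloop in range(4, 13):
                for s2 in range(0, 4):
                    ac5 = 7 + s1 + 2 * dlen + dloop + s2
                    for var in range(3, 10):
                        for tlen in (4, 5):
                            for tloop in range(3, 10):
                                for disc in range(0, 4):
                                    total = (ac5 + 17 + var + 2 * tlen + tloop + 7 + disc)
                                    if total != L:
                                        continue
                                    t5 = ac5 + 17 + var
                                    acc3_end = L - disc
                                    s = (stem_score(0, acc3_end, 7)
                                         + stem_score(7 + s1, 7 + s1 + 2 * dlen + dloop, dlen)
                                         + stem_score(ac5, ac5 + 17, 5)
                                         + stem_score(t5, t5 + 2 * tlen + tloop, tlen))
                                    best = max(best, s)
    return best


class TestPlantedRecovery:
    def test_perfect_template_recovered_exactly(self):
        seq, planted = generate_trna("trnM", 0, seed=3)
        fold = fold_cloverleaf(seq, expected_anticodon="CAT")
        assert fold.segments == planted.segments
        assert fold.pairs == planted.pairs
        assert sum(1 for p in fold.pairs if p[2] != "WC") == 0
        assert fold.anticodon == "CAT"

    def test_two_planted_pairs_census(self):
        seq, planted = generate_trna("trnD", [("DHU", "G-U"), ("acceptor", "A-A")], seed=5)
        fold = fold_cloverleaf(seq, expected_anticodon="GTC")
        assert fold.segments == planted.segments
        census = census_mismatches([fold])
        assert census.total == 2 and census.gu == 1
        assert census.by_class == {"G-U": 1, "A-A": 1}
        assert census.per_arm["DHU"] == 1 and census.per_arm["acceptor"] == 1

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_k_planted_pairs_recovered_exactly(self, k):
        seq, planted = generate_trna("trnG", k, seed=20 + k)
        fold = fold_cloverleaf(seq, expected_anticodon="TCC")
        assert fold.segments == planted.segments
        assert census_mismatches([fold]).total == k

    def test_dhu_less_template_returns_dhu_less_topology(self):
        seq, planted = generate_trna("trnS1", 0, seed=9)
        fold = fold_cloverleaf(seq, expected_anticodon="GCT", allow_dhu_less=True)
        assert fold.topology == "DHU_less"
        assert "DHU5" not in fold.segments
        assert fold.segments == planted.segments


class TestBruteForceOracle:
    def test_score_equals_exhaustive_enumeration(self):
        seqs = []
        for i, name in enumerate(["trnM", "trnW", "trnK", "trnE"]):
            seqs.append(generate_trna(name, i % 3, seed=40 + i)[0])
        rng = random.Random(0)
        while len(seqs) < 7:  # adversarial random sequences too
            seqs.append("".join(rng.choice("ACGT") for _ in range(rng.randint(60, 70))))
        for seq in seqs:
            if len(seq) > 70:
                continue
            fold = fold_cloverleaf(seq)
            assert fold.score == brute_force_best_score(seq), seq


class TestFoldBasics:
    def test_deterministic(self):
        seq = generate_trna("trnA", 2, seed=2)[0]
        f1, f2 = fold_cloverleaf(seq), fold_cloverleaf(seq)
        assert f1.segments == f2.segments and f1.pairs == f2.pairs

    def test_every_pair_classified(self):
        seq = generate_trna("trnV", 3, seed=8)[0]
        fold = fold_cloverleaf(seq)
        assert all(cls in ("WC", "GU", "mismatch") for (_, _, cls) in fold.pairs)

    def test_anticodon_is_loop_center(self):
        seq, planted = generate_trna("trnH", 0, seed=1)
        fold = fold_cloverleaf(seq, expected_anticodon="GTG")
        s, e = fold.segments["anticodonloop"]
        assert e - s == 7
        assert fold.sequence[s + 2 : s + 5] == fold.anticodon == "GTG"

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            fold_cloverleaf("ACGT" * 10)  # 40 nt, below range


class TestCensus:
    def test_all_perfect_folds_give_zero(self):
        folds = [fold_cloverleaf(generate_trna(n, 0, seed=i)[0])
                 for i, n in enumerate(["trnM", "trnI"])]
        census = census_mismatches(folds)
        assert census.total == 0 and census.gu == 0 and census.by_class == {}

    def test_total_equals_sum_over_arms(self, default_genome, default_truth):
        folds = [t["fold"] for t in default_truth.trna.values()]
        census = census_mismatches(folds)
        assert census.total == sum(census.per_arm.values())
        assert census.gu == census.by_class.get("G-U", 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            census_mismatches([])


class TestDotBracket:
    def test_cloverleaf_has_four_helix_blocks_and_round_trips(self):
        seq = generate_trna("trnQ", 0, seed=4)[0]
        fold = fold_cloverleaf(seq, expected_anticodon="TTG")
        db = to_dot_bracket(fold)
        assert len(db) == len(seq)
        blocks = sum(1 for i, ch in enumerate(db)
                     if ch == "(" and (i == 0 or db[i - 1] != "("))
        assert blocks == 4
        assert pairs_from_dot_bracket(db) == {(i, j) for (i, j, _) in fold.pairs}

    def test_dhu_less_has_three_helix_blocks(self):
        seq = generate_trna("trnS1", 0, seed=6)[0]
        fold = fold_cloverleaf(seq, expected_anticodon="GCT", allow_dhu_less=True)
        db = to_dot_bracket(fold)
        blocks = sum(1 for i, ch in enumerate(db)
                     if ch == "(" and (i == 0 or db[i - 1] != "("))
        assert blocks == 3

    def test_unbalanced_string_rejected(self):
        with pytest.raises(ValueError):
            pairs_from_dot_bracket("((..)")
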