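"""Fold tRNA genes into constrained cloverleaves and tally their mismatches.

The folder searches every arm-boundary assignment allowed by canonical tRNA
geometry and keeps the one pairing the most stem positions (Watson-Crick +
G-U wobble).  trnS1(AGN) lacks the DHU arm, so it is folded with a DHU-less
topology.
"""

from mitochar import census_mismatches, fold_cloverleaf, generate_trna, to_dot_bracket

# a clean tRNA-Met, then one with two planted non-WC pairs
seq, _ = generate_trna("trnM", 0, seed=1)
fold = fold_cloverleaf(seq, expected_anticodon="CAT")
print(f"trnM  {len(seq)} nt  topology={fold.topology}  anticodon={fold.anticodon}  "
      f"{fold.score}/{len(fold.pairs)} stem positions paired")
print(seq)
print(to_dot_bracket(fold))
# four '(' blocks = acceptor, DHU, anticodon and TpsiC helices of the cloverleaf

seq2, _ = generate_trna("trnD", [("DHU", "G-U"), ("acceptor", "A-A")], seed=5)
fold2 = fold_cloverleaf(seq2, expected_anticodon="GTC")
census = census_mismatches([fold2])
print(f"\ntrnD with planted pairs -> census: total={census.total} "
      f"G-U={census.gu} classes={census.by_class} arms={census.per_arm}")
# the census separates weakly bonding G-U wobbles from true mismatches

seq3, _ = generate_trna("trnS1", 0, seed=9)
fold3 = fold_cloverleaf(seq3, expected_anticodon="GCT", allow_dhu_less=True)
print(f"\ntrnS1(AGN)  topology={fold3.topology}  (three helix blocks, no DHU stem)")
print(to_dot_bracket(fold3))
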