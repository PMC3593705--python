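"""Constrained cloverleaf folding of mitochondrial tRNA genes.

Mitochondrial tRNAs are short (here 55-90 nt) and their secondary structure
is the canonical cloverleaf: acceptor stem (7 bp), DHU arm, anticodon arm
(5 bp stem, 7 nt loop with the anticodon at its center), variable region and
TpsiC arm, closed by the acceptor 3' side and a short discriminator tail.
Rather than folding thermodynamically, this module searches exhaustively
over all arm-boundary assignments allowed by the canonical geometry and
keeps the assignment pairing the most stem positions (Watson-Crick plus G-U
wobble), which is how such structures are inferred by inspection.  DNA
letters are used throughout (T for U); rendering may transliterate.

The metazoan trnS1(AGN) lacks the DHU arm; a DHU-less topology replacing the
arm with an unpaired region is searched when requested and kept when the
cloverleaf fold pairs its mandatory stems poorly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "CloverleafConstraints", "DEFAULT_CONSTRAINTS", "TrnaFold", "MismatchCensus",
    "pair_class", "fold_cloverleaf", "census_mismatches",
    "to_dot_bracket", "pairs_from_dot_bracket",
]

_WC = {"AT", "TA", "GC", "CG"}
_GU = {"GT", "TG"}


def pair_class(a: str, b: str) -> str:
    """Classify a base pair as WC, GU (wobble) or mismatch."""
    ab = a + b
    if ab in _WC:
        return "WC"
    if ab in _GU:
        return "GU"
    return "mismatch"


def mismatch_label(a: str, b: str) -> str:
    """Unordered pair label in RNA letters, e.g. 'G-U', 'A-A', 'C-U'."""
    x, y = sorted(base.replace("T", "U") for base in (a, b))
    return f"{x}-{y}"


@dataclass(frozen=True)
class CloverleafConstraints:
    """Canonical tRNA geometry: fixed acceptor/anticodon arms, bounded elsewhere."""

    acceptor_stem: int = 7
    dhu_stem: tuple[int, int] = (3, 4)
    dhu_loop: tuple[int, int] = (4, 12)
    anticodon_stem: int = 5
    anticodon_loop: int = 7
    tpsic_stem: tuple[int, int] = (4, 5)
    tpsic_loop: tuple[int, int] = (3, 9)
    variable: tuple[int, int] = (3, 9)
    spacer: tuple[int, int] = (0, 3)        # between acceptor/DHU and DHU/anticodon
    discriminator: tuple[int, int] = (0, 3)  # unpaired 3' tail
    dhu_replacement: tuple[int, int] = (2, 14)  # unpaired region in DHU-less folds


DEFAULT_CONSTRAINTS = CloverleafConstraints()

#: Stems of each topology, in 5'->3' order of their 5' halves.
_ARMS = ("acceptor", "DHU", "anticodon", "TpsiC")


@dataclass
class TrnaFold:
    """One folded tRNA: segment boundaries, classified pairs, anticodon, score."""

    sequence: str
    topology: str  # cloverleaf | DHU_less | unfoldable
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)
    pairs: list[tuple[int, int, str]] = field(default_factory=list)  # (i, j, class)
    anticodon: Optional[str] = None
    score: int = 0      # WC + GU pairs
    wc_count: int = 0

    @property
    def n_stem_positions(self) -> int:
        return len(self.pairs)

    def arm_of_pair(self, i: int, j: int) -> str:
        for arm in _ARMS:
            seg = self.segments.get(arm + "5")
            if seg and seg[0] <= i < seg[1]:
                return arm
        raise ValueError(f"pair ({i},{j}) not in any stem")

    def stem_fraction(self, arm: str) -> float:
        """Fraction of an arm's positions paired WC or GU; 0 for an absent arm."""
        ps = [p for p in self.pairs if self._in_arm(p, arm)]
        if not ps:
            return 0.0
        good = sum(1 for (_, _, c) in ps if c in ("WC", "GU"))
        return good / len(ps)

    def _in_arm(self, pair, arm: str) -> bool:
        seg = self.segments.get(arm + "5")
        return bool(seg) and seg[0] <= pair[0] < seg[1]

    def mismatches(self) -> list[tuple[int, int, str]]:
        return [p for p in self.pairs if p[2] == "mismatch"]


# ---------------------------------------------------------------------------
# Folding search
# ---------------------------------------------------------------------------


def _segments_cloverleaf(s1, dlen, dloop, s2, var, tlen, tloop, disc, c: CloverleafConstraints):
    p = 0
    segs = {}
    for name, ln in (("acceptor5", c.acceptor_stem), ("spacer1", s1), ("DHU5", dlen),
                     ("DHUloop", dloop), ("DHU3", dlen), ("spacer2", s2),
                     ("anticodon5", c.anticodon_stem), ("anticodonloop", c.anticodon_loop),
                     ("anticodon3", c.anticodon_stem), ("variable", var),
                     ("TpsiC5", tlen), ("TpsiCloop", tloop), ("TpsiC3", tlen),
                     ("acceptor3", c.acceptor_stem), ("discriminator", disc)):
        segs[name] = (p, p + ln)
        p += ln
    return segs, p


def _segments_dhu_less(repl, var, tlen, tloop, disc, c: CloverleafConstraints):
    p = 0
    segs = {}
    for name, ln in (("acceptor5", c.acceptor_stem), ("DHUreplacement", repl),
                     ("anticodon5", c.anticodon_stem), ("anticodonloop", c.anticodon_loop),
                     ("anticodon3", c.anticodon_stem), ("variable", var),
                     ("TpsiC5", tlen), ("TpsiCloop", tloop), ("TpsiC3", tlen),
                     ("acceptor3", c.acceptor_stem), ("discriminator", disc)):
        segs[name] = (p, p + ln)
        p += ln
    return segs, p


def _stem_pairs(segs) -> list[tuple[int, int]]:
    pairs = []
    for arm in _ARMS:
        five = segs.get(arm + "5")
        three = segs.get(arm + "3")
        if not five or not three:
            continue
        ln = five[1] - five[0]
        for i in range(ln):
            pairs.append((five[0] + i, three[1] - 1 - i))
    return pairs


def _score_segments(seq: str, segs) -> tuple[int, int, list[tuple[int, int, str]]]:
    pairs = []
    score = wc = 0
    for i, j in _stem_pairs(segs):
        cls = pair_class(seq[i], seq[j])
        if cls == "WC":
            score += 1
            wc += 1
        elif cls == "GU":
            score += 1
        pairs.append((i, j, cls))
    return score, wc, pairs


def _anticodon(seq: str, segs) -> str:
    s, _ = segs["anticodonloop"]
    return seq[s + 2 : s + 5]


def _search(seq: str, topology: str, expected_anticodon: Optional[str],
            c: CloverleafConstraints) -> Optional[TrnaFold]:
    """Exhaustive search over boundary assignments; deterministic total order.

    Objective: most WC+GU pairs; ties broken by more WC pairs, then by the
    smaller DHU-loop (or replacement-region) start, then by the
    lexicographically smallest boundary tuple.  Stem scores are computed with
    direct index arithmetic and memoized on their geometric parameters, and
    the anticodon anchor is tested before any inner loop runs.
    """
    L = len(seq)
    acc_n, ac_n, ac_loop = c.acceptor_stem, c.anticodon_stem, c.anticodon_loop
    ac_arm = 2 * ac_n + ac_loop

    def stem(i5: int, i3_end: int, n: int) -> tuple[int, int]:
        s = w = 0
        for i in range(n):
            p = seq[i5 + i] + seq[i3_end - 1 - i]
            if p in _WC:
                s += 1
                w += 1
            elif p in _GU:
                s += 1
        return s, w

    acc_by_disc = {d: stem(0, L - d, acc_n)
                   for d in range(c.discriminator[0], c.discriminator[1] + 1)
                   if L - d >= acc_n}
    memo: dict[tuple, tuple[int, int]] = {}

    def stem_memo(i5: int, i3_end: int, n: int) -> tuple[int, int]:
        key = (i5, i3_end, n)
        r = memo.get(key)
        if r is None:
            r = memo[key] = stem(i5, i3_end, n)
        return r

    best_key = None
    if topology == "cloverleaf":
        for s1 in range(c.spacer[0], c.spacer[1] + 1):
            for dlen in range(c.dhu_stem[0], c.dhu_stem[1] + 1):
                for dloop in range(c.dhu_loop[0], c.dhu_loop[1] + 1):
                    for s2 in range(c.spacer[0], c.spacer[1] + 1):
                        ac5 = acc_n + s1 + 2 * dlen + dloop + s2
                        rem = L - ac5 - ac_arm - acc_n
                        if rem < 0:
                            continue
                        loop_start = ac5 + ac_n
                        if expected_anticodon is not None and \
                                seq[loop_start + 2 : loop_start + 5] != expected_anticodon:
                            continue
                        d_s, d_w = stem_memo(acc_n + s1, ac5 - s2, dlen)
                        a_s, a_w = stem_memo(ac5, ac5 + ac_arm, ac_n)
                        for var in range(c.variable[0], c.variable[1] + 1):
                            t5 = ac5 + ac_arm + var
                            for tlen in range(c.tpsic_stem[0], c.tpsic_stem[1] + 1):
                                for disc in range(c.discriminator[0], c.discriminator[1] + 1):
                                    tloop = rem - var - 2 * tlen - disc
                                    if not (c.tpsic_loop[0] <= tloop <= c.tpsic_loop[1]):
                                        continue
                                    t_s, t_w = stem_memo(t5, t5 + 2 * tlen + tloop, tlen)
                                    acc_s, acc_w = acc_by_disc[disc]
                                    score = acc_s + d_s + a_s + t_s
                                    wc = acc_w + d_w + a_w + t_w
                                    key = (-score, -wc, acc_n + s1 + dlen,
                                           (s1, dlen, dloop, s2, var, tlen, tloop, disc))
                                    if best_key is None or key < best_key:
                                        best_key = key
    else:  # DHU_less
        for repl in range(c.dhu_replacement[0], c.dhu_replacement[1] + 1):
            ac5 = acc_n + repl
            rem = L - ac5 - ac_arm - acc_n
            if rem < 0:
                continue
            loop_start = ac5 + ac_n
            if expected_anticodon is not None and \
                    seq[loop_start + 2 : loop_start + 5] != expected_anticodon:
                continue
            a_s, a_w = stem_memo(ac5, ac5 + ac_arm, ac_n)
            for var in range(c.variable[0], c.variable[1] + 1):
                t5 = ac5 + ac_arm + var
                for tlen in range(c.tpsic_stem[0], c.tpsic_stem[1] + 1):
                    for disc in range(c.discriminator[0], c.discriminator[1] + 1):
                        tloop = rem - var - 2 * tlen - disc
                        if not (c.tpsic_loop[0] <= tloop <= c.tpsic_loop[1]):
                            continue
                        t_s, t_w = stem_memo(t5, t5 + 2 * tlen + tloop, tlen)
                        acc_s, acc_w = acc_by_disc[disc]
                        score = acc_s + a_s + t_s
                        wc = acc_w + a_w + t_w
                        key = (-score, -wc, acc_n,
                               (repl, var, tlen, tloop, disc))
                        if best_key is None or key < best_key:
                            best_key = key
    if best_key is None:
        return None
    combo = best_key[3]
    if topology == "cloverleaf":
        segs, total = _segments_cloverleaf(*combo, c)
    else:
        segs, total = _segments_dhu_less(*combo, c)
    assert total == L
    score, wc, pairs = _score_segments(seq, segs)
    assert (score, wc) == (-best_key[0], -best_key[1])
    return TrnaFold(seq, topology, segs, pairs, _anticodon(seq, segs), score, wc)


#: A cloverleaf fold is accepted outright when each mandatory stem
#: (acceptor, anticodon, TpsiC) has at least this fraction of WC+GU pairs.
MANDATORY_STEM_FRACTION = 0.6


def fold_cloverleaf(seq: str, expected_anticodon: Optional[str] = None,
                    allow_dhu_less: bool = False,
                    constraints: CloverleafConstraints = DEFAULT_CONSTRAINTS) -> TrnaFold:
    """Fold one tRNA gene sequence into its best constrained cloverleaf.

    If ``expected_anticodon`` is given only folds placing that triplet at the
    center of the anticodon loop are considered.  With ``allow_dhu_less``,
    when the best cloverleaf pairs any mandatory stem below
    ``MANDATORY_STEM_FRACTION`` a DHU-less fold is also searched and the
    better structure (by fraction of stem positions paired) is returned.
    Returns a fold with topology ``"unfoldable"`` when no boundary assignment
    satisfies the constraints.
    """
    seq = seq.upper()
    if not (55 <= len(seq) <= 90):
        raise ValueError(f"tRNA length {len(seq)} outside the 55-90 nt range")
    cl = _search(seq, "cloverleaf", expected_anticodon, constraints)
    if not allow_dhu_less:
        return cl if cl is not None else TrnaFold(seq, "unfoldable")
    if cl is not None and all(cl.stem_fraction(a) >= MANDATORY_STEM_FRACTION
                              for a in ("acceptor", "anticodon", "TpsiC")):
        return cl
    dl = _search(seq, "DHU_less", expected_anticodon, constraints)
    if cl is None and dl is None:
        return TrnaFold(seq, "unfoldable")
    if cl is None or (dl is not None and
                      dl.score / dl.n_stem_positions > cl.score / cl.n_stem_positions):
        return dl
    return cl


# ---------------------------------------------------------------------------
# Mismatch census
# ---------------------------------------------------------------------------


@dataclass
class MismatchCensus:
    """Genome-wide tally of non-Watson-Crick stem pairs across folded tRNAs."""

    total: int
    per_arm: dict[str, int]
    gu: int
    by_class: dict[str, int]  # unordered RNA-letter pair label -> count
    genes_with_mismatch: int

    def as_dict(self) -> dict:
        return {"total": self.total, "per_arm": dict(self.per_arm), "gu": self.gu,
                "by_class": dict(self.by_class),
                "genes_with_mismatch": self.genes_with_mismatch}


def census_mismatches(folds: Iterable[TrnaFold]) -> MismatchCensus:
    """Aggregate all non-WC pairs (G-U wobbles and true mismatches) by arm and class."""
    folds = list(folds)
    if not folds:
        raise ValueError("census requires at least one fold")
    per_arm = {a: 0 for a in _ARMS}
    by_class: dict[str, int] = {}
    total = gu = 0
    genes = 0
    for fold in folds:
        seen = False
        for (i, j, cls) in fold.pairs:
            if cls == "WC":
                continue
            seen = True
            total += 1
            per_arm[fold.arm_of_pair(i, j)] += 1
            if cls == "GU":
                gu += 1
            label = mismatch_label(fold.sequence[i], fold.sequence[j])
            by_class[label] = by_class.get(label, 0) + 1
        genes += seen
    return MismatchCensus(total, per_arm, gu, by_class, genes)


# ---------------------------------------------------------------------------
# Dot-bracket rendering
# ---------------------------------------------------------------------------


def to_dot_bracket(fold: TrnaFold) -> str:
    """Balanced dot-bracket string of the fold (all stem pairs as brackets)."""
    chars = ["."] * len(fold.sequence)
    for i, j, _ in fold.pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def pairs_from_dot_bracket(db: str) -> set[tuple[int, int]]:
    """Recover the pair set from a dot-bracket string (raises on imbalance)."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.add((stack.pop(), idx))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs
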