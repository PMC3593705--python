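"""Synthetic annotated mitogenomes with exhaustive ground truth.

Generates a circular ~15 kb lepidopteran-style mitogenome: the 37-gene
complement in the derived order (control region - trnM - trnI - trnQ -
nad2 ...), AT-biased partitions, planted intergenic spacers carrying
microsatellites, a control region with the ATAGA + poly-T signature, gene
overlaps including the 7-nt atp8/atp6 overlap sharing the ATGATAA motif,
and tRNA genes emitted from cloverleaf templates with a controlled number
and class of non-Watson-Crick stem pairs.  Every planted element is recorded
in a :class:`TruthTable` so downstream finders can be tested for exact
recovery.

Default parameters are the study conditions of the rice-moth mitogenome this
package models: 15,273 bp total, per-partition A+T targets (PCG 78.96%,
rrnL 82.95%, rrnS 85.86%, control 96.58%), a 61-bp trnQ-nad2 spacer at
96.72% A+T, a 49-bp trnE-trnF spacer containing (TA)18 and (TTAT)3, a 16-bp
trnS2-nad1 spacer with the ATACTAT motif, 35 bp of overlap over 8 regions,
a codon sampler that never emits CTG/CCG/AGG, and a tRNA mismatch plan of
43 non-WC pairs (24 G-U) split 20/8/9/6 over the DHU, acceptor, TpsiC and
anticodon stems across 20 of the 22 tRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codons import classify_start_codon, classify_stop_codon
from .io import CANONICAL_GENE_ORDER, AnnotatedMitogenome, GeneFeature, revcomp
from .trna import (DEFAULT_CONSTRAINTS as _CONS, TrnaFold, _score_segments,
                   _segments_cloverleaf, _segments_dhu_less, fold_cloverleaf)

__all__ = ["GenomeSpec", "TruthTable", "generate_mitogenome", "generate_trna",
           "N_STRAND_GENES", "ANTICODONS", "DEFAULT_MISMATCH_PLAN"]


# ---------------------------------------------------------------------------
# Study-condition constants
# ---------------------------------------------------------------------------

N_STRAND_GENES = frozenset({
    "trnQ", "trnC", "trnY", "trnF", "nad5", "trnH", "nad4", "nad4l",
    "trnP", "nad1", "trnL1", "rrnL", "trnV", "rrnS",
})

ANTICODONS = {
    "trnM": "CAT", "trnI": "GAT", "trnQ": "TTG", "trnW": "TCA", "trnC": "GCA",
    "trnY": "GTA", "trnL2": "TAA", "trnK": "CTT", "trnD": "GTC", "trnG": "TCC",
    "trnA": "TGC", "trnR": "TCG", "trnN": "GTT", "trnS1": "GCT", "trnE": "TTC",
    "trnF": "GAA", "trnH": "GTG", "trnT": "TGT", "trnP": "TGG", "trnS2": "TGA",
    "trnL1": "TAG", "trnV": "TAC",
}

_START_CODONS = {
    "nad2": "ATT", "cox1": "CGA", "cox2": "ATT", "atp8": "ATT", "atp6": "ATG",
    "cox3": "ATG", "nad3": "ATT", "nad5": "ATA", "nad4": "ATG", "nad4l": "ATG",
    "nad6": "ATT", "cob": "ATA", "nad1": "ATA",
}
_INCOMPLETE_T = frozenset({"nad2", "cox1", "cox2", "nad4"})

#: Reading-direction PCG lengths (bp); nad5 is the flex gene sized at build
#: time so the genome totals exactly the target length.
_PCG_LENGTHS = {
    "nad2": 1021, "cox1": 1531, "cox2": 682, "atp8": 168, "atp6": 678,
    "cox3": 789, "nad3": 354, "nad4": 1339, "nad4l": 297, "nad6": 531,
    "cob": 1149, "nad1": 942,
}
_RRNA_LENGTHS = {"rrnL": 1350, "rrnS": 779}

#: Codons never emitted by the sampler: the two in-frame stops plus the three
#: codons absent from the modelled genome's coding sequences.
_EXCLUDED_CODONS = frozenset({"TAA", "TAG", "CTG", "CCG", "AGG"})

#: Overlap junctions (gene A, gene B, bp); 8 regions, 35 bp total.
_DEFAULT_OVERLAPS: tuple[tuple[str, str, int], ...] = (
    ("trnW", "trnC", 8),
    ("atp8", "atp6", 7),
    ("trnK", "trnD", 5),
    ("trnA", "trnR", 5),
    ("trnN", "trnS1", 4),
    ("trnT", "trnP", 3),
    ("trnY", "cox1", 2),
    ("trnH", "nad4", 1),
)

#: tRNAs whose acceptor stem gets re-complemented against an overlap; their
#: mismatch plan must avoid the acceptor arm.
_PATCHED_TRNAS = frozenset({"trnW", "trnK", "trnA", "trnN", "trnT", "trnH", "trnY"})

#: Default planted non-WC stem pairs: 43 total, 24 G-U, arms 20/8/9/6
#: (DHU/acceptor/TpsiC/anticodon), spread over 20 of the 22 genes.
DEFAULT_MISMATCH_PLAN: dict[str, tuple[tuple[str, str], ...]] = {
    "trnM": (("DHU", "G-U"),),
    "trnQ": (("DHU", "G-U"), ("acceptor", "A-G")),
    "trnW": (("DHU", "G-U"), ("TpsiC", "G-U")),
    "trnC": (("DHU", "G-U"), ("acceptor", "A-A")),
    "trnY": (("DHU", "G-U"), ("TpsiC", "U-U")),
    "trnL2": (("DHU", "G-U"), ("DHU", "A-G"), ("acceptor", "G-U")),
    "trnK": (("DHU", "G-U"), ("anticodon", "U-U")),
    "trnD": (("DHU", "G-U"), ("acceptor", "C-U")),
    "trnG": (("DHU", "G-U"), ("TpsiC", "C-U")),
    "trnA": (("DHU", "A-C"), ("anticodon", "G-U")),
    "trnR": (("DHU", "G-U"), ("acceptor", "A-C")),
    "trnN": (("DHU", "G-G"), ("TpsiC", "G-U")),
    "trnS1": (("acceptor", "G-U"), ("anticodon", "A-A")),
    "trnE": (("DHU", "G-U"), ("acceptor", "G-G")),
    "trnF": (("DHU", "U-U"), ("TpsiC", "A-C")),
    "trnH": (("DHU", "G-U"), ("TpsiC", "G-U"), ("anticodon", "G-U")),
    "trnT": (("DHU", "A-A"), ("TpsiC", "G-U")),
    "trnP": (("DHU", "G-U"), ("acceptor", "U-U"), ("anticodon", "C-U")),
    "trnL1": (("DHU", "G-U"), ("TpsiC", "A-C")),
    "trnV": (("DHU", "A-G"), ("TpsiC", "G-U"), ("anticodon", "G-U")),
}


def _default_spacers() -> dict[tuple[str, str], dict]:
    """Planted spacer plan keyed by (left gene, right gene)."""
    return {
        ("trnQ", "nad2"): {"kind": "major", "length": 61, "gc": 2},  # 59/61 = 96.72% A+T
        ("trnE", "trnF"): {"kind": "microsat"},   # (TA)18 'G' (TTAT)3 -> 49 bp
        ("trnS2", "nad1"): {"kind": "motif"},     # 16 bp with ATACTAT
        ("nad1", "trnL1"): {"kind": "fixed", "sequence": "TATTAATTAA"},
        # small spacers emulating the remaining short non-coding stretches
        ("trnM", "trnI"): {"kind": "tiny", "length": 1},
        ("trnI", "trnQ"): {"kind": "tiny", "length": 3},
        ("nad2", "trnW"): {"kind": "tiny", "length": 2},
        ("cox1", "trnL2"): {"kind": "tiny", "length": 1},
        ("cox2", "trnK"): {"kind": "tiny", "length": 1},
        ("atp6", "cox3"): {"kind": "tiny", "length": 1},
        ("cox3", "trnG"): {"kind": "tiny", "length": 2},
        ("nad3", "trnA"): {"kind": "tiny", "length": 2},
        ("nad4l", "trnT"): {"kind": "tiny", "length": 2},
        ("cob", "trnS2"): {"kind": "tiny", "length": 2},
        ("nad6", "cob"): {"kind": "shim", "length": 1},  # absorbs the 0-2 bp residue
    }


@dataclass
class GenomeSpec:
    """Recipe for one synthetic mitogenome.  Defaults are the study conditions."""

    target_length: int = 15273
    at_pcg: float = 0.7896
    at_rrnl: float = 0.8295
    at_rrns: float = 0.8586
    at_trna: float = 0.80
    control_length: int = 351
    control_gc: int = 12            # 339/351 = 96.58% A+T
    gene_order: tuple[str, ...] = CANONICAL_GENE_ORDER
    spacers: dict = field(default_factory=_default_spacers)
    overlaps: tuple[tuple[str, str, int], ...] = _DEFAULT_OVERLAPS
    mismatch_plan: dict = field(default_factory=lambda: dict(DEFAULT_MISMATCH_PLAN))
    seed: int = 0
    verify_trna: bool = True        # re-fold each tRNA to certify unambiguous truth

    @classmethod
    def uniform(cls, at: float, seed: int = 0, **kw) -> "GenomeSpec":
        """All stochastic partitions drawn at one A+T fraction (for recovery tests)."""
        return cls(at_pcg=at, at_rrnl=at, at_rrns=at, at_trna=at, seed=seed, **kw)


@dataclass
class TruthTable:
    """Exhaustive record of everything planted in one synthetic genome."""

    features: dict[str, tuple[int, int, str, str]] = field(default_factory=dict)
    spacers: dict[tuple[str, str], tuple[int, str]] = field(default_factory=dict)
    overlaps: dict[tuple[str, str], tuple[int, str]] = field(default_factory=dict)
    repeats: list[dict] = field(default_factory=list)
    tracts: list[dict] = field(default_factory=list)
    motifs: list[dict] = field(default_factory=list)
    trna: dict[str, dict] = field(default_factory=dict)
    start_codons: dict[str, str] = field(default_factory=dict)
    stop_classes: dict[str, str] = field(default_factory=dict)

    @property
    def planted_mismatch_total(self) -> int:
        return sum(len(t["planted"]) for t in self.trna.values())

    @property
    def planted_gu_total(self) -> int:
        return sum(1 for t in self.trna.values() for (_, c) in t["planted"] if c == "G-U")


# ---------------------------------------------------------------------------
# Base/codon sampling
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _sample_bases(rng: np.random.Generator, n: int, at: float) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(_BASES, size=n, p=p)) if n else ""


def _sample_codon(rng: np.random.Generator, at: float,
                  first_base: Optional[str] = None) -> str:
    while True:
        c = _sample_bases(rng, 3, at)
        if first_base:
            c = first_base + c[1:]
        if c not in _EXCLUDED_CODONS:
            return c


def _sample_codons(rng: np.random.Generator, n: int, at: float) -> list[str]:
    """n codons from the AT-biased sampler, excluded codons rejected (bulk draws)."""
    out: list[str] = []
    while len(out) < n:
        block = _sample_bases(rng, 3 * (n - len(out) + 8), at)
        for i in range(0, len(block) - 2, 3):
            c = block[i : i + 3]
            if c not in _EXCLUDED_CODONS:
                out.append(c)
                if len(out) == n:
                    break
    return out


# ---------------------------------------------------------------------------
# tRNA construction
# ---------------------------------------------------------------------------

_WC_PARTNER = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _draw_layout(rng: np.random.Generator, dhu_less: bool):
    if dhu_less:
        while True:
            repl = int(rng.integers(6, 10))
            var = int(rng.integers(3, 6))
            tlen = int(rng.integers(4, 6))
            tloop = int(rng.integers(4, 9))
            L = 32 + repl + var + 2 * tlen + tloop
            if 59 <= L <= 70:
                return ("dhu_less", repl, var, tlen, tloop, 1), L
    while True:
        s1 = int(rng.integers(1, 3))
        dlen = int(rng.integers(3, 5))
        dloop = int(rng.integers(4, 10))
        var = int(rng.integers(3, 6))
        tlen = int(rng.integers(4, 6))
        tloop = int(rng.integers(4, 9))
        L = 33 + s1 + 2 * dlen + dloop + var + 2 * tlen + tloop
        if 64 <= L <= 73:
            return ("cloverleaf", s1, dlen, dloop, 1, var, tlen, tloop, 1), L


_MISMATCH_BASES = {
    "G-U": (("G", "T"), ("T", "G")),
    "A-A": (("A", "A"),),
    "U-U": (("T", "T"),),
    "G-G": (("G", "G"),),
    "A-C": (("A", "C"), ("C", "A")),
    "A-G": (("A", "G"), ("G", "A")),
    "C-U": (("C", "T"), ("T", "C")),
}


def _build_trna_once(rng, name, anticodon, planted, at, forced_head, forced_tail):
    dhu_less = name == "trnS1"
    layout, L = _draw_layout(rng, dhu_less)
    if dhu_less:
        segs, total = _segments_dhu_less(*layout[1:], _CONS)
    else:
        segs, total = _segments_cloverleaf(*layout[1:], _CONS)
    assert total == L
    chars = [""] * L
    # unpaired regions
    for seg_name, (s, e) in segs.items():
        if seg_name.endswith("5") or seg_name.endswith("3"):
            continue
        for i in range(s, e):
            chars[i] = _sample_bases(rng, 1, at)
    # anticodon at the loop center
    ls, _ = segs["anticodonloop"]
    for k, b in enumerate(anticodon):
        chars[ls + 2 + k] = b
    # stems: 5' base sampled, 3' partner complementary
    stem_pairs = []
    for arm in ("acceptor", "DHU", "anticodon", "TpsiC"):
        five = segs.get(arm + "5")
        three = segs.get(arm + "3")
        if not five:
            continue
        ln = five[1] - five[0]
        for i in range(ln):
            stem_pairs.append((arm, five[0] + i, three[1] - 1 - i))
    for _, i, j in stem_pairs:
        b = _sample_bases(rng, 1, at)
        chars[i] = b
        chars[j] = _WC_PARTNER[b]
    # planted non-WC pairs: distinct positions per arm
    used: set[int] = set()
    for arm, label in planted:
        arm_pairs = [(i, j) for (a, i, j) in stem_pairs if a == arm and i not in used]
        if not arm_pairs:
            raise ValueError(f"{name}: no free {arm} stem position for planted pair")
        i, j = arm_pairs[int(rng.integers(0, len(arm_pairs)))]
        used.add(i)
        options = _MISMATCH_BASES[label]
        bi, bj = options[int(rng.integers(0, len(options)))]
        chars[i], chars[j] = bi, bj
    # forced genome-junction constraints touch the acceptor arm + discriminator
    if forced_tail:
        k = len(forced_tail)
        for off, b in enumerate(forced_tail):
            chars[L - k + off] = b
    if forced_head:
        for off, b in enumerate(forced_head):
            chars[off] = b
    if forced_head or forced_tail:
        acc5 = segs["acceptor5"]
        acc3 = segs["acceptor3"]
        n_forced_head = len(forced_head or "")
        n_forced_tail = len(forced_tail or "")
        for i in range(7):
            p5 = acc5[0] + i
            p3 = acc3[1] - 1 - i
            if p3 >= L - n_forced_tail and n_forced_tail:
                chars[p5] = _WC_PARTNER[chars[p3]]
            if p5 < n_forced_head and n_forced_head:
                chars[p3] = _WC_PARTNER[chars[p5]]
    seq = "".join(chars)
    score, wc, pairs = _score_segments(seq, segs)
    fold = TrnaFold(seq, "DHU_less" if dhu_less else "cloverleaf", segs, pairs,
                    anticodon, score, wc)
    return seq, fold


#: Replacement base guaranteed not to pair (WC or GU) with the key base.
_ANTI_PAIR = {"A": "A", "T": "T", "G": "A", "C": "T"}


def _build_trna(rng, name, anticodon, planted, at, forced_head=None, forced_tail=None,
                verify=True, max_tries=40, max_repairs=60):
    """Emit one tRNA gene whose planted fold is provably what the folder recovers.

    When planted true mismatches lower the truth score, rival boundary
    assignments over the AT-rich loops can tie or beat it; rather than
    redrawing blindly, the builder breaks each winning rival by mutating one
    free (non-stem, non-anticodon, non-forced) base its pairing relies on,
    which leaves the planted structure untouched.  Full redraws remain the
    fallback when a rival uses only protected positions.
    """
    dhu_less = name == "trnS1"
    for _ in range(max_tries):
        seq, fold = _build_trna_once(rng, name, anticodon, planted, at,
                                     forced_head, forced_tail)
        if not verify:
            return seq, fold
        chars = list(seq)
        L = len(chars)
        protected = {i for (i, j, _) in fold.pairs} | {j for (i, j, _) in fold.pairs}
        ac_start, _ = fold.segments["anticodonloop"]
        protected |= {ac_start + 2, ac_start + 3, ac_start + 4}
        if forced_head:
            protected |= set(range(len(forced_head)))
        if forced_tail:
            protected |= set(range(L - len(forced_tail), L))
        for _repair in range(max_repairs):
            cur = "".join(chars)
            got = fold_cloverleaf(cur, expected_anticodon=anticodon,
                                  allow_dhu_less=dhu_less)
            if got.topology == fold.topology and got.segments == fold.segments \
                    and got.pairs == fold.pairs:
                if cur == seq:
                    return seq, fold
                score, wc, pairs = _score_segments(cur, fold.segments)
                assert pairs == fold.pairs  # repairs never touch stem positions
                return cur, TrnaFold(cur, fold.topology, fold.segments, pairs,
                                     anticodon, score, wc)
            target = None
            for (i, j, cls) in got.pairs:
                if cls == "mismatch":
                    continue
                if i not in protected:
                    target = (i, j)
                    break
                if j not in protected:
                    target = (j, i)
                    break
            if target is None:
                break  # rival built entirely from protected bases: redraw
            i, j = target
            chars[i] = _ANTI_PAIR[chars[j]]
    raise RuntimeError(f"could not build an unambiguous {name} in {max_tries} draws")


def generate_trna(template_id: str, n_planted: int | Sequence[tuple[str, str]] = 0,
                  seed: int = 0, at: float = 0.80):
    """Standalone tRNA emitter: (sequence, planted fold) for one template.

    ``n_planted`` may be an explicit list of (arm, class) pairs or an integer
    n <= 5, in which case a default plan of alternating G-U and true
    mismatches over the available arms is used.
    """
    if template_id not in ANTICODONS:
        raise KeyError(f"unknown tRNA template {template_id!r}")
    if isinstance(n_planted, int):
        if n_planted > 5:
            raise ValueError("at most 5 planted pairs")
        arms = ("acceptor", "TpsiC", "anticodon") if template_id == "trnS1" else \
               ("DHU", "acceptor", "TpsiC", "anticodon")
        classes = ("G-U", "A-A", "G-U", "C-U", "G-U")
        planted = tuple((arms[i % len(arms)], classes[i]) for i in range(n_planted))
    else:
        planted = tuple(n_planted)
    rng = np.random.default_rng(seed)
    return _build_trna(rng, template_id, ANTICODONS[template_id], planted, at)


# ---------------------------------------------------------------------------
# PCG / rRNA construction
# ---------------------------------------------------------------------------


def _build_pcg(rng, name, length, at):
    start = _START_CODONS[name]
    incomplete = name in _INCOMPLETE_T
    if incomplete:
        if length % 3 != 1:
            raise ValueError(f"{name}: incomplete-T gene length must be 1 mod 3")
        n_mid = (length - 1) // 3 - 1
        tail = "T"
    else:
        if length % 3 != 0:
            raise ValueError(f"{name}: complete-stop gene length must be 0 mod 3")
        n_mid = length // 3 - 2
        tail = "TAA"
    if n_mid < 1:
        raise ValueError(f"{name}: length {length} too short")
    if name == "atp6":
        # head ATG-ATA-A.. so that atp8's tail can share the ATGATAA overlap
        mids = ["ATA", _sample_codon(rng, at, first_base="A")]
        mids += _sample_codons(rng, n_mid - 2, at)
    elif name == "atp8":
        # tail ..A-TGA-TAA: the last 7 bases read ATGATAA
        mids = _sample_codons(rng, n_mid - 2, at)
        c = _sample_codon(rng, at)
        while c[2] != "A":
            c = _sample_codon(rng, at)
        mids += [c, "TGA"]
    else:
        mids = _sample_codons(rng, n_mid, at)
    seq = start + "".join(mids) + tail
    assert len(seq) == length
    assert classify_start_codon(seq)[0] in ("ATN", "CGA")
    assert classify_stop_codon(seq) == ("incomplete_T" if incomplete else "complete_TAA")
    return seq


def _build_control(rng, length, gc_budget):
    """Control region: ATAGA + 20T + (TA)9 + (TA)8 + 10A with AT-rich filler.

    Exactly ``gc_budget`` G/C bases overall (5 guards + 1 in ATAGA + the rest
    planted in the filler), guards placed so every planted repeat/tract is
    maximal.  Returns (sequence, local truth elements).
    """
    blocks_fixed = 5 + 20 + 1 + 1 + 18 + 1 + 1 + 16 + 1 + 10
    filler_total = length - blocks_fixed
    if filler_total < 12:
        raise ValueError("control region too short for its planted signature")
    f1 = filler_total // 3
    f2 = filler_total // 3
    f3 = filler_total - f1 - f2
    free_gc = gc_budget - 6
    if free_gc < 0:
        raise ValueError("control gc budget below the 6 fixed guard bases")

    def filler(n, n_gc, forbid_last_a=False):
        s = list("".join(rng.choice(np.array(list("AT")), size=n)))
        pos = rng.choice(np.arange(1, n - 1), size=n_gc, replace=False) if n_gc else []
        for p in pos:
            s[int(p)] = str(rng.choice(np.array(list("CG"))))
        if forbid_last_a:
            s[-1] = "T"
        return "".join(s)

    per = [free_gc // 3] * 3
    per[2] += free_gc - sum(per)
    parts = ["ATAGA", "T" * 20, "C", filler(f1, per[0]), "G", "TA" * 9, "C",
             filler(f2, per[1]), "G", "TA" * 8, "C", filler(f3, per[2], True),
             "A" * 10]
    seq = "".join(parts)
    assert len(seq) == length
    off = [0]
    starts = []
    for p in parts:
        starts.append(off[0])
        off[0] += len(p)
    truth = {
        "motifs": [{"motif": "ATAGA", "position": starts[0]}],
        "tracts": [{"base": "T", "start": starts[1], "end": starts[1] + 20},
                   {"base": "A", "start": starts[12], "end": starts[12] + 10}],
        "repeats": [{"canonical_unit": "AT", "copies": 9.0,
                     "start": starts[5], "end": starts[5] + 18},
                    {"canonical_unit": "AT", "copies": 8.0,
                     "start": starts[9], "end": starts[9] + 16}],
    }
    return seq, truth


def _build_spacer(rng, plan, shim_extra=0):
    kind = plan["kind"]
    if kind == "major":
        n, gc = plan["length"], plan["gc"]
        s = list("".join(rng.choice(np.array(list("AT")), size=n)))
        for p in rng.choice(np.arange(1, n - 1), size=gc, replace=False):
            s[int(p)] = str(rng.choice(np.array(list("CG"))))
        return "".join(s), {}
    if kind == "microsat":
        seq = "TA" * 18 + "G" + "TTAT" * 3
        truth = {"repeats": [{"canonical_unit": "AT", "copies": 18.0, "start": 0, "end": 36},
                             {"canonical_unit": "ATTT", "copies": 3.0, "start": 37, "end": 49}]}
        return seq, truth
    if kind == "motif":
        seq = "TAAT" + "ATACTAT" + "TATTA"
        return seq, {"motifs": [{"motif": "ATACTAT", "position": 4}]}
    if kind == "fixed":
        return plan["sequence"], {}
    n = plan["length"] + (shim_extra if kind == "shim" else 0)
    return "".join(rng.choice(np.array(list("AT")), size=n)), {}


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------


def _kind_of(name: str) -> str:
    if name == "AT_rich":
        return "control"
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    return "PCG"


def generate_mitogenome(spec: GenomeSpec) -> tuple[AnnotatedMitogenome, TruthTable]:
    """Build one synthetic genome + truth table, deterministically from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    order = list(spec.gene_order)
    overlaps = {(a, b): k for a, b, k in spec.overlaps}
    for (a, b) in overlaps:
        ia, ib = order.index(a), order.index(b)
        if ib != ia + 1:
            raise ValueError(f"overlap {a}/{b}: genes not adjacent in the order")

    control_seq, control_truth = _build_control(rng, spec.control_length, spec.control_gc)

    microsat_spacer = spec.spacers.get(("trnE", "trnF"), {}).get("kind") == "microsat"

    # --- reading-direction gene sequences -------------------------------
    reading: dict[str, str] = {}
    trna_truth: dict[str, dict] = {}
    for name in order:
        if name == "AT_rich" or name == "nad5":
            continue
        if name in _PCG_LENGTHS:
            reading[name] = _build_pcg(rng, name, _PCG_LENGTHS[name], spec.at_pcg)
        elif name in _RRNA_LENGTHS:
            at = spec.at_rrnl if name == "rrnL" else spec.at_rrns
            reading[name] = _sample_bases(rng, _RRNA_LENGTHS[name], at)
        elif name in ANTICODONS and name not in _PATCHED_TRNAS:
            planted = tuple(spec.mismatch_plan.get(name, ()))
            forced_head = "G" if name == "trnM" else None  # guards the poly-A tract
            # the discriminators flanking the microsatellite spacer must not
            # extend the planted (TA)18 / (TTAT)3 arrays
            forced_tail = "C" if (microsat_spacer and name in ("trnE", "trnF")) else None
            seq, fold = _build_trna(rng, name, ANTICODONS[name], planted, spec.at_trna,
                                    forced_head=forced_head, forced_tail=forced_tail,
                                    verify=spec.verify_trna)
            reading[name] = seq
            trna_truth[name] = {"fold": fold, "planted": planted,
                                "anticodon": ANTICODONS[name]}
    # A-role (patched) tRNAs need their junction partner's final bases
    for name in (g for g in order if g in _PATCHED_TRNAS):
        b_name, k = next(((b, k) for (a, b), k in overlaps.items() if a == name))
        b_read = reading[b_name]
        b_genome_head = (b_read[:k] if b_name not in N_STRAND_GENES
                         else revcomp(b_read)[:k])
        planted = tuple(spec.mismatch_plan.get(name, ()))
        if any(arm == "acceptor" for arm, _ in planted):
            raise ValueError(f"{name}: acceptor mismatches collide with its overlap patch")
        if name in N_STRAND_GENES:
            # genome tail of an N gene is its reading head
            seq, fold = _build_trna(rng, name, ANTICODONS[name], planted, spec.at_trna,
                                    forced_head=revcomp(b_genome_head),
                                    verify=spec.verify_trna)
        else:
            seq, fold = _build_trna(rng, name, ANTICODONS[name], planted, spec.at_trna,
                                    forced_tail=b_genome_head, verify=spec.verify_trna)
        reading[name] = seq
        trna_truth[name] = {"fold": fold, "planted": planted,
                            "anticodon": ANTICODONS[name]}

    # --- size the flex gene and the shim spacer -------------------------
    spacer_plans = dict(spec.spacers)
    fixed_spacer_bp = 0
    for (lft, rgt), plan in spacer_plans.items():
        if plan["kind"] == "major":
            fixed_spacer_bp += plan["length"]
        elif plan["kind"] == "microsat":
            fixed_spacer_bp += 49
        elif plan["kind"] == "motif":
            fixed_spacer_bp += 16
        elif plan["kind"] == "fixed":
            fixed_spacer_bp += len(plan["sequence"])
        else:
            fixed_spacer_bp += plan["length"]
    gene_bp_known = sum(len(s) for s in reading.values())
    overlap_bp = sum(overlaps.values())
    residual = (spec.target_length - spec.control_length - gene_bp_known
                - fixed_spacer_bp + overlap_bp)
    nad5_len = residual - (residual % 3)
    shim_extra = residual - nad5_len
    if nad5_len < 300:
        raise ValueError(f"infeasible spec: flex gene would be {nad5_len} bp; "
                         "planted elements exceed the target length")
    reading["nad5"] = _build_pcg(rng, "nad5", nad5_len, spec.at_pcg)

    # --- assemble the circle --------------------------------------------
    buf: list[str] = []
    truth = TruthTable()
    cursor = 0

    def emit(s: str):
        nonlocal cursor
        buf.append(s)
        cursor += len(s)

    def add_local_truth(local: dict, offset: int):
        for r in local.get("repeats", []):
            truth.repeats.append({**r, "start": r["start"] + offset,
                                  "end": r["end"] + offset})
        for t in local.get("tracts", []):
            truth.tracts.append({**t, "start": t["start"] + offset,
                                 "end": t["end"] + offset})
        for m in local.get("motifs", []):
            truth.motifs.append({**m, "position": m["position"] + offset})

    prev = None
    for name in order:
        if prev is not None:
            key = (prev, name)
            if key in overlaps:
                k = overlaps[key]
                seg = reading[name] if name not in N_STRAND_GENES else revcomp(reading[name])
                tail = "".join(buf)[-k:]
                if tail != seg[:k]:
                    raise AssertionError(f"overlap {key} bases disagree: {tail} vs {seg[:k]}")
                start = cursor - k
                truth.overlaps[key] = (start, seg[:k])
                # replace: drop the duplicated tail, emit full segment from start
                whole = "".join(buf)[: start]
                buf.clear()
                buf.append(whole)
                cursor = start
                truth.features[name] = (cursor, cursor + len(seg),
                                        "N" if name in N_STRAND_GENES else "J",
                                        _kind_of(name))
                emit(seg)
                prev = name
                continue
            if key in spacer_plans:
                sp_seq, local = _build_spacer(rng, spacer_plans[key],
                                              shim_extra=shim_extra)
                truth.spacers[key] = (cursor, sp_seq)
                add_local_truth(local, cursor)
                emit(sp_seq)
        if name == "AT_rich":
            truth.features[name] = (cursor, cursor + len(control_seq), "J", "control")
            add_local_truth(control_truth, cursor)
            emit(control_seq)
        else:
            seg = reading[name] if name not in N_STRAND_GENES else revcomp(reading[name])
            truth.features[name] = (cursor, cursor + len(seg),
                                    "N" if name in N_STRAND_GENES else "J",
                                    _kind_of(name))
            emit(seg)
        prev = name

    sequence = "".join(buf)
    if len(sequence) != spec.target_length:
        raise AssertionError(f"assembled {len(sequence)} bp, expected {spec.target_length}")

    for name in order:
        if name in _START_CODONS:
            truth.start_codons[name] = _START_CODONS[name]
            truth.stop_classes[name] = ("incomplete_T" if name in _INCOMPLETE_T
                                        else "complete_TAA")
    truth.trna = trna_truth

    features = [GeneFeature(n, k, s, e, st)
                for n, (s, e, st, k) in truth.features.items()]
    genome = AnnotatedMitogenome(f"SYNMITO_{spec.seed}", sequence, features, "circular")
    return genome, truth
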