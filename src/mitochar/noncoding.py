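"""Non-coding sequence analysis on the mitochondrial circle.

Catalogues intergenic spacers and gene overlaps implied by the feature table
(including the origin-spanning junction), finds maximal tandem repeats
(microsatellites), homopolymer tracts and conserved motifs, and measures
sequence identity by global alignment -- used e.g. to test whether a spacer
originated as a partial duplication of a neighbouring gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .composition import base_composition
from .io import AnnotatedMitogenome, GeneFeature, extract_feature_sequence, revcomp

__all__ = [
    "Spacer", "SpacerCatalog", "Overlap", "OverlapCatalog",
    "RepeatHit", "MotifHit", "PolyTract", "AlignmentResult",
    "catalog_spacers_overlaps", "find_tandem_repeats", "find_poly_tracts",
    "find_motif", "global_identity", "spacer_origin_scan",
    "circle_accounting", "control_region",
    "DEFAULT_MIN_COPIES",
]


# ---------------------------------------------------------------------------
# Spacers and overlaps
# ---------------------------------------------------------------------------


@dataclass
class Spacer:
    left: str   # flanking gene before the gap (circle order)
    right: str  # flanking gene after the gap
    start: int
    end: int    # may exceed genome length for the origin-spanning junction
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def at_percent(self) -> float | None:
        return base_composition(self.sequence).at_percent


@dataclass
class SpacerCatalog:
    entries: list[Spacer] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return len(self.entries)

    @property
    def total_bp(self) -> int:
        return sum(s.length for s in self.entries)

    def between(self, left: str, right: str) -> Spacer | None:
        for s in self.entries:
            if s.left == left and s.right == right:
                return s
        return None


@dataclass
class Overlap:
    a: str
    b: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OverlapCatalog:
    entries: list[Overlap] = field(default_factory=list)
    containments: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return len(self.entries)

    @property
    def total_bp(self) -> int:
        return sum(o.length for o in self.entries)

    def between(self, a: str, b: str) -> Overlap | None:
        for o in self.entries:
            if o.a == a and o.b == b:
                return o
        return None


def _slice_circular(seq: str, start: int, end: int) -> str:
    n = len(seq)
    start %= n
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]


def catalog_spacers_overlaps(genome: AnnotatedMitogenome) -> tuple[SpacerCatalog, OverlapCatalog]:
    """All intergenic spacers and overlaps between circularly adjacent features.

    Features are sorted by start; for each adjacent pair a positive gap is a
    spacer, a negative gap an overlap, zero neither.  The junction across the
    origin is handled identically.  A feature wholly contained in another is
    recorded as a containment, excluded from both catalogues, and warned
    about.
    """
    if len(genome.features) < 2:
        raise ValueError("need at least two features to form junctions")
    n = genome.length
    feats = sorted(genome.features, key=lambda f: (f.start, -f.end))
    spacers = SpacerCatalog()
    overlaps = OverlapCatalog()

    # sweep with a frontier to detect containments
    kept: list[GeneFeature] = []
    frontier_end = -1
    frontier_name = ""
    for f in feats:
        if f.end <= frontier_end:
            overlaps.containments.append((f.name, frontier_name))
            warnings.warn(f"feature {f.name} contained in {frontier_name}; "
                          "excluded from spacer/overlap catalogues", stacklevel=2)
            continue
        kept.append(f)
        frontier_end, frontier_name = f.end, f.name
    for idx, cur in enumerate(kept):
        nxt = kept[(idx + 1) % len(kept)]
        if idx + 1 < len(kept):
            gap = nxt.start - cur.end
            s, e = cur.end, nxt.start
        else:  # origin-spanning junction
            gap = nxt.start + n - cur.end
            s, e = cur.end, nxt.start + n
        if gap > 0:
            spacers.entries.append(Spacer(cur.name, nxt.name, s % n, (s % n) + gap,
                                          _slice_circular(genome.sequence, s, e)))
        elif gap < 0:
            o_start = nxt.start
            overlaps.entries.append(Overlap(cur.name, nxt.name, o_start, o_start - gap,
                                            _slice_circular(genome.sequence, o_start,
                                                            o_start - gap)))
    return spacers, overlaps


def circle_accounting(genome: AnnotatedMitogenome) -> dict[str, int]:
    """Identity check: sum(feature lengths) - overlap bp + spacer bp == genome length."""
    spacers, overlaps = catalog_spacers_overlaps(genome)
    gene_bp = sum(f.length for f in genome.features
                  if f.name not in {c[0] for c in overlaps.containments})
    lhs = gene_bp - overlaps.total_bp + spacers.total_bp
    return {"gene_bp": gene_bp, "overlap_bp": overlaps.total_bp,
            "spacer_bp": spacers.total_bp, "lhs": lhs, "genome_length": genome.length,
            "residual": lhs - genome.length}


def control_region(genome: AnnotatedMitogenome) -> tuple[str, str]:
    """(label, sequence) of the control region.

    The annotated A+T-rich feature when present; otherwise the largest
    unannotated gap on the circle is taken as the control region.
    """
    ctrl = genome.features_of_kind("control")
    if ctrl:
        return ctrl[0].name, extract_feature_sequence(genome, ctrl[0])
    spacers, _ = catalog_spacers_overlaps(genome)
    if not spacers.entries:
        raise ValueError("no control feature and no spacer to fall back on")
    best = max(spacers.entries, key=lambda s: s.length)
    return f"largest_gap({best.left}-{best.right})", best.sequence


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

#: Minimum copy numbers by repeat-unit length (microsatellite conventions).
DEFAULT_MIN_COPIES = {1: 8, 2: 5, 3: 3, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class RepeatHit:
    unit: str
    canonical_unit: str  # lexicographically least rotation of the unit
    copies: float        # fractional trailing copy allowed
    start: int
    end: int

    @property
    def copies_floor(self) -> int:
        return int(self.copies)


def _least_rotation(s: str) -> str:
    return min(s[i:] + s[:i] for i in range(len(s)))


def _is_primitive(unit: str) -> bool:
    u = len(unit)
    for d in range(1, u):
        if u % d == 0 and unit == unit[:d] * (u // d):
            return False
    return True


def find_tandem_repeats(seq: str, max_unit: int = 6,
                        min_copies: dict[int, int] | None = None) -> list[RepeatHit]:
    """All maximal exact tandem arrays with unit length 1..max_unit.

    A hit's region [start, end) cannot be extended a base in either direction
    while keeping period ``len(unit)``; fractional trailing copies are kept
    in the coordinates.  Only primitive units are reported (a (TATA)n array
    surfaces once as (TA)2n), and equal regions found under rotated phases
    are reported once under the canonical (least-rotation) unit.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    s = seq.upper()
    n = len(s)
    thresholds = dict(DEFAULT_MIN_COPIES)
    if min_copies:
        thresholds.update(min_copies)
    hits: dict[tuple[int, int], RepeatHit] = {}
    for u in range(1, min(max_unit, n) + 1):
        k = u
        while k < n:
            if s[k] != s[k - u]:
                k += 1
                continue
            run_start = k
            while k < n and s[k] == s[k - u]:
                k += 1
            region_start = run_start - u
            region_end = k
            unit = s[region_start : region_start + u]
            if not _is_primitive(unit):
                continue
            copies = (region_end - region_start) / u
            if copies < thresholds.get(u, 3):
                continue
            key = (region_start, region_end)
            if key not in hits:  # smaller unit wins for an identical region
                hits[key] = RepeatHit(unit, _least_rotation(unit), copies,
                                      region_start, region_end)
    return sorted(hits.values(), key=lambda h: (h.start, h.end, len(h.unit)))


# ---------------------------------------------------------------------------
# Homopolymer tracts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolyTract:
    base: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def find_poly_tracts(seq: str, base: str, min_length: int = 5) -> list[PolyTract]:
    """Maximal runs of one base with length >= min_length (min_length >= 5)."""
    if min_length < 5:
        raise ValueError("min_length must be at least 5")
    base = base.upper()
    if base not in "ACGT":
        raise ValueError("base must be one of A, C, G, T")
    s = seq.upper()
    hits = []
    i = 0
    n = len(s)
    while i < n:
        if s[i] != base:
            i += 1
            continue
        j = i
        while j < n and s[j] == base:
            j += 1
        if j - i >= min_length:
            hits.append(PolyTract(base, i, j))
        i = j
    return hits


# ---------------------------------------------------------------------------
# Motif search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifHit:
    motif: str
    position: int
    mismatches: int
    strand: str = "J"


def find_motif(seq: str, motif: str, max_mismatches: int = 0,
               both_strands: bool = False) -> list[MotifHit]:
    """All positions where the motif matches within a Hamming-distance budget."""
    if len(motif) < 3:
        raise ValueError("motif must be at least 3 nt")
    s = seq.upper()
    m = motif.upper()
    hits = []
    for strand, query in (("J", m),) + ((("N", revcomp(m)),) if both_strands else ()):
        for i in range(len(s) - len(query) + 1):
            d = sum(1 for a, b in zip(s[i : i + len(query)], query) if a != b)
            if d <= max_mismatches:
                hits.append(MotifHit(m, i, d, strand))
    return sorted(hits, key=lambda h: (h.position, h.strand))


# ---------------------------------------------------------------------------
# Global alignment identity
# ---------------------------------------------------------------------------


@dataclass
class AlignmentResult:
    identity: float      # matches / alignment columns * 100
    columns: int
    matches: int
    score: int
    aligned_a: str
    aligned_b: str


#: Alignment scoring: match +1, mismatch -1, linear gap -2.  The scheme is a
#: configurable; these defaults are used for all identity figures.
MATCH, MISMATCH, GAP = 1, -1, -2


def global_identity(a: str, b: str, match: int = MATCH, mismatch: int = MISMATCH,
                    gap: int = GAP) -> AlignmentResult:
    """Needleman-Wunsch global alignment with a deterministic traceback.

    Traceback ties prefer the diagonal move, then up (gap in ``b``, consuming
    a base of ``a``), then left (gap in ``a``).
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    # DP over python lists; sequences here are spacer/gene scale (<= a few kb)
    prev = [j * gap for j in range(m + 1)]
    rows = [prev]
    for i in range(1, n + 1):
        cur = [i * gap] + [0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = prev[j] + gap
            left = cur[j - 1] + gap
            cur[j] = diag if diag >= up and diag >= left else (up if up >= left else left)
        rows.append(cur)
        prev = cur
    # traceback
    i, j = n, m
    out_a: list[str] = []
    out_b: list[str] = []
    matches = 0
    while i > 0 or j > 0:
        here = rows[i][j]
        if i > 0 and j > 0 and \
                here == rows[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            matches += a[i - 1] == b[j - 1]
            i -= 1
            j -= 1
        elif i > 0 and here == rows[i - 1][j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    cols = len(aligned_a)
    return AlignmentResult(100.0 * matches / cols, cols, matches, rows[n][m],
                           aligned_a, aligned_b)


def spacer_origin_scan(spacer: str, gene: str) -> tuple[int, AlignmentResult]:
    """Best identity of a spacer against every gene window of the spacer's length.

    Slides the spacer across the gene; returns (offset, alignment) for the
    window maximizing identity, ties broken by the leftmost window.  Used to
    ask whether a spacer arose by partial duplication of the gene.
    """
    if len(gene) <= len(spacer):
        raise ValueError("gene must be longer than the spacer")
    best: tuple[int, AlignmentResult] | None = None
    w = len(spacer)
    for off in range(len(gene) - w + 1):
        res = global_identity(spacer, gene[off : off + w])
        if best is None or res.identity > best[1].identity:
            best = (off, res)
    return best
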