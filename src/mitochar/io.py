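"""Reading, writing and coordinate handling for annotated mitochondrial genomes.

Internal convention: 0-based half-open coordinates on the stored forward
strand (the J, majority strand).  A feature that wraps across the origin of
the circle is encoded with ``end > genome length``; modular reduction happens
only at sequence extraction time.  Strands are named ``J`` (forward/majority)
and ``N`` (reverse/minority), the vocabulary used for insect mitogenomes.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "AnnotatedMitogenome",
    "GeneOrderComparison",
    "read_genbank",
    "write_genbank",
    "read_fasta_tsv",
    "write_fasta_tsv",
    "extract_feature_sequence",
    "compare_gene_order",
    "revcomp",
    "CANONICAL_GENE_ORDER",
    "ANCESTRAL_INSECT_ORDER",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One gene on the circle.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``end`` may exceed the
    genome length to encode a wrap across the origin.  ``kind`` is one of
    ``PCG``, ``tRNA``, ``rRNA``, ``control``.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str = "J"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"feature {self.name}: end must exceed start")
        if self.strand not in ("J", "N"):
            raise ValueError(f"feature {self.name}: strand must be J or N")
        if self.kind not in ("PCG", "tRNA", "rRNA", "control", "other"):
            raise ValueError(f"feature {self.name}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length


@dataclass
class AnnotatedMitogenome:
    """A circular (or linear) mitochondrial genome plus its ordered feature table."""

    identifier: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    topology: str = "circular"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-DNA characters: {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise ValueError("topology must be 'circular' or 'linear'")
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        n = len(self.sequence)
        for f in self.features:
            if f.length > n:
                raise ValueError(f"feature {f.name} longer than genome")
            if f.start < 0 or f.start >= n:
                raise ValueError(f"feature {f.name} start outside [0, length)")
            if f.end > n and self.topology != "circular":
                raise ValueError(f"feature {f.name} wraps a linear genome")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def gene_order(self) -> list[str]:
        """Feature names sorted by start position on the circle."""
        return [f.name for f in sorted(self.features, key=lambda f: (f.start, f.end))]

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]


def extract_feature_sequence(genome: AnnotatedMitogenome, feature: GeneFeature) -> str:
    """Reading-direction sequence of a feature (modular slice, revcomp for N)."""
    n = genome.length
    if feature.end <= n:
        s = genome.sequence[feature.start : feature.end]
    else:
        s = genome.sequence[feature.start :] + genome.sequence[: feature.end - n]
    return revcomp(s) if feature.strand == "N" else s


# ---------------------------------------------------------------------------
# Gene-name normalization
# ---------------------------------------------------------------------------

#: Canonical symbols for the 37 genes + control region.
_AA3_TO_TRN = {
    "ALA": "trnA", "ARG": "trnR", "ASN": "trnN", "ASP": "trnD", "CYS": "trnC",
    "GLN": "trnQ", "GLU": "trnE", "GLY": "trnG", "HIS": "trnH", "ILE": "trnI",
    "LYS": "trnK", "MET": "trnM", "PHE": "trnF", "PRO": "trnP", "THR": "trnT",
    "TRP": "trnW", "TYR": "trnY", "VAL": "trnV",
}

ALIASES: dict[str, str] = {
    # protein-coding genes
    "COI": "cox1", "CO1": "cox1", "COX1": "cox1", "COXI": "cox1",
    "COII": "cox2", "CO2": "cox2", "COX2": "cox2", "COXII": "cox2",
    "COIII": "cox3", "CO3": "cox3", "COX3": "cox3", "COXIII": "cox3",
    "ND1": "nad1", "NAD1": "nad1", "NADH1": "nad1",
    "ND2": "nad2", "NAD2": "nad2", "NADH2": "nad2",
    "ND3": "nad3", "NAD3": "nad3", "NADH3": "nad3",
    "ND4": "nad4", "NAD4": "nad4", "NADH4": "nad4",
    "ND4L": "nad4l", "NAD4L": "nad4l", "NADH4L": "nad4l",
    "ND5": "nad5", "NAD5": "nad5", "NADH5": "nad5",
    "ND6": "nad6", "NAD6": "nad6", "NADH6": "nad6",
    "ATP6": "atp6", "ATPASE6": "atp6", "ATPASE 6": "atp6",
    "ATP8": "atp8", "ATPASE8": "atp8", "ATPASE 8": "atp8",
    "CYTB": "cob", "CYB": "cob", "COB": "cob", "CB": "cob",
    # rRNAs
    "16S": "rrnL", "16S RRNA": "rrnL", "L-RRNA": "rrnL", "RRNL": "rrnL",
    "LARGE SUBUNIT RIBOSOMAL RNA": "rrnL", "LSU": "rrnL",
    "12S": "rrnS", "12S RRNA": "rrnS", "S-RRNA": "rrnS", "RRNS": "rrnS",
    "SMALL SUBUNIT RIBOSOMAL RNA": "rrnS", "SSU": "rrnS",
    # control region
    "D-LOOP": "AT_rich", "A+T RICH REGION": "AT_rich", "A+T-RICH REGION": "AT_rich",
    "AT RICH REGION": "AT_rich", "AT_RICH": "AT_rich", "CONTROL REGION": "AT_rich",
}


def normalize_gene_name(raw: str, feature_key: str = "", qualifiers: dict | None = None) -> tuple[str, bool]:
    """Map a record's gene label to a canonical symbol.

    Returns ``(name, known)``; unknown labels are kept verbatim so third-party
    records never lose features.  tRNA names are resolved from the amino acid
    (``tRNA-Met`` -> ``trnM``) with the Leu/Ser paralogs disambiguated by the
    codon family written in the label (``tRNA-Leu(CUN)`` -> ``trnL1``,
    ``(UUR)`` -> ``trnL2``, ``tRNA-Ser(AGN)`` -> ``trnS1``, ``(UCN)`` -> ``trnS2``).
    """
    qualifiers = qualifiers or {}
    label = raw.strip()
    up = label.upper()
    if up in ALIASES:
        return ALIASES[up], True
    canonical = {"cox1", "cox2", "cox3", "nad1", "nad2", "nad3", "nad4", "nad4l",
                 "nad5", "nad6", "atp6", "atp8", "cob", "rrnL", "rrnS", "AT_rich"}
    low = label.lower()
    if low in {c.lower() for c in canonical}:
        for c in canonical:
            if c.lower() == low:
                return c, True
    if low.startswith("trn") and 4 <= len(label) <= 6:
        return label if label[:3] == "trn" else "trn" + label[3:], True
    if "TRNA" in up:
        # e.g. "tRNA-Leu (CUN)" or product qualifier
        for aa3, sym in _AA3_TO_TRN.items():
            if aa3 in up:
                return sym, True
        if "LEU" in up:
            return ("trnL1", True) if "CUN" in up else ("trnL2", True)
        if "SER" in up:
            return ("trnS1", True) if "AGN" in up else ("trnS2", True)
    return label, False


_KIND_BY_KEY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                "D-loop": "control", "misc_feature": "other"}


def _kind_for(name: str, feature_key: str) -> str:
    if name == "AT_rich":
        return "control"
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    return _KIND_BY_KEY.get(feature_key, "other")


# ---------------------------------------------------------------------------
# GenBank I/O (via Biopython)
# ---------------------------------------------------------------------------


def _location_to_span(loc, length: int) -> tuple[int, int]:
    """Convert a Biopython location to (start, end) with wrap encoded as end > length."""
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) == 2 and int(parts[1].end) == length and int(parts[0].start) == 0:
            # origin-spanning join: tail part then head part
            return int(parts[1].start), length + int(parts[0].end)
        raise ValueError(f"unsupported compound location {loc}")
    return int(loc.start), int(loc.end)


def read_genbank(source) -> AnnotatedMitogenome:
    """Parse a single-record GenBank flat file into an :class:`AnnotatedMitogenome`.

    1-based inclusive coordinates become 0-based half-open; ``complement``
    features get strand N; origin-spanning joins are encoded with
    ``end > length``.  Gene labels are normalized through the alias map;
    unknown labels are kept verbatim with a warning.
    """
    records = list(SeqIO.parse(source, "genbank"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one GenBank record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    topology = rec.annotations.get("topology", "circular")
    features: list[GeneFeature] = []
    seen: set[str] = set()
    for feat in rec.features:
        if feat.type in ("source", "gene"):
            continue
        if feat.type not in ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature"):
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [feat.type])[0]
        name, known = normalize_gene_name(raw, feat.type, quals)
        if not known:
            warnings.warn(f"unknown gene alias {raw!r}; kept verbatim", stacklevel=2)
        if name in seen:  # paired gene/CDS annotations collapse to one feature
            continue
        start, end = _location_to_span(feat.location, len(seq))
        if start < 0 or start >= len(seq) or end - start > len(seq):
            raise ValueError(f"feature {name} outside sequence bounds")
        strand = "N" if feat.location.strand == -1 else "J"
        features.append(GeneFeature(name, _kind_for(name, feat.type), start, end, strand))
        seen.add(name)
    return AnnotatedMitogenome(rec.id or rec.name, seq, features, topology)


def write_genbank(genome: AnnotatedMitogenome, handle) -> None:
    """Write the genome as a single GenBank record readable by :func:`read_genbank`."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.identifier, name=genome.identifier[:16],
                    description="annotated mitochondrial genome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    key_by_kind = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                   "control": "misc_feature", "other": "misc_feature"}
    n = genome.length
    for f in genome.features:
        strand = -1 if f.strand == "N" else 1
        if f.end <= n:
            loc = SimpleLocation(f.start, f.end, strand=strand)
        else:
            parts = [SimpleLocation(f.start, n, strand=strand),
                     SimpleLocation(0, f.end - n, strand=strand)]
            if strand == -1:
                parts = parts[::-1]
            loc = CompoundLocation(parts)
        quals = {"gene": [f.name]}
        if f.name == "AT_rich":
            quals["note"] = ["A+T rich region"]
        rec.features.append(SeqFeature(loc, type=key_by_kind[f.kind], qualifiers=quals))
    if isinstance(handle, (str, Path)):
        with open(handle, "w") as fh:
            SeqIO.write([rec], fh, "genbank")
    else:
        SeqIO.write([rec], handle, "genbank")


def genbank_text(genome: AnnotatedMitogenome) -> str:
    buf = _io.StringIO()
    write_genbank(genome, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# FASTA + TSV feature table I/O
# ---------------------------------------------------------------------------

_TSV_HEADER = ["name", "kind", "start", "end", "strand"]


def read_fasta_tsv(fasta_source, tsv_source) -> AnnotatedMitogenome:
    """Read a genome from FASTA plus a tab-separated feature table.

    The table uses 1-based inclusive coordinates and +/- strands (the
    conventional exchange format); they are converted to the internal 0-based
    half-open J/N representation.
    """
    records = list(SeqIO.parse(fasta_source, "fasta"))
    if len(records) != 1:
        raise ValueError("expected exactly one FASTA record")
    rec = records[0]
    lines = Path(tsv_source).read_text().splitlines() if isinstance(tsv_source, (str, Path)) \
        else tsv_source.read().splitlines()
    features = []
    for line in lines:
        if not line.strip() or line.startswith("#") or line.split("\t")[0] == "name":
            continue
        name, kind, start, end, strand = line.rstrip("\n").split("\t")
        features.append(GeneFeature(name, kind, int(start) - 1, int(end),
                                    "N" if strand in ("-", "N") else "J"))
    return AnnotatedMitogenome(rec.id, str(rec.seq), features)


def write_fasta_tsv(genome: AnnotatedMitogenome, fasta_handle, tsv_handle) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.identifier, description="")
    if isinstance(fasta_handle, (str, Path)):
        with open(fasta_handle, "w") as fh:
            SeqIO.write([rec], fh, "fasta")
    else:
        SeqIO.write([rec], fasta_handle, "fasta")
    rows = ["\t".join(_TSV_HEADER)]
    for f in genome.features:
        rows.append("\t".join([f.name, f.kind, str(f.start + 1), str(f.end),
                               "-" if f.strand == "N" else "+"]))
    text = "\n".join(rows) + "\n"
    if isinstance(tsv_handle, (str, Path)):
        Path(tsv_handle).write_text(text)
    else:
        tsv_handle.write(text)


# ---------------------------------------------------------------------------
# Gene-order comparison
# ---------------------------------------------------------------------------

#: The derived lepidopteran order (control region first, then trnM before trnI).
CANONICAL_GENE_ORDER: tuple[str, ...] = (
    "AT_rich", "trnM", "trnI", "trnQ", "nad2", "trnW", "trnC", "trnY", "cox1",
    "trnL2", "cox2", "trnK", "trnD", "atp8", "atp6", "cox3", "trnG", "nad3",
    "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF", "nad5", "trnH", "nad4",
    "nad4l", "trnT", "trnP", "nad6", "cob", "trnS2", "nad1", "trnL1", "rrnL",
    "trnV", "rrnS",
)

#: Ancestral insect arrangement of the same genes (trnI-trnQ-trnM after the control region).
ANCESTRAL_INSECT_ORDER: tuple[str, ...] = (
    "AT_rich", "trnI", "trnQ", "trnM", "nad2", "trnW", "trnC", "trnY", "cox1",
    "trnL2", "cox2", "trnK", "trnD", "atp8", "atp6", "cox3", "trnG", "nad3",
    "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF", "nad5", "trnH", "nad4",
    "nad4l", "trnT", "trnP", "nad6", "cob", "trnS2", "nad1", "trnL1", "rrnL",
    "trnV", "rrnS",
)


@dataclass
class GeneOrderComparison:
    identical: bool
    displaced: tuple[str, ...] | None
    only_in_a: tuple[str, ...]
    only_in_b: tuple[str, ...]


def _rotations_equal(a: Sequence[str], b: Sequence[str]) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    la = list(a)
    lb = list(b)
    return any(lb[i:] + lb[:i] == la for i in range(len(lb)))


def compare_gene_order(order_a, order_b, max_displaced: int = 4) -> GeneOrderComparison:
    """Rotation-invariant comparison of two circular gene orders.

    Reports whether the orders are identical up to rotation; otherwise the
    smallest set of shared genes whose removal from both makes them identical,
    searched exhaustively by increasing size (ties broken by the
    alphabetically first set).  Genes present in only one order are reported
    separately and excluded from the search.
    """
    if isinstance(order_a, AnnotatedMitogenome):
        order_a = order_a.gene_order()
    if isinstance(order_b, AnnotatedMitogenome):
        order_b = order_b.gene_order()
    a, b = list(order_a), list(order_b)
    common = set(a) & set(b)
    only_a = tuple(x for x in a if x not in common)
    only_b = tuple(x for x in b if x not in common)
    ra = [x for x in a if x in common]
    rb = [x for x in b if x in common]
    if _rotations_equal(ra, rb):
        return GeneOrderComparison(not only_a and not only_b, (), only_a, only_b)
    for k in range(1, max_displaced + 1):
        for drop in combinations(sorted(common), k):
            ds = set(drop)
            if _rotations_equal([x for x in ra if x not in ds],
                                [x for x in rb if x not in ds]):
                return GeneOrderComparison(False, tuple(drop), only_a, only_b)
    return GeneOrderComparison(False, None, only_a, only_b)
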