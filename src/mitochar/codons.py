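"""Codon usage under the invertebrate mitochondrial genetic code.

Covers translation (with internal-stop flagging and incomplete terminal
codons), start/stop classification for mitochondrial CDS — including the
single-T and TA incomplete stops completed by post-transcriptional
polyadenylation — per-codon counts, relative synonymous codon usage (RSCU),
and amino-acid frequencies.

RSCU of codon c is count(c) * k / family_total where k is the size of c's
synonymous family.  Under the invertebrate mitochondrial code Leu is one
six-codon family (TTR + CTN) and Ser one eight-codon family (TCN + AGN);
stop codons form no family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Data import CodonTable

from .io import AnnotatedMitogenome, extract_feature_sequence

__all__ = [
    "GeneticCode", "INVERTEBRATE_MITO", "ARTHROPOD_VARIANT",
    "CodonUsageTable", "StartStopEntry",
    "classify_start_codon", "classify_stop_codon", "translate_cds",
    "codon_counts", "rscu", "aa_frequencies", "build_usage", "start_stop_report",
]

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass(frozen=True)
class GeneticCode:
    """A total map from the 64 codons to one-letter amino acids ('*' = stop)."""

    name: str
    codon_to_aa: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("genetic code must cover exactly the 64 codons")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")

    def families(self) -> dict[str, tuple[str, ...]]:
        """Amino acid -> synonymous codons (stops excluded)."""
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = self.codon_to_aa[codon]
            if aa != "*":
                fams.setdefault(aa, []).append(codon)
        return {aa: tuple(cs) for aa, cs in fams.items()}


def _code_from_ncbi(table_id: int, name: str) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return GeneticCode(name, mapping)


#: NCBI translation table 5: AGA/AGG = Ser, ATA = Met, TGA = Trp.
INVERTEBRATE_MITO = _code_from_ncbi(5, "invertebrate mitochondrial")

#: Variant arthropod code in which AGG is reassigned to Lys; available but
#: never the default (the moth genome this package models does not use AGG).
ARTHROPOD_VARIANT = GeneticCode(
    "arthropod variant (AGG=Lys)",
    {**INVERTEBRATE_MITO.codon_to_aa, "AGG": "K"},
)


# ---------------------------------------------------------------------------
# Start / stop classification
# ---------------------------------------------------------------------------

_ATN = {"ATT", "ATC", "ATA", "ATG"}


def classify_start_codon(cds: str) -> tuple[str, str]:
    """Classify the first triplet as ATN (ATT/ATC/ATA/ATG), CGA, or other."""
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    triplet = cds[:3].upper()
    if triplet in _ATN:
        return "ATN", triplet
    if triplet == "CGA":
        return "CGA", triplet
    return "other", triplet


def classify_stop_codon(cds: str) -> str:
    """Stop class of a mitochondrial CDS.

    complete_TAA / complete_TAG when the length is a codon multiple and the
    final triplet is that stop; incomplete_T when one base hangs over and it
    is T; incomplete_TA when two hang over and they are TA; otherwise other.
    Incomplete stops are completed to TAA on the transcript by
    polyadenylation, so the genomic CDS simply ends in T or TA.
    """
    if len(cds) < 4:
        raise ValueError("CDS too short to classify a stop")
    s = cds.upper()
    r = len(s) % 3
    if r == 0:
        last = s[-3:]
        if last == "TAA":
            return "complete_TAA"
        if last == "TAG":
            return "complete_TAG"
        return "other"
    if r == 1:
        return "incomplete_T" if s[-1] == "T" else "other"
    return "incomplete_TA" if s[-2:] == "TA" else "other"


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------


@dataclass
class Translation:
    peptide: str
    internal_stops: tuple[int, ...]  # codon indices with a stop before the end
    trailing_bases: int  # 0-2 bases of an incomplete terminal codon, dropped
    terminal_stop: str | None  # the excluded final stop codon, if complete


def translate_cds(cds: str, code: GeneticCode = INVERTEBRATE_MITO) -> Translation:
    """In-frame translation; terminal stop excluded, internal stops flagged."""
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    s = cds.upper()
    trailing = len(s) % 3
    body = s[: len(s) - trailing] if trailing else s
    aas: list[str] = []
    internal: list[int] = []
    n_codons = len(body) // 3
    for i in range(n_codons):
        codon = body[3 * i : 3 * i + 3]
        aa = code.codon_to_aa.get(codon, "X")
        aas.append(aa)
    terminal_stop = None
    if aas and aas[-1] == "*":
        terminal_stop = body[-3:]
        aas.pop()
    for i, aa in enumerate(aas):
        if aa == "*":
            internal.append(i)
    return Translation("".join(aas), tuple(internal), trailing, terminal_stop)


# ---------------------------------------------------------------------------
# Counts, RSCU, amino-acid frequencies
# ---------------------------------------------------------------------------


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    n_codons: int
    skipped_ambiguous: int = 0
    rscu: dict[str, float] = field(default_factory=dict)
    aa_percent: dict[str, float] = field(default_factory=dict)


def _in_frame_codons(cds: str, code: GeneticCode) -> Iterable[str]:
    """Counted triplets: frame 0, terminal complete stop and trailing 1-2 nt excluded."""
    s = cds.upper()
    trailing = len(s) % 3
    body = s[: len(s) - trailing] if trailing else s
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    if codons and codons[-1] in code.stop_codons:
        codons.pop()
    return codons


def codon_counts(cds_set: Iterable[str], code: GeneticCode = INVERTEBRATE_MITO) -> CodonUsageTable:
    counts: Counter[str] = Counter()
    skipped = 0
    for cds in cds_set:
        for codon in _in_frame_codons(cds, code):
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
            else:
                skipped += 1
    full = {c: counts.get(c, 0) for c in ALL_CODONS}
    return CodonUsageTable(full, sum(counts.values()), skipped)


def rscu(table: CodonUsageTable, code: GeneticCode = INVERTEBRATE_MITO) -> CodonUsageTable:
    """Fill the RSCU column: count * family_size / family_total (0 if the family is unused)."""
    values: dict[str, float] = {}
    for aa, fam in code.families().items():
        total = sum(table.counts.get(c, 0) for c in fam)
        k = len(fam)
        for c in fam:
            values[c] = table.counts.get(c, 0) * k / total if total else 0.0
    for stop in code.stop_codons:
        values.setdefault(stop, 0.0)
    table.rscu = values
    return table


def aa_frequencies(cds_set: Iterable[str], code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, float]:
    """Percent of each amino acid among all translated (non-stop) codons."""
    table = codon_counts(cds_set, code)
    totals: Counter[str] = Counter()
    for codon, n in table.counts.items():
        aa = code.codon_to_aa[codon]
        if aa != "*":
            totals[aa] += n
    grand = sum(totals.values())
    return {aa: 100.0 * n / grand for aa, n in sorted(totals.items()) if n} if grand else {}


def build_usage(cds_set: Iterable[str], code: GeneticCode = INVERTEBRATE_MITO) -> CodonUsageTable:
    """Counts + RSCU + amino-acid percentages in one pass over a CDS collection."""
    cds_list = list(cds_set)
    table = rscu(codon_counts(cds_list, code), code)
    table.aa_percent = aa_frequencies(cds_list, code)
    return table


# ---------------------------------------------------------------------------
# Per-genome start/stop report
# ---------------------------------------------------------------------------


@dataclass
class StartStopEntry:
    gene: str
    start_triplet: str
    start_class: str
    stop_class: str


def start_stop_report(genome: AnnotatedMitogenome) -> list[StartStopEntry]:
    """Start and stop classification for every protein-coding gene of a genome."""
    entries = []
    for f in sorted(genome.features_of_kind("PCG"), key=lambda f: f.start):
        cds = extract_feature_sequence(genome, f)
        cls, triplet = classify_start_codon(cds)
        entries.append(StartStopEntry(f.name, triplet, cls, classify_stop_codon(cds)))
    return entries
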