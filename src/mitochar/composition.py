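"""Nucleotide composition and A+T statistics, whole-genome and per partition.

A+T percent, G+C percent and the two strand skews, AT-skew = (A-T)/(A+T) and
GC-skew = (G-C)/(G+C), computed on the J strand.  N bases are excluded from
all counts and denominators.  Per-class partitions (PCG, rRNA, tRNA) are
computed on the concatenation of the reading-direction sequences of the
member features, so a base shared by two overlapping genes counts once per
gene.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import AnnotatedMitogenome, extract_feature_sequence

__all__ = ["CompositionReport", "base_composition", "partition_composition", "PARTITIONS"]

PARTITIONS = ("whole", "PCG", "rRNA", "tRNA", "rrnL", "rrnS", "control")


@dataclass
class CompositionReport:
    counts: dict[str, int]
    denominator: int
    at_percent: float | None
    gc_percent: float | None
    at_skew: float | None
    gc_skew: float | None

    def as_dict(self) -> dict:
        return {"counts": dict(self.counts), "denominator": self.denominator,
                "at_percent": self.at_percent, "gc_percent": self.gc_percent,
                "at_skew": self.at_skew, "gc_skew": self.gc_skew}


def base_composition(seq: str) -> CompositionReport:
    """Composition of one sequence; skews are None when their denominator is 0."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    s = seq.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    denom = a + c + g + t
    at = a + t
    gc = g + c
    return CompositionReport(
        counts=counts,
        denominator=denom,
        at_percent=100.0 * at / denom if denom else None,
        gc_percent=100.0 * gc / denom if denom else None,
        at_skew=(a - t) / at if at else None,
        gc_skew=(g - c) / gc if gc else None,
    )


def partition_composition(genome: AnnotatedMitogenome) -> dict[str, CompositionReport | None]:
    """Composition for the standard partitions; absent partitions map to None.

    ``control`` uses the annotated A+T-rich feature when present, else the
    largest unannotated gap on the circle (the usual fallback for records
    that do not annotate the control region).
    """
    out: dict[str, CompositionReport | None] = {}
    out["whole"] = base_composition(genome.sequence)
    for kind, key in (("PCG", "PCG"), ("rRNA", "rRNA"), ("tRNA", "tRNA")):
        feats = genome.features_of_kind(kind)
        out[key] = base_composition(
            "".join(extract_feature_sequence(genome, f) for f in feats)) if feats else None
    for gene in ("rrnL", "rrnS"):
        try:
            out[gene] = base_composition(
                extract_feature_sequence(genome, genome.feature(gene)))
        except KeyError:
            out[gene] = None
    control = _control_sequence(genome)
    out["control"] = base_composition(control) if control else None
    return out


def _control_sequence(genome: AnnotatedMitogenome) -> str | None:
    ctrl = genome.features_of_kind("control")
    if ctrl:
        return extract_feature_sequence(genome, ctrl[0])
    # fallback: largest unannotated gap on the circle
    from .noncoding import catalog_spacers_overlaps  # local import avoids a cycle
    if len(genome.features) < 2:
        return None
    spacers, _ = catalog_spacers_overlaps(genome)
    if not spacers.entries:
        return None
    best = max(spacers.entries, key=lambda s: s.length)
    return best.sequence
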