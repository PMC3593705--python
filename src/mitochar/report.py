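"""One-shot characterization report tying every analysis stage together.

The report is a plain JSON-serializable dict (the canonical output); TSV
projections of its main tables can be written alongside.  Sections that an
input cannot support (e.g. a FASTA with no feature table) are present but
marked absent with a reason, so a report always has the same shape.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

from . import codons as _codons
from . import composition as _composition
from . import noncoding as _noncoding
from . import trna as _trna
from .io import AnnotatedMitogenome, extract_feature_sequence, read_fasta_tsv, read_genbank
from .synthetic import ANTICODONS

__all__ = ["run_characterize", "write_report"]


def _absent(reason: str) -> dict:
    return {"absent": True, "reason": reason}


def load_genome(path, table=None) -> AnnotatedMitogenome:
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".genbank"):
        return read_genbank(path)
    if table is None:
        from Bio import SeqIO
        rec = next(iter(SeqIO.parse(path, "fasta")))
        return AnnotatedMitogenome(rec.id, str(rec.seq), [])
    return read_fasta_tsv(path, table)


def run_characterize(genome_or_path, code=_codons.INVERTEBRATE_MITO,
                     min_spacer: int = 1, motifs: tuple[str, ...] = ("ATACTAA",),
                     motif_max_mismatch: int = 1, feature_table=None,
                     log=sys.stderr) -> dict:
    """Run every stage on one genome and return the full report dict."""
    if isinstance(genome_or_path, AnnotatedMitogenome):
        genome = genome_or_path
    else:
        genome = load_genome(genome_or_path, feature_table)

    def decision(msg: str) -> None:
        if log is not None:
            print(f"[mitochar] {msg}", file=log)

    report: dict = {}
    counts = {k: len(genome.features_of_kind(k)) for k in ("PCG", "tRNA", "rRNA", "control")}
    strands = {
        "J": sum(1 for f in genome.features if f.strand == "J"),
        "N": sum(1 for f in genome.features if f.strand == "N"),
    }
    report["genome"] = {
        "identifier": genome.identifier,
        "length_bp": genome.length,
        "topology": genome.topology,
        "gene_counts": counts,
        "total_features": len(genome.features),
        "strand_distribution": strands,
        "gene_order": genome.gene_order(),
    }

    comp = _composition.partition_composition(genome)
    report["composition"] = {k: (v.as_dict() if v else _absent("partition missing"))
                             for k, v in comp.items()}

    if counts["PCG"]:
        cds = {f.name: extract_feature_sequence(genome, f)
               for f in genome.features_of_kind("PCG")}
        usage = _codons.build_usage(cds.values(), code)
        report["start_stop"] = [vars(e) for e in _codons.start_stop_report(genome)]
        report["codon_usage"] = {
            "n_codons": usage.n_codons,
            "counts": usage.counts,
            "rscu": usage.rscu,
            "aa_percent": usage.aa_percent,
            "absent_codons": sorted(c for c, n in usage.counts.items()
                                    if n == 0 and code.codon_to_aa[c] != "*"),
        }
    else:
        report["start_stop"] = _absent("no protein-coding features annotated")
        report["codon_usage"] = _absent("no protein-coding features annotated")

    trnas = genome.features_of_kind("tRNA")
    if trnas:
        folds = {}
        table = []
        for f in sorted(trnas, key=lambda f: f.start):
            seq = extract_feature_sequence(genome, f)
            anticodon = ANTICODONS.get(f.name)
            fold = _trna.fold_cloverleaf(seq, expected_anticodon=anticodon,
                                         allow_dhu_less=True)
            if fold.topology == "unfoldable" and anticodon is not None:
                decision(f"{f.name}: no fold with anticodon {anticodon}; retrying unanchored")
                fold = _trna.fold_cloverleaf(seq, allow_dhu_less=True)
            folds[f.name] = fold
            table.append({"gene": f.name, "length": len(seq), "topology": fold.topology,
                          "anticodon": fold.anticodon, "score": fold.score,
                          "mismatches": sum(1 for p in fold.pairs if p[2] != "WC"),
                          "dot_bracket": _trna.to_dot_bracket(fold)})
        census = _trna.census_mismatches(folds.values())
        report["trna"] = {"table": table, "census": census.as_dict()}
    else:
        report["trna"] = _absent("no tRNA features annotated")

    if len(genome.features) >= 2:
        spacers, overlaps = _noncoding.catalog_spacers_overlaps(genome)
        report["spacers"] = {
            "total_count": spacers.total_count,
            "total_bp": spacers.total_bp,
            "entries": [{"left": s.left, "right": s.right, "start": s.start,
                         "length": s.length, "at_percent": s.at_percent,
                         "sequence": s.sequence}
                        for s in spacers.entries if s.length >= min_spacer],
        }
        report["overlaps"] = {
            "total_count": overlaps.total_count,
            "total_bp": overlaps.total_bp,
            "entries": [{"a": o.a, "b": o.b, "start": o.start, "length": o.length,
                         "sequence": o.sequence} for o in overlaps.entries],
            "containments": overlaps.containments,
        }
        report["circle_accounting"] = _noncoding.circle_accounting(genome)
        label, ctrl_seq = _noncoding.control_region(genome)
        if label.startswith("largest_gap"):
            decision(f"control region fallback: {label}")
        noncoding_seq = "".join(s.sequence for s in spacers.entries) + (
            ctrl_seq if label != "AT_rich" else "")
        scan_targets = [("control", ctrl_seq)] + [
            (f"spacer:{s.left}-{s.right}", s.sequence)
            for s in spacers.entries if s.length >= 10]
        repeats = []
        tracts = []
        motif_hits = []
        for where, seq in scan_targets:
            for h in _noncoding.find_tandem_repeats(seq):
                repeats.append({"where": where, "unit": h.unit,
                                "canonical_unit": h.canonical_unit, "copies": h.copies,
                                "start": h.start, "end": h.end})
            for base in "AT":
                for t in _noncoding.find_poly_tracts(seq, base, 8):
                    tracts.append({"where": where, "base": t.base, "start": t.start,
                                   "length": t.length})
            for m in motifs:
                for hit in _noncoding.find_motif(seq, m, motif_max_mismatch):
                    motif_hits.append({"where": where, "motif": m,
                                       "position": hit.position,
                                       "mismatches": hit.mismatches})
        report["repeats"] = repeats
        report["poly_tracts"] = tracts
        report["motifs"] = motif_hits
    else:
        for key in ("spacers", "overlaps", "circle_accounting", "repeats",
                    "poly_tracts", "motifs"):
            report[key] = _absent("fewer than two annotated features")
    return report


def write_report(report: dict, outdir) -> None:
    """JSON canonical output + TSV projections of the tabular sections."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    import pandas as pd

    cu = report.get("codon_usage")
    if isinstance(cu, dict) and not cu.get("absent"):
        rows = [{"codon": c, "count": cu["counts"][c], "rscu": cu["rscu"].get(c, 0.0)}
                for c in sorted(cu["counts"])]
        pd.DataFrame(rows).to_csv(outdir / "codon_usage.tsv", sep="\t", index=False)
    tr = report.get("trna")
    if isinstance(tr, dict) and not tr.get("absent"):
        pd.DataFrame(tr["table"]).to_csv(outdir / "trna.tsv", sep="\t", index=False)
    sp = report.get("spacers")
    if isinstance(sp, dict) and not sp.get("absent"):
        pd.DataFrame(sp["entries"]).to_csv(outdir / "spacers.tsv", sep="\t", index=False)
        pd.DataFrame(report["overlaps"]["entries"]).to_csv(
            outdir / "overlaps.tsv", sep="\t", index=False)
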