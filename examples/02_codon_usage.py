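"""Codon usage under the invertebrate mitochondrial code.

Builds the 13 coding sequences of a synthetic genome, classifies their start
and stop codons (including the single-T incomplete stops completed by
polyadenylation), and computes counts, RSCU and amino-acid frequencies.
"""

from mitochar import (GenomeSpec, build_usage, extract_feature_sequence,
                      generate_mitogenome, start_stop_report)
from mitochar.codons import INVERTEBRATE_MITO

genome, _ = generate_mitogenome(GenomeSpec(seed=7))
cds = [extract_feature_sequence(genome, f) for f in genome.features_of_kind("PCG")]

print("gene    start  class  stop")
for e in start_stop_report(genome):
    print(f"{e.gene:7s} {e.start_triplet}    {e.start_class:5s} {e.stop_class}")
# cox1 starts with CGA (arginine), the classic exception to the ATN rule;
# nad2/cox1/cox2/nad4 end in a bare T that becomes TAA on the transcript.

usage = build_usage(cds)
print(f"\n{usage.n_codons} codons counted (terminal stops and trailing bases excluded)")
print("codon  aa  count  RSCU   (RSCU > 1: used more than its synonymous average)")
for codon in sorted(usage.counts, key=lambda c: -usage.rscu.get(c, 0))[:8]:
    aa = INVERTEBRATE_MITO.codon_to_aa[codon]
    print(f"{codon}    {aa}  {usage.counts[codon]:5d}  {usage.rscu[codon]:.2f}")

absent = [c for c, n in usage.counts.items()
          if n == 0 and INVERTEBRATE_MITO.codon_to_aa[c] != "*"]
print(f"\nabsent sense codons: {sorted(absent)}")
top = sorted(usage.aa_percent.items(), key=lambda kv: -kv[1])[:4]
print("most frequent amino acids:",
      ", ".join(f"{aa} {pct:.2f}%" for aa, pct in top),
      f"(together {sum(p for _, p in top):.2f}% of all residues)")
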