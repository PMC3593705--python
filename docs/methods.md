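# Methods

`mitochar` characterizes annotated circular mitochondrial genomes of the kind
carried by insects: a ~15 kb circle with 13 protein-coding genes (PCGs),
22 tRNAs, 2 rRNAs and an A+T-rich control region. This note records the
models and procedures it implements, the defaults and why, and what its
synthetic-data generator does and does not emulate.

## Coordinates, strands, topology

All features live on a single stored forward strand — the J (majority)
strand, the one carrying cox1 — in 0-based half-open coordinates. A feature
crossing the origin of the circle is encoded with `end > genome length`;
modular reduction happens only when a sequence is extracted. Minority-strand
(N) features are reverse-complemented at extraction, so every downstream
stage sees reading-direction sequence. GenBank input (1-based inclusive,
`complement(join(...))` wraps) is normalized on read; gene labels go through
an alias map (COI→cox1, ND2→nad2, 16S→rrnL, tRNA-Leu(CUN)→trnL1, ...).
Unknown labels are preserved verbatim with a warning rather than dropped, so
third-party records never silently lose features.

## Composition

A+T% and G+C% with N bases excluded from every count and denominator;
AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), reported as missing when a
skew's denominator is zero. Partition values (PCG, rRNA, tRNA) are computed
on the concatenation of member reading-direction sequences, so a base shared
by two overlapping genes counts once per gene. This concatenation semantics
is a deliberate choice: per-class figures in the literature do not define a
de-duplication rule, and concatenation is reproducible and testable (the
weighted-mean identity over parts holds exactly). The PCG partition includes
the full annotated CDS span, incomplete stop nucleotides included. The
control partition uses the annotated A+T-rich feature; when a record lacks
one, the largest unannotated gap on the circle stands in, and the fallback is
logged.

## Codon usage

Translation uses the invertebrate mitochondrial code (NCBI table 5:
AGA/AGG = Ser, ATA = Met, TGA = Trp), built from Biopython's table. The
variant arthropod code with AGG reassigned to Lys is available as an
alternative but never the default. Start codons are classified ATN
(ATT/ATC/ATA/ATG — ATC included for generality although rarely observed),
CGA (the cox1 exception), or other. Stop classes follow the residue rule:
length ≡ 0 (mod 3) with TAA/TAG → complete; ≡ 1 with terminal T →
incomplete_T; ≡ 2 with terminal TA → incomplete_TA; anything else → other.
Incomplete stops are completed to TAA by post-transcriptional
polyadenylation; that is a transcript-level event, so trailing bases are
excluded from genomic codon counts and translations rather than padded.

RSCU(c) = count(c) × k / family total, with k the synonymous family size;
stop codons form no family; Leu is one six-codon family (TTR + CTN) and Ser
one eight-codon family (TCN + AGN), the standard convention when the source
of a usage table does not say otherwise. Within any used family the RSCU
values sum to k exactly — an arithmetic identity the tests exploit.
Amino-acid percentages count translated non-stop codons only; terminal
stops and the one-residue contribution of incomplete stops are excluded.

## tRNA cloverleaf folding

Structures are inferred, not energy-minimized: the folder enumerates every
arm-boundary assignment allowed by canonical cloverleaf geometry and keeps
the one that pairs the most stem positions, counting Watson–Crick and G-U
wobble pairs alike (ties: more WC pairs, then smaller DHU-loop start, then
lexicographically smallest boundary tuple — a total order, so folding is
deterministic). The geometry: acceptor stem fixed at 7 bp, anticodon arm
fixed at 5 bp + 7 nt loop with the anticodon central, DHU stem 3–4 bp with a
4–12 nt loop, TψC stem 4–5 bp with a 3–9 nt loop, variable region 3–9 nt,
inter-arm spacers and discriminator 0–3 nt each. The search space is ~10^4
assignments per gene, small enough that tests can check it against an
independent naive enumeration. An expected anticodon, when known, anchors
the search to folds placing that triplet at the loop center.

trnS1(AGN) lacks the DHU arm in most metazoans. When `allow_dhu_less` is
set and the best cloverleaf pairs any mandatory stem (acceptor, anticodon,
TψC) below 60%, a DHU-less topology — the arm replaced by a 2–14 nt unpaired
region — is also searched and the structure with the higher fraction of
paired stem positions wins. The 60% threshold is this package's own cut; the
literature states only the outcome (a missing DHU arm), not a criterion.

The mismatch census aggregates every non-WC stem pair across a genome's
folds: total, per arm, G-U wobbles separately from true mismatches, and true
mismatches by unordered pair class (A-A, A-C, A-G, C-U, G-G, U-U — written
in RNA letters; the sequences themselves are handled as DNA throughout, T
for U).

## Non-coding analysis

Features sorted by start on the circle define junctions; a positive gap is a
spacer, a negative gap an overlap, with the origin-spanning junction treated
identically. A feature wholly contained in another is catalogued as a
containment, excluded, and warned about. The accounting identity
Σ gene bp − overlap bp + spacer bp = genome length must hold exactly and is
tested on every synthetic genome.

Tandem repeats: all maximal exact arrays with unit 1–6 nt, fractional
trailing copies kept in coordinates and floored in printed copy numbers.
Minimum copies default to 8 (unit 1), 5 (unit 2), 3 (units 3–6) — the usual
microsatellite reporting thresholds. Only primitive units are reported, and
a unit is normalized to its lexicographically least rotation, which also
resolves the (AT)n-vs-(TA)n naming ambiguity. Homopolymer tracts are maximal
single-base runs (minimum length ≥ 5). Motif search is a Hamming scan with a
mismatch budget, optionally on both strands.

Identity between sequences is global (Needleman–Wunsch) alignment with
match +1, mismatch −1, linear gap −2, identity = matches / alignment
columns × 100. The scheme is configurable; these defaults are used for every
reported figure. Traceback ties prefer diagonal, then a gap in the second
sequence, then a gap in the first, making alignments reproducible. The
spacer-origin scan slides a spacer over every same-length gene window and
reports the best-identity window (leftmost on ties). Because AT-rich
sequences align well by chance, a duplication claim should compare the
observed identity against a shuffled-spacer null rather than a fixed
threshold; the tests do exactly that.

Gene-order comparison is rotation-invariant on the circle. When two orders
differ, the reported displacement is the smallest set of shared genes whose
removal makes the orders identical up to rotation, found by exhaustive
search over subsets of size ≤ 4 (ties broken by the alphabetically first
set). Real mitogenome rearrangements at n ≈ 37 involve one or two genes;
beyond size 4 the function reports failure explicitly rather than guessing.

## Synthetic genomes

The generator emits a deterministic (seeded) annotated circle plus a truth
table listing every planted element. Defaults are the study conditions of
the lepidopteran genome the package models:

- 15,273 bp total; the 37-gene complement in the derived order (control
  region – trnM – trnI – trnQ – nad2 – ...), 14 tRNAs on J and 8 on N. The
  nad5 gene is the flex member whose length absorbs the residual so the
  total is exact; a 1-bp shim spacer takes the 0–2 bp rounding remainder.
- Background bases drawn per site with P(A) = P(T) = at/2,
  P(C) = P(G) = (1−at)/2. Per-partition targets: PCG 0.7896, rrnL 0.8295,
  rrnS 0.8586, tRNA 0.80. The control region is built with exactly 12 G/C
  bases in 351 bp (96.58% A+T by construction).
- PCGs are generated in frame with the documented start codons (CGA for
  cox1, ATN otherwise) and stop classes (single-T for nad2/cox1/cox2/nad4,
  TAA otherwise). The codon sampler rejects TAA/TAG (in-frame stops) and
  CTG/CCG/AGG (absent from the modelled genome's coding sequences), so
  internal stops cannot occur and those codons count zero by construction.
- Planted spacers: trnQ–nad2 61 bp with exactly 2 G/C (96.72% A+T);
  trnE–trnF 49 bp = (TA)18 + guard + (TTAT)3; trnS2–nad1 16 bp containing
  ATACTAT; nad1–trnL1 10 bp; eleven 1–3 bp spacers at fixed junctions. The
  control region carries ATAGA + a 20-bp poly-T + (TA)9 + (TA)8 + a 10-bp
  poly-A. Guard bases at every planted-array boundary (including the
  discriminators of the flanking tRNAs) ensure each array is maximal exactly
  as planted.
- Overlaps: 35 bp over 8 junctions — atp8/atp6 7 nt sharing ATGATAA (atp8's
  stop is built into atp6's start, as in the real gene pair), trnW/trnC
  8 bp, and six junctions of 1–5 bp. Where an overlap consumes a tRNA's
  acceptor tail, the generator rewrites the complementary acceptor positions
  so the planted fold still pairs; such tRNAs therefore carry no planted
  acceptor-stem mismatches.
- tRNAs come from cloverleaf templates (lengths 64–73 nt; trnS1 DHU-less,
  59–66 nt) with the standard anticodons. The default mismatch plan plants
  43 non-WC stem pairs — 24 G-U, split 20/8/9/6 over DHU/acceptor/TψC/
  anticodon arms across 20 of the 22 genes, with all six true-mismatch
  classes represented — mirroring the census of the modelled genome. Each
  tRNA is re-folded at generation time (anticodon-anchored) to certify that
  the planted structure is the folder's unique optimum. Planted true
  mismatches lower the truth score, so rival boundary assignments over the
  AT-rich loops can tie it; when one does, the builder mutates a free loop
  base the rival's pairing relies on (never a stem, anticodon or
  junction-forced position), which breaks the rival while leaving the
  planted structure intact, falling back to a full redraw if a rival uses
  only protected bases. Verified generation takes about a second per
  genome; `verify_trna=False` skips it for bulk runs that do not fold.

What the generator does **not** emulate: realistic codon-usage bias (codons
are sampled i.i.d. given the base composition, so amino-acid frequencies
reflect AT bias and family sizes, not selection — leucine comes out near
12–13% rather than the ~14% of real moth proteins), rRNA secondary
structure, sequence homology between the trnQ–nad2 spacer and nad2 (the
spacer is random, so the origin scan finds only chance identity), and
substitution-process realism of any kind. Passing recovery tests therefore
demonstrates that the finders detect what the annotation geometry and the
planted signals define — not that they would annotate a raw genome, which is
out of scope.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design: one
fully verified 15,273-bp genome as the shared fixture, 100 unverified
genomes for the circle-accounting identity, 2-kb random sequences for the
repeat-finder oracle, tRNAs ≤ 70 nt for the brute-force folding oracle, and
A+T recovery at three targets (0.70/0.80/0.85) judged on the ~11-kb PCG
partition within ±2 percentage points (≈ 5σ of binomial sampling; the codon
sampler's exclusions shift the expectation by up to ~0.7 points, which the
band accommodates). All randomness flows from explicit integer seeds;
identical spec + seed reproduces genomes byte for byte.

The reproduction check against the deposited reference record requires that
record as a local file (`data/HQ897685.gb`); it is not redistributed here,
and without it that single check reports failure explicitly instead of
passing vacuously. Every other check is self-contained.
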