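# Methods

## Overview

`intronit` designs intron-targeting (IT) PCR markers that distinguish an
alien chromosome arm (labelled V) from its three wheat homoeologs (A, B,
D). The method rests on two comparative-genomics assumptions: exon
sequences of orthologous Triticeae genes are conserved well enough for a
single primer pair to amplify all four genomes, while intron lengths
diverge fast enough that a size difference of ≥ 10% is common and
resolvable on a polyacrylamide gel. Each pipeline stage below documents
its model, parameters and the choices made where the design was open.

## Gene-set construction

Two annotation sources describing the same chromosome arm are merged into
a non-redundant query set. Redundancy between two transcripts is called
from a striped local alignment (match +1, mismatch −2, gap open −5, gap
extend −2, via Biopython's `PairwiseAligner`) when the e-value is
≤ 1e-5 and the aligned region covers > 80% of the reference transcript.
The e-value uses ungapped Karlin–Altschul statistics on the two-sequence
search space (λ solved from the score distribution under uniform base
composition; K fixed at 0.1 — at the 1e-5 cut-off the decision is
insensitive to K within an order of magnitude). The coverage denominator
is the **shorter** transcript by default: this is the conservative
reading (it flags more redundancy, which is the goal of a non-redundant
set); `longer` is available in the configuration. An adapter accepts
precomputed 12-column BLAST-tabular alignments in place of the built-in
aligner. A positional window filter (`window_filter`) restricts a source
to genes starting before a given pseudomolecule coordinate and degrades
to a warned no-op when positions are unknown.

## Spliced mapping

Transcripts are mapped onto each genomic arm with a seed–chain–extend
spliced aligner:

* **Seeding** — exact k-mer matches (default k = 15) are found via a
  2-bit-packed hash index of each scaffold (built once per
  scaffold/strand and cached); k-mers with more than 50 scaffold hits are
  treated as repeats and skipped. Seeds on a common diagonal merge into
  maximal exact anchors.
* **Chaining** — anchors are chained by dynamic programming requiring
  agreement of query and target order, a bounded unseeded query gap
  (200 bp) and a bounded target gap; the chain score is the total
  anchored length. Per arm the best chain wins, ties broken by query
  coverage, then lexicographic scaffold id, then strand — making the
  result independent of scaffold iteration order.
* **Block segmentation** — the chain splits into exon blocks wherever the
  target jumps ahead of the query by at least `min_intron_bp` (default
  40 bp, the smallest credible plant intron). Smaller jumps are treated
  as alignment artifacts and fused into one block.
* **Junction refinement** — the unseeded query stretch at each junction
  is split between the flanking exons at the position maximising base
  matches. The intron *size* is invariant to the split; only the
  junction's transcript coordinate depends on it.

An arm counts as hit when the best chain covers ≥ 50% of the transcript.
Junctions are matched across arms by transcript coordinate within a
12 bp tolerance (absorbing alignment-boundary wobble at exon ends); only
junctions recovered on all four arms yield an intron quartet. The mapper
is checked against an independent quadratic-DP spliced aligner (exact on
indel-free instances) and against generator ground truth.

## Polymorphism filter

A quartet is a *targeted intron* when the V size differs from every
wheat size simultaneously: `|V − w| / w ≥ t` for each `w ∈ {A, B, D}`,
with `t = 0.10`. The wheat-referenced denominator is the default reading
(all six published worked-example rows pass under it); `max` and `mean`
denominators are available. The one-marker-per-gene rule picks the intron
with the largest *minimum* relative difference — the most robustly
polymorphic — with ties going to the smallest junction index. The filter
is scale-invariant and threshold-monotone, which the test suite asserts
on random quartets.

## Primer design

Primers are enumerated in the two exons flanking the selected intron on
the V template, under: length 18–25 nt (optimum 20), Tm 55–65 °C
(optimum 60), GC 30–70%, no mononucleotide run > 4, no ambiguous base,
and a complementarity cap of 8 consecutive complementary bases as a
cheap hairpin/self- and cross-dimer screen. Tm is nearest-neighbour
thermodynamics (SantaLucia unified parameters at 50 mM monovalent salt
and 250 nM oligo, via Biopython's `Tm_NN`; a hand-rolled NN calculation
serves as an independent oracle in the tests, and the Wallace rule is a
quick fallback). Primer 3′ ends may sit up to 60 bp from the junction;
singles are scored by `|Tm − 60| + |len − 20|`, pairs add the Tm
difference, and the best 15 singles per side are paired exhaustively.

The product constraint "approximately 50 bp more than the targeted
intron" is made reproducible as a hard bound
`product_V ≥ intron_V + 50` plus a soft optimum
`intron_V + 50 + 2·(len_opt − len_min)`. Because exon sequence is assumed
conserved, the predicted product on any arm is the shared exonic
footprint plus that arm's intron size, so
`product(arm) − product(V) = intron(arm) − intron(V)` by construction.
Primer uniqueness in the genome is *not* enforced at design time; the
in-silico PCR stage screens for it, mirroring a design-then-screen
workflow. Genes where no pair qualifies are reported as design failures.

## In-silico PCR and band patterns

A primer anneals wherever it matches the template (either strand) with at
most 2 total mismatches and zero mismatches over its 3′-terminal 5
bases; template `N` counts as a mismatch. These defaults emulate the
permissiveness of real PCR and are configurable. Every convergent
forward/reverse site pair on one scaffold within 3000 bp yields an
amplicon. The implementation is a vectorised sliding-window comparison
and is tested for equality against an exhaustive position-by-position
scan.

Product sizes cluster into gel bands by single linkage: two sizes
co-migrate when `|Δ| ≤ max(4 bp, 1% · mean)`. The 1% relative term
approximates 8% PAGE resolution; it reproduces the published worked
examples (e.g. products 348/354/357/495 giving three bands with only the
two middle sizes merged), whereas 2% would merge all three wheat
products there. Typing is by band count with the alien product distinct:
four bands = Type I; three bands are labelled by the wheat arm hidden in
the merged pair (B → II, A → III, D → IV; the hidden member of a pair is
taken to be the larger product — a reporting convention, since gel truth
cannot decide it); two bands with all wheat merged = Type V. The
published labels VI and VII are accepted as aliases of IV and V. A
marker is **specific** iff its V product exists and shares no band with
any wheat product; a marker with zero amplicons on at least one template
is flagged `no-amplification`. Predicted patterns describe fragment
sizes only — amplification-efficiency effects are out of scope.

## Bin assignment

Translocation lines each retain a distal segment of the alien arm,
nested from smallest to largest. A marker present exactly in lines
`i..n` (ordered distal → proximal) maps between breakpoints `i−1` and
`i`; presence in a smaller segment with absence from a larger one
violates nesting and is flagged inconsistent rather than silently
binned.

## Synthetic panels

The generator emulates a homoeologous gene family: an ancestral gene
(2–6 exons of 90–220 bp; introns 80–1000 bp) is realized on each arm.
Wheat intron sizes get independent ±3% jitter; the alien size is drawn
either from a divergent range (14–40%, guaranteeing the 10% criterion
passes — *targeted* families) or a null range (0–5%, guaranteeing it
fails). The targeted status recorded in the truth table is always
recomputed from the realized sizes, and the panel composition (targeted
/ untargeted / intronless counts) is exact. Homologous introns share
ancestry: each junction has one ancestral core realized per arm as
`GT + core-prefix + AG`, so the 5′ splice region is conserved and the
size difference sits 3′-ward; the exon bases abutting each junction are
pinned so exon/intron boundaries cannot slide (as canonical GT–AG splice
sites fix them in real genes). Exons accumulate substitutions per arm
(default 2% on A, B, V; 0 on D, the annotated source genome), sparing
90 bp windows at junction-facing exon edges so primer sites stay
conserved; optional small indels avoid the same windows. Families are
embedded in composition-preserving shuffled decoy background with ≥ 2 kb
spacing, keeping spurious seed chains at quantifiable k-mer chance
levels.

What the panels do **not** model: codon structure, transposon insertion
spectra, segmental duplication, presence/absence variation of whole
introns, and assembly artifacts. Passing tests therefore demonstrate the
pipeline's internal correctness (exact size recovery, perfect
recall/precision on clean panels, ≥-threshold semantics), not its
performance on raw draft assemblies.

## Determinism and numerics

All randomness flows through seeded `numpy` generators; every selection
step has an explicit total tie-break (scores, then offsets, then
lexicographic sequence/scaffold ids), so fixed seed + fixed inputs give
bitwise-identical marker tables. The pipeline runner checksums its
inputs and config and skips an unchanged rerun. Degenerate inputs are
defined, not special-cased: transcripts too short to seed map nowhere,
genes with no complete quartet emit none, an empty candidate list is a
design failure, and a zero-gene funnel reports its mean as unavailable.

Problem sizes used in the shipped test suite — panels of 10–100
families, transcripts ≤ ~1 kb, scaffolds of tens of kb, 200 DP-oracle
and 500 e-PCR-oracle instances — were chosen as the smallest scales at
which every contract (including the end-to-end recall/precision check)
is exercised meaningfully.
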