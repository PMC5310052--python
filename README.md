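# intronit

Design and in-silico validation of **intron-targeting (IT) PCR markers**
for tracing alien chromatin in a wheat background.

## The problem

Wild relatives of wheat carry valuable resistance genes — for example the
short arm of *Haynaldia villosa* chromosome 4V (4VS), which carries the
yellow-mosaic-virus resistance locus *Wss1*. Introgression lines that move
such an arm into wheat need cheap, co-dominant PCR markers that
distinguish the alien chromatin from its three wheat homoeologs (4AL,
4BS, 4DS). Exon sequence is strongly conserved across Triticeae, but
intron *lengths* diverge fast. An IT marker exploits this: a primer pair
anchored in the two exons flanking an intron amplifies all four genomes
at once, and the product sizes read out each genome's intron length as
separate gel bands.

`intronit` implements the complete design funnel as a library with a thin
CLI:

1. **gene set** — merge two annotation sources into a non-redundant query
   set (local alignment at e-value ≤ 1e-5 and coverage > 80% marks
   redundant genes; all genes of the preferred source are kept);
2. **spliced mapping** — map each transcript onto each of the four arms
   with a seed–chain–extend spliced aligner, recover exon–exon junctions,
   and measure every intron's size per arm;
3. **polymorphism filter** — keep introns whose alien (V) size differs by
   at least 10% from *every* wheat homoeolog: `|V − w| / w ≥ 0.10` for
   each wheat size `w`; one intron per gene (the most divergent) goes
   forward;
4. **primer design** — enumerate exon-anchored primer pairs on the V
   template (length 18–25 nt, optimum 20; Tm 55–65 °C, optimum 60;
   product ≥ intron + 50 bp) and pick the best-scoring pair;
5. **in-silico PCR** — predict every amplicon of each pair on all four
   arms (≤ 2 mismatches per primer, perfect 3′-terminal 5 bases), cluster
   co-migrating product sizes into gel bands, type the band pattern
   (Types I–V) and call a marker **arm-specific** when its V product
   forms a band of its own;
6. **bin mapping** — place specific markers into physical bins from their
   presence/absence across nested translocation lines.

A first-class synthetic-panel generator (`intronit.simulate`) builds
four-genome panels with known gene structures, controlled intron-size
divergence and exact ground truth, so the whole pipeline is testable
without genome downloads.

## Worked example

```bash
python examples/02_polymorphism_filter.py
```

prints, for six published marker rows (intron sizes on A, B, D, V):

```
CINAU687: sizes A=632 B=545 D=687 V=433 -> rel diffs A:0.315 B:0.206 D:0.370 -> targeted (min 0.206)
CINAU648: sizes A=269 B=308 D=281 V=233 -> rel diffs A:0.134 B:0.244 D:0.171 -> targeted (min 0.134)
...
```

Every relative difference clears the 10% threshold, so all six introns
qualify for marker design. Adding the constant 50 bp exonic footprint and
clustering the products predicts the gel pattern
(`examples/03_band_patterns.py`):

```
CINAU687: 4 bands [D@737; A@682; B@595; V@483] type I specific=True
```

— four resolvable bands, one per genome, with the alien product alone in
its band: a co-dominant, 4VS-specific marker.

An end-to-end run on a simulated panel (`examples/01_simulate_and_run.py`)
prints the design funnel (genes in → genes hit on all arms → genes with a
junction → targeted introns → markers designed) and confirms that the
markers called specific coincide exactly with the generator's targeted
families.

The same pipeline runs from the shell:

```bash
intronit simulate --families 50 --seed 42 --outdir panel/
intronit run --arm A=panel/arm_A.fa --arm B=panel/arm_B.fa \
             --arm D=panel/arm_D.fa --arm V=panel/arm_V.fa \
             --annotation panel/genes.gff3 --outdir results/
```

writing `markers.tsv`, `validated.tsv`, `funnel.json` and a checksummed
`manifest.json` (an unchanged rerun is skipped and bitwise-reproducible).

## Limitations

Band typing uses predicted product sizes only; a real 8% polyacrylamide
gel resolves long fragments less sharply than the numeric co-migration
model. Splice-signal validation, protein-guided alignment and multi-copy
genes (beyond best-hit) are out of scope. See `docs/methods.md` for the
models, defaults and design decisions.
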