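"""Synthetic homoeologous genome panels with known gene structures.

The generator emulates the comparative situation the marker pipeline is
built for: a gene family present on four related genome arms (wheat-like
A, B, D and an alien V) whose exons are conserved but whose intron sizes
have diverged.  Each family is drawn from an ancestral gene (random exon
and intron lengths), the wheat arms receive small independent intron-size
jitter, and the alien arm either a large size change (a *targeted*
family, detectable by the >=10% rule) or a change kept safely below the
threshold.  Exons accumulate substitutions per arm at a configurable
rate, sparing the primer-design windows at exon edges so that marker
design and in-silico PCR remain possible; ground truth (realized intron
sizes, targeted status per junction) is recorded for every family and
re-verified against the emitted sequence.

Families are embedded in decoy background built by composition-preserving
shuffling of real family sequence, so spurious seed matches occur only at
quantifiable k-mer chance levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import ConfigError, PipelineConfig
from .filtering import is_targeted_intron
from .io import GeneModel, GenomePanel, spliced_sequence, write_gene_models_gff3
from .mapping import ALIEN_ARM, WHEAT_ARMS, IntronQuartet

ARMS = (*WHEAT_ARMS, ALIEN_ARM)
BASES = np.array(list("ACGT"))

# primer windows spared from substitutions at exon edges facing a junction
SPARED_WINDOW_BP = 90
DECOY_SPACING_BP = 2000


@dataclass
class FamilyParams:
    """Tunable knobs of one synthetic gene family."""

    n_exons_range: Tuple[int, int] = (2, 6)
    exon_len_range: Tuple[int, int] = (90, 220)
    intron_len_range: Tuple[int, int] = (80, 1000)
    wheat_jitter: float = 0.03            # per-arm relative intron-size jitter
    v_divergence_range: Tuple[float, float] = (0.14, 0.40)  # targeted families
    v_null_range: Tuple[float, float] = (0.0, 0.05)         # untargeted families
    substitution_rate: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.02, "B": 0.02, "D": 0.0, "V": 0.02})
    indel_rate: float = 0.0               # per-exon probability of a 1-3 bp indel
    primer_site_conserved: bool = True

    def validate(self) -> None:
        rates = [*self.substitution_rate.values(), self.indel_rate,
                 self.wheat_jitter]
        if any(not (0 <= r <= 0.2) for r in rates):
            raise ConfigError("rates must lie in [0, 0.2]")


@dataclass
class Placement:
    scaffold_id: str
    offset: int
    strand: str
    exon_lengths: List[int]
    intron_lengths: List[int]


@dataclass
class FamilyTruth:
    gene_id: str
    n_exons: int
    exon_lengths: List[int]
    intron_sizes: Dict[str, List[int]]
    substitution_rate: Dict[str, float]
    indel_rate: float
    is_targeted: List[bool]               # per junction
    primer_site_conserved: bool
    segments: Dict[str, str] = field(default_factory=dict, repr=False)
    placements: Dict[str, Placement] = field(default_factory=dict)

    @property
    def any_targeted(self) -> bool:
        return any(self.is_targeted)


@dataclass
class PanelBundle:
    panels: Dict[str, GenomePanel]
    genes: List[GeneModel]
    truth: List[FamilyTruth]

    def write(self, outdir) -> Dict[str, Path]:
        """Emit FASTA x5 (four arms + transcripts), GFF3 and the truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for arm, panel in self.panels.items():
            p = outdir / f"arm_{arm}.fa"
            with open(p, "w") as fh:
                for sid in sorted(panel.scaffolds):
                    fh.write(f">{sid}\n{panel.scaffolds[sid]}\n")
            paths[f"arm_{arm}"] = p
        tx = outdir / "transcripts.fa"
        with open(tx, "w") as fh:
            for g in self.genes:
                fh.write(f">{g.gene_id}\n{g.transcript_seq}\n")
        paths["transcripts"] = tx
        gff = outdir / "genes.gff3"
        write_gene_models_gff3(self.genes, gff)
        paths["annotation"] = gff
        truth = outdir / "truth.tsv"
        with open(truth, "w") as fh:
            cols = ["gene_id", "n_exons", "exon_lengths",
                    *(f"introns_{a}" for a in ARMS), "is_targeted",
                    "primer_site_conserved"]
            fh.write("\t".join(cols) + "\n")
            for t in self.truth:
                fh.write("\t".join([
                    t.gene_id, str(t.n_exons),
                    ",".join(map(str, t.exon_lengths)),
                    *(",".join(map(str, t.intron_sizes[a])) or "-" for a in ARMS),
                    ",".join("1" if x else "0" for x in t.is_targeted) or "-",
                    "1" if t.primer_site_conserved else "0",
                ]) + "\n")
        paths["truth"] = truth
        return paths


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            spared: Sequence[Tuple[int, int]] = ()) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for s, e in spared:
        hit[s:e] = False
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _shuffled(rng: np.random.Generator, seq: str, n: int) -> str:
    """Composition-preserving decoy of length n shuffled from ``seq``."""
    pool = list(seq) * (n // len(seq) + 1)
    arr = np.array(pool[:n])
    rng.shuffle(arr)
    return "".join(arr)


# ---------------------------------------------------------------------------
# family generation


def generate_family(gene_id: str, params: Optional[FamilyParams] = None,
                    targeted: bool = True, intronless: bool = False,
                    seed: int = 0,
                    rng: Optional[np.random.Generator] = None,
                    cfg: Optional[PipelineConfig] = None) -> FamilyTruth:
    """Draw one gene family and realize its genomic segment on every arm.

    ``targeted`` controls whether the alien intron sizes are drawn from
    the divergent range (guaranteeing the >=10% criterion on at least one
    junction) or the null range (guaranteeing failure on all junctions);
    the realized classification is recomputed from the actual sizes and
    redrawn on the rare draw that lands on the wrong side.  Deterministic
    given the seed/rng.
    """
    params = params or FamilyParams()
    params.validate()
    cfg = cfg or PipelineConfig()
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_exons = 1 if intronless else int(rng.integers(*params.n_exons_range,
                                                    endpoint=True))
    exon_lengths = [int(rng.integers(*params.exon_len_range, endpoint=True))
                    for _ in range(n_exons)]
    exons = [_random_seq(rng, n) for n in exon_lengths]
    n_junctions = n_exons - 1
    # canonical GT..AG introns need unambiguous flanks: pin the exon bases
    # abutting each junction so exon/intron boundaries cannot slide
    for i in range(n_exons):
        if i < n_exons - 1:
            exons[i] = exons[i][:-1] + "C"
        if i > 0:
            exons[i] = "A" + exons[i][1:]

    for _attempt in range(50):
        base_sizes = [int(rng.integers(*params.intron_len_range, endpoint=True))
                      for _ in range(n_junctions)]
        intron_sizes: Dict[str, List[int]] = {a: [] for a in ARMS}
        for j, base in enumerate(base_sizes):
            for arm in WHEAT_ARMS:
                jit = rng.uniform(-params.wheat_jitter, params.wheat_jitter)
                intron_sizes[arm].append(max(cfg.min_intron_bp + 10,
                                             round(base * (1 + jit))))
            divergent = targeted and (j == 0 or rng.random() < 0.3)
            lo, hi = (params.v_divergence_range if divergent
                      else params.v_null_range)
            delta = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
            intron_sizes[ALIEN_ARM].append(max(cfg.min_intron_bp + 10,
                                               round(base * (1 + delta))))
        flags = _targeted_flags(gene_id, intron_sizes, n_junctions, cfg)
        if n_junctions == 0 or any(flags) == targeted:
            break
    else:
        raise RuntimeError("could not realize requested targeted status")

    # homologous introns share ancestry: one ancestral core per junction,
    # realized per arm as GT + core-prefix + AG of the required size (the
    # 5' splice region is conserved, the size difference sits 3'-ward)
    ancestral_cores = [_random_seq(rng, max(intron_sizes[a][j] for a in ARMS))
                       for j in range(n_junctions)]
    segments: Dict[str, str] = {}
    for arm in ARMS:
        parts = []
        for i, exon in enumerate(exons):
            spared = []
            if params.primer_site_conserved:
                if i > 0:
                    spared.append((0, SPARED_WINDOW_BP))
                if i < n_exons - 1:
                    spared.append((max(0, len(exon) - SPARED_WINDOW_BP), len(exon)))
            mutated = _mutate(rng, exon, params.substitution_rate.get(arm, 0.0),
                              spared)
            if params.indel_rate > 0 and rng.random() < params.indel_rate:
                mutated = _apply_indel(rng, mutated, spared)
            parts.append(mutated)
            if i < n_junctions:
                size = intron_sizes[arm][i]
                parts.append("GT" + ancestral_cores[i][:size - 4] + "AG")
        segments[arm] = "".join(parts)

    return FamilyTruth(
        gene_id=gene_id, n_exons=n_exons, exon_lengths=exon_lengths,
        intron_sizes=intron_sizes,
        substitution_rate=dict(params.substitution_rate),
        indel_rate=params.indel_rate, is_targeted=flags,
        primer_site_conserved=params.primer_site_conserved,
        segments=segments)


def _targeted_flags(gene_id: str, sizes: Dict[str, List[int]],
                    n_junctions: int, cfg: PipelineConfig) -> List[bool]:
    flags = []
    for j in range(n_junctions):
        quartet = IntronQuartet(gene_id, j + 1,
                                {a: sizes[a][j] for a in ARMS}, 0)
        flags.append(is_targeted_intron(quartet, cfg) is not None)
    return flags


def _apply_indel(rng: np.random.Generator, exon: str,
                 spared: Sequence[Tuple[int, int]]) -> str:
    free = [i for i in range(len(exon))
            if not any(s <= i < e for s, e in spared)]
    if len(free) < 10:
        return exon
    pos = int(free[rng.integers(0, len(free))])
    n = int(rng.integers(1, 4))
    if rng.random() < 0.5:
        return exon[:pos] + _random_seq(rng, n) + exon[pos:]
    return exon[:pos] + exon[pos + n:]


# ---------------------------------------------------------------------------
# panel generation


def generate_panel(n_families: int, fraction_targeted: float = 0.4,
                   fraction_intronless: float = 0.1, seed: int = 42,
                   params: Optional[FamilyParams] = None,
                   families_per_scaffold: int = 8,
                   cfg: Optional[PipelineConfig] = None) -> PanelBundle:
    """Generate a four-arm panel of gene families with exact composition.

    Exactly ``round(n * fraction_targeted)`` families carry a targeted
    intron and ``round(n * fraction_intronless)`` are single-exon genes;
    the remainder have introns but fail the polymorphism criterion
    everywhere.  Families are embedded in shuffled decoy background with
    at least 2 kb spacing; gene models are annotated on the D arm (the
    source genome) and transcripts are the spliced D sequence.
    """
    if fraction_targeted + fraction_intronless > 1:
        raise ConfigError("fractions sum above 1")
    params = params or FamilyParams()
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    n_targeted = round(n_families * fraction_targeted)
    n_intronless = round(n_families * fraction_intronless)
    kinds = (["targeted"] * n_targeted + ["intronless"] * n_intronless
             + ["untargeted"] * (n_families - n_targeted - n_intronless))
    order = rng.permutation(len(kinds))
    truths: List[FamilyTruth] = []
    for i, ki in enumerate(order):
        kind = kinds[ki]
        truths.append(generate_family(
            f"FAM{i + 1:04d}", params, targeted=(kind == "targeted"),
            intronless=(kind == "intronless"), rng=rng, cfg=cfg))

    scaffolds: Dict[str, Dict[str, str]] = {a: {} for a in ARMS}
    genes: List[GeneModel] = []
    for arm in ARMS:
        chunks = [truths[i:i + families_per_scaffold]
                  for i in range(0, len(truths), families_per_scaffold)]
        for ci, chunk in enumerate(chunks):
            sid = f"{arm}_scaf{ci + 1:03d}"
            parts: List[str] = []
            pos = 0
            for t in chunk:
                seg = t.segments[arm]
                strand = "+" if rng.random() < 0.7 else "-"
                spacer = _shuffled(rng, seg, DECOY_SPACING_BP)
                parts.append(spacer)
                pos += len(spacer)
                placed = seg if strand == "+" else _revcomp(seg)
                t.placements[arm] = Placement(
                    sid, pos, strand,
                    _arm_exon_lengths(t, arm), list(t.intron_sizes[arm]))
                parts.append(placed)
                if arm == "D":
                    genes.append(_gene_model(t, sid, pos, strand))
                pos += len(placed)
            parts.append(_shuffled(rng, chunk[-1].segments[arm],
                                   DECOY_SPACING_BP))
            scaffolds[arm][sid] = "".join(parts)

    panels = {a: GenomePanel(a, scaffolds[a]) for a in ARMS}
    return PanelBundle(panels=panels, genes=genes, truth=truths)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _arm_exon_lengths(t: FamilyTruth, arm: str) -> List[int]:
    # exon lengths can differ per arm once indels are simulated; recover
    # them from the segment and the intron sizes
    total_introns = sum(t.intron_sizes[arm])
    if t.indel_rate == 0:
        return list(t.exon_lengths)
    # distribute the residual naively; placements are only used for
    # verification on indel-free panels
    residual = len(t.segments[arm]) - total_introns
    lens = list(t.exon_lengths)
    lens[-1] += residual - sum(t.exon_lengths)
    return lens


def _gene_model(t: FamilyTruth, scaffold_id: str, offset: int,
                strand: str) -> GeneModel:
    seg = t.segments["D"]
    lens = _arm_exon_lengths(t, "D")
    exons_fwd = []
    cur = 0
    for i, L in enumerate(lens):
        exons_fwd.append((cur, cur + L))
        if i < len(t.intron_sizes["D"]):
            cur += L + t.intron_sizes["D"][i]
        else:
            cur += L
    if strand == "+":
        exons = [(offset + s, offset + e) for s, e in exons_fwd]
    else:
        n = len(seg)
        exons = sorted((offset + n - e, offset + n - s) for s, e in exons_fwd)
    tx_parts = [seg[s:e] for s, e in exons_fwd]
    tx = "".join(tx_parts)
    return GeneModel(t.gene_id, "synthetic", scaffold_id, strand, exons, tx,
                     start_pos=exons[0][0])
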