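"""Exon-anchored primer design around a targeted intron.

Primers are designed on the alien (V) genome sequence, in the two exons
flanking the targeted intron, under the marker-design criteria: length
18-25 nt (optimum 20), Tm 55-65 degC (optimum 60), GC between 30% and
70%, no mononucleotide run longer than four, no ambiguous base, and a
self/cross complementarity cap as a cheap hairpin/dimer screen.  The
amplified fragment must exceed the targeted intron by at least ~50 bp
(primers plus retained exon flanks), and because exon sequence is assumed
conserved across arms, the predicted product on any arm is the shared
exonic footprint plus that arm's intron size.

Melting temperatures come from nearest-neighbour thermodynamics
(SantaLucia unified parameters; 50 mM monovalent salt, 250 nM oligo),
with the Wallace rule available as a quick fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Seq import reverse_complement
from Bio.SeqUtils import MeltingTemp as _mt

from .config import PipelineConfig
from .filtering import TargetedIntron
from .mapping import ALIEN_ARM, SplicedHit

# how far from the junction a primer 3' end may sit (limits enumeration and
# keeps products close to the intron size)
MAX_ANCHOR_OFFSET = 60
MAX_SINGLES = 15  # per side, best-scoring singles paired exhaustively

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass
class PrimerPair:
    """A forward/reverse primer pair flanking one intron.

    The reverse primer is given 5'->3' on the antisense strand.
    ``anchor_left``/``anchor_right`` are the distances (bp) between each
    primer's 3' end and the exon-exon junction.
    """

    forward_seq: str
    reverse_seq: str
    tm_f: float
    tm_r: float
    anchor_left: int
    anchor_right: int
    pair_score: float

    @property
    def footprint(self) -> int:
        """Total exonic bases contributed to the product by both sides."""
        return (len(self.forward_seq) + self.anchor_left
                + len(self.reverse_seq) + self.anchor_right)


@dataclass
class MarkerCandidate:
    marker_id: str
    gene_id: str
    junction_index: int
    primer_pair: PrimerPair
    intron_sizes: Dict[str, int]
    product_sizes: Dict[str, int] = field(default_factory=dict)
    type_label: Optional[str] = None
    is_specific: Optional[bool] = None


def melting_temperature(primer: str, cfg: Optional[PipelineConfig] = None,
                        method: str = "nn") -> float:
    """Oligo melting temperature in degC.

    ``nn`` uses nearest-neighbour thermodynamics at 50 mM Na+ and 250 nM
    oligo; ``wallace`` the 2/4-degree rule.  Ambiguous bases are refused.
    """
    primer = primer.upper()
    if len(primer) < 8:
        raise ValueError("primer too short for a meaningful Tm")
    if set(primer) - set("ACGT"):
        raise ValueError(f"ambiguous base in primer {primer!r}")
    if method == "wallace":
        return float(_mt.Tm_Wallace(primer))
    return float(_mt.Tm_NN(primer, Na=50, dnac1=250, dnac2=0))


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _max_complementarity(a: str, b: str) -> int:
    """Longest contiguous complementary stretch over all ungapped offsets.

    ``a`` is read 5'->3' and ``b`` 3'->5' (i.e. b reversed), the geometry
    of two annealed oligos; used as a self-dimer/hairpin screen with
    ``a == b`` and as a cross-dimer screen otherwise.
    """
    import numpy as np

    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    # complement of b, reversed, so equality with a means a complementary pair
    cb = np.frombuffer(
        b.translate(str.maketrans("ACGT", "TGCA"))[::-1].encode(), dtype=np.uint8)
    eq = aa[:, None] == cb[None, :]
    # longest diagonal run of equality = longest annealed stretch
    best = 0
    prev = np.zeros(len(cb) + 1, dtype=np.int16)
    for row in eq:
        cur = np.zeros(len(cb) + 1, dtype=np.int16)
        cur[1:] = (prev[:-1] + 1) * row
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best


def _single_ok(seq: str, cfg: PipelineConfig) -> Optional[float]:
    """Return the Tm when a primer passes all single-primer filters."""
    if set(seq) - set("ACGT"):
        return None
    if not (cfg.gc_min <= _gc(seq) <= cfg.gc_max):
        return None
    if _max_run(seq) > cfg.max_mononucleotide_run:
        return None
    if _max_complementarity(seq, seq) > cfg.max_complementarity:
        return None
    tm = melting_temperature(seq, cfg)
    if not (cfg.tm_min <= tm <= cfg.tm_max):
        return None
    return tm


def _enumerate_side(exon: str, side: str, cfg: PipelineConfig
                    ) -> List[Tuple[float, str, float, int]]:
    """Valid single primers on one side: (score, seq, tm, anchor_offset).

    For the left exon primers run on the sense strand ending near the
    exon's 3' edge; for the right exon they are reverse complements of
    windows starting near its 5' edge.
    """
    out = []
    n = len(exon)
    for length in range(cfg.primer_len_min, cfg.primer_len_max + 1):
        if length > n:
            continue
        for offset in range(0, min(MAX_ANCHOR_OFFSET, n - length) + 1):
            if side == "left":
                window = exon[n - length - offset:n - offset]
                seq = window
            else:
                window = exon[offset:offset + length]
                seq = reverse_complement(window)
            tm = _single_ok(seq, cfg)
            if tm is None:
                continue
            score = abs(tm - cfg.tm_opt) + abs(length - cfg.primer_len_opt)
            out.append((score, seq, tm, offset))
    out.sort(key=lambda t: (t[0], t[3], t[1]))
    return out


def enumerate_primer_candidates(left_exon: str, right_exon: str,
                                cfg: Optional[PipelineConfig] = None
                                ) -> List[PrimerPair]:
    """All acceptable primer pairs on the two flanking exons, best first.

    Each side is enumerated independently under the single-primer filters;
    the best singles are then paired, adding a Tm-difference penalty and a
    forward/reverse cross-complementarity screen.
    """
    cfg = cfg or PipelineConfig()
    left_exon, right_exon = left_exon.upper(), right_exon.upper()
    if len(left_exon) < cfg.primer_len_min or len(right_exon) < cfg.primer_len_min:
        return []
    fwd = _enumerate_side(left_exon, "left", cfg)[:MAX_SINGLES]
    rev = _enumerate_side(right_exon, "right", cfg)[:MAX_SINGLES]
    pairs = []
    for fs, fseq, ftm, foff in fwd:
        for rs, rseq, rtm, roff in rev:
            if _max_complementarity(fseq, rseq) > cfg.max_complementarity:
                continue
            score = fs + rs + abs(ftm - rtm)
            pairs.append(PrimerPair(fseq, rseq, ftm, rtm, foff, roff, score))
    pairs.sort(key=lambda p: (p.pair_score, p.anchor_left, p.anchor_right,
                              p.forward_seq))
    return pairs


def pick_primer_pair(candidates: Sequence[PrimerPair], target: TargetedIntron,
                     cfg: Optional[PipelineConfig] = None
                     ) -> Optional[MarkerCandidate]:
    """Best candidate whose V product exceeds the intron by the overhead.

    Product sizes per arm are the shared exonic footprint plus that arm's
    intron size.  Returns None when no candidate qualifies (the gene is
    counted as a design failure).
    """
    cfg = cfg or PipelineConfig()
    intron_v = target.quartet.sizes[ALIEN_ARM]
    optimum = intron_v + cfg.product_overhead_bp \
        + 2 * (cfg.primer_len_opt - cfg.primer_len_min)
    best, best_key = None, None
    for pair in candidates:
        product_v = pair.footprint + intron_v
        if product_v < intron_v + cfg.product_overhead_bp:
            continue
        key = (pair.pair_score + 0.05 * abs(product_v - optimum),
               pair.anchor_left, pair.anchor_right, pair.forward_seq)
        if best_key is None or key < best_key:
            best_key, best = key, pair
    if best is None:
        return None
    products = {arm: best.footprint + size
                for arm, size in target.quartet.sizes.items()}
    return MarkerCandidate(
        marker_id="", gene_id=target.gene_id,
        junction_index=target.junction_index, primer_pair=best,
        intron_sizes=dict(target.quartet.sizes), product_sizes=products)


def flanking_exon_sequences(hit: SplicedHit, junction_index: int,
                            scaffold_seq: str) -> Tuple[str, str]:
    """Sense-orientation sequences of the two exons flanking a junction."""
    seq = scaffold_seq if hit.strand == "+" else reverse_complement(scaffold_seq)
    left = hit.blocks[junction_index - 1]
    right = hit.blocks[junction_index]
    return (seq[left.target_interval[0]:left.target_interval[1]],
            seq[right.target_interval[0]:right.target_interval[1]])


def design_all(targets: Sequence[TargetedIntron],
               v_hits: Dict[str, SplicedHit], v_scaffolds: Dict[str, str],
               cfg: Optional[PipelineConfig] = None
               ) -> Tuple[List[MarkerCandidate], List[str]]:
    """Design one marker per selected targeted intron.

    ``v_hits`` maps gene_id to the gene's spliced hit on the V arm and
    ``v_scaffolds`` scaffold_id to sequence.  Genes where no primer pair
    satisfies the constraints are returned in the failure list.  Marker
    ids are assigned deterministically (``ITM`` + zero-padded ordinal in
    gene order).
    """
    cfg = cfg or PipelineConfig()
    markers: List[MarkerCandidate] = []
    failures: List[str] = []
    for target in sorted(targets, key=lambda t: (t.gene_id, t.junction_index)):
        hit = v_hits.get(target.gene_id)
        if hit is None:
            failures.append(target.gene_id)
            continue
        left, right = flanking_exon_sequences(hit, target.junction_index,
                                              v_scaffolds[hit.scaffold_id])
        candidates = enumerate_primer_candidates(left, right, cfg)
        marker = pick_primer_pair(candidates, target, cfg)
        if marker is None:
            failures.append(target.gene_id)
        else:
            markers.append(marker)
    for i, m in enumerate(markers, start=1):
        m.marker_id = f"ITM{i:04d}"
    return markers, failures
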