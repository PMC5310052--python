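"""Building the non-redundant query gene set.

Two annotation sources describe overlapping gene complements of the same
chromosome arm (here an *Ae. tauschii*-like source and a Chinese
Spring-like source).  Genes from the preferred source are all kept;
genes from the other source that are redundant with a preferred gene —
local alignment at e-value <= 1e-5 covering > 80% of the transcript —
are dropped.  A positional window filter restricts the preferred source
to the arm of interest (e.g. the first 60 Mb of a pseudomolecule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import Align
from scipy.optimize import brentq

from .config import ConfigError, PipelineConfig
from .io import GeneModel

logger = logging.getLogger("intronit")

# local alignment scoring used for redundancy detection
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -2.0, -5.0, -2.0
KA_K = 0.1  # Karlin-Altschul K for this scheme (order-of-magnitude constant)


def _karlin_lambda() -> float:
    """Ungapped Karlin-Altschul lambda for +1/-2 scoring, uniform bases."""
    f = lambda lam: 0.25 * math.exp(lam * MATCH) + 0.75 * math.exp(lam * MISMATCH) - 1.0
    return brentq(f, 1e-6, 10.0)


_LAMBDA = _karlin_lambda()


def alignment_evalue(score: float, m: int, n: int) -> float:
    """E-value of a local alignment score in an m x n search space."""
    return KA_K * m * n * math.exp(-_LAMBDA * score)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    return al


@dataclass
class RedundantPair:
    a_id: str
    b_id: str
    identity: float
    coverage: float
    evalue: float


@dataclass
class MergedGeneSet:
    genes: List[GeneModel]
    provenance: Dict[str, dict] = field(default_factory=dict)
    removed: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)


def window_filter(genes: Sequence[GeneModel], max_position: int) -> List[GeneModel]:
    """Keep genes whose pseudomolecule start lies before ``max_position``.

    Genes without positional metadata pass through unchanged (with a
    warning): the filter degrades to a no-op when positions are unknown.
    """
    if any(g.start_pos is None for g in genes):
        logger.warning("window_filter: genes lack pseudomolecule positions; no-op")
        return list(genes)
    return [g for g in genes if g.start_pos < max_position]


def find_redundant_pairs(set_a: Sequence[GeneModel], set_b: Sequence[GeneModel],
                         cfg: Optional[PipelineConfig] = None,
                         ) -> List[RedundantPair]:
    """Report transcript pairs that meet the redundancy thresholds.

    A pair is redundant when local alignment of the two transcripts has
    e-value <= ``dedup_evalue_cutoff`` and the aligned region covers more
    than ``dedup_coverage_cutoff`` of the reference transcript (the
    shorter one by default).  Symmetric in its two inputs.
    """
    cfg = cfg or PipelineConfig()
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    aligner = _aligner()
    pairs: List[RedundantPair] = []
    for ga in set_a:
        for gb in set_b:
            pair = _score_pair(aligner, ga, gb, cfg)
            if pair is not None:
                pairs.append(pair)
    return pairs


def _score_pair(aligner, ga: GeneModel, gb: GeneModel,
                cfg: PipelineConfig) -> Optional[RedundantPair]:
    sa, sb = ga.transcript_seq, gb.transcript_seq
    score = aligner.score(sa, sb)
    ev = alignment_evalue(score, len(sa), len(sb))
    if ev > cfg.dedup_evalue_cutoff:
        return None
    aln = next(iter(aligner.align(sa, sb)))
    qspan = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
    sspan = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
    if cfg.dedup_coverage_denominator == "shorter":
        cov = (qspan if len(sa) <= len(sb) else sspan) / min(len(sa), len(sb))
    else:
        cov = (qspan if len(sa) >= len(sb) else sspan) / max(len(sa), len(sb))
    if cov <= cfg.dedup_coverage_cutoff:
        return None
    matches = _count_matches(aln)
    identity = matches / max(qspan, sspan)
    return RedundantPair(ga.gene_id, gb.gene_id, identity, cov, ev)


def _count_matches(aln) -> int:
    a, b = aln.target, aln.query
    n = 0
    for (qs, qe), (ss, se) in zip(aln.aligned[0], aln.aligned[1]):
        n += sum(1 for x, y in zip(a[qs:qe], b[ss:se]) if x == y)
    return n


def redundant_pairs_from_table(alignments: pd.DataFrame,
                               cfg: Optional[PipelineConfig] = None,
                               ) -> List[RedundantPair]:
    """Adapter: derive redundant pairs from a precomputed 12-column table.

    Coverage is aggregated per (query, subject) pair as the fraction of the
    query covered by the longest HSP; callers providing transcript lengths
    via ``qlen``/``slen`` extra columns get exact coverage, otherwise the
    HSP length over the larger of qend/send serves as a lower bound.
    """
    cfg = cfg or PipelineConfig()
    pairs = []
    for (qid, sid), grp in alignments.groupby(["qid", "sid"], sort=True):
        best = grp.loc[grp["bitscore"].idxmax()]
        if best["evalue"] > cfg.dedup_evalue_cutoff:
            continue
        if "qlen" in grp.columns:
            denom = (min(best["qlen"], best["slen"])
                     if cfg.dedup_coverage_denominator == "shorter"
                     else max(best["qlen"], best["slen"]))
        else:
            denom = max(best["qend"], abs(best["send"] - best["sstart"]))
        cov = best["length"] / denom
        if cov > cfg.dedup_coverage_cutoff:
            pairs.append(RedundantPair(str(qid), str(sid),
                                       best["pident"] / 100.0, cov, best["evalue"]))
    return pairs


def merge_gene_sets(set_a: Sequence[GeneModel], set_b: Sequence[GeneModel],
                    redundant: Sequence[RedundantPair],
                    prefer: str = "a") -> MergedGeneSet:
    """Merge two gene sets, dropping redundant members of the other set.

    All genes of the preferred set are kept; genes of the other set that
    appear in any redundant pair are removed, recording which partner made
    them redundant.
    """
    if prefer not in ("a", "b"):
        raise ConfigError(f"prefer must be 'a' or 'b', got {prefer!r}")
    if prefer == "b":
        set_a, set_b = set_b, set_a
        redundant = [RedundantPair(p.b_id, p.a_id, p.identity, p.coverage, p.evalue)
                     for p in redundant]
    a_ids = {g.gene_id for g in set_a}
    b_ids = {g.gene_id for g in set_b}
    partner: Dict[str, str] = {}
    for p in redundant:
        if p.a_id not in a_ids or p.b_id not in b_ids:
            raise ValueError(f"redundant pair ({p.a_id}, {p.b_id}) references "
                             "unknown gene ids")
        partner.setdefault(p.b_id, p.a_id)
    genes: List[GeneModel] = list(set_a)
    provenance = {g.gene_id: {"kept_reason": "preferred_source",
                              "redundant_partner": None} for g in set_a}
    removed = []
    for g in set_b:
        if g.gene_id in partner:
            removed.append(g.gene_id)
        else:
            genes.append(g)
            provenance[g.gene_id] = {"kept_reason": "unique", "redundant_partner": None}
    for b_id, a_id in partner.items():
        provenance[b_id] = {"kept_reason": "removed", "redundant_partner": a_id}
    return MergedGeneSet(genes=genes, provenance=provenance, removed=removed)
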