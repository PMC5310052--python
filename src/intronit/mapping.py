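"""Spliced transcript-to-genome mapping and intron-size inference.

Each transcript is mapped onto each genomic arm with a seed-chain-extend
spliced aligner: exact k-mer seeds are merged into maximal exact anchors,
anchors are chained collinearly (query and target order agree), and the
chain is segmented into exon blocks wherever the target sequence jumps by
at least the minimum credible intron length.  The unseeded query region at
each junction is split between the two flanking exons at the position
maximising base matches, which pins the exon-exon junction; the genomic
gap between consecutive blocks is the intron size.

Intron sizes are then compared across arms: junctions are matched by their
transcript coordinate, and a junction recovered on all four arms yields an
:class:`IntronQuartet` — one homologous intron with four sizes — the unit
on which the length-polymorphism filter operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Seq import reverse_complement

from .config import PipelineConfig
from .io import GeneModel, GenomePanel

WHEAT_ARMS = ("A", "B", "D")
ALIEN_ARM = "V"

# anchors with more scaffold hits than this are treated as repeats
MAX_KMER_HITS = 50
MAX_QUERY_GAP = 200  # bp of unseeded transcript tolerated inside a chain


class MalformedChainError(ValueError):
    """Raised when block trimming empties an exon block."""


@dataclass
class ExonBlock:
    """One collinear exon alignment block.

    Intervals are 0-based half-open; ``target_interval`` is expressed on
    the aligned orientation of the scaffold (the reverse complement when
    ``strand`` is ``-``).
    """

    query_interval: Tuple[int, int]
    target_interval: Tuple[int, int]
    identity: float
    strand: str


@dataclass
class Chain:
    """A candidate chain of exon blocks on one scaffold/strand."""

    scaffold_id: str
    strand: str
    blocks: List[ExonBlock]
    score: int          # total anchored bases
    query_coverage: float

    @property
    def query_span(self) -> int:
        return self.blocks[-1].query_interval[1] - self.blocks[0].query_interval[0]


@dataclass
class SplicedHit:
    """Best spliced alignment of one gene on one arm."""

    gene_id: str
    arm_id: str
    scaffold_id: str
    strand: str
    blocks: List[ExonBlock]
    introns: List[Tuple[int, int, int]] = field(default_factory=list)
    # (junction_index, target_gap_bp, junction_query_pos)
    score: int = 0
    query_coverage: float = 0.0


@dataclass
class IntronQuartet:
    """One homologous intron with its size on every arm."""

    gene_id: str
    junction_index: int
    sizes: Dict[str, int]
    junction_query_pos: int


# ---------------------------------------------------------------------------
# seeding


import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _hash_kmers(seq: str, k: int) -> np.ndarray:
    """2-bit pack every k-mer into an int64 hash; -1 where ambiguous."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    hashes = windows.astype(np.int64) @ powers
    hashes[(windows == 255).any(axis=1)] = -1
    return hashes


def _kmer_index(seq: str, k: int) -> Dict[int, np.ndarray]:
    """Map k-mer hash -> sorted array of start positions."""
    hashes = _hash_kmers(seq, k)
    order = np.argsort(hashes, kind="stable")
    sorted_h = hashes[order]
    boundaries = np.flatnonzero(np.diff(sorted_h)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(sorted_h)]))
    index: Dict[int, np.ndarray] = {}
    for s, e in zip(starts, ends):
        h = int(sorted_h[s])
        if h >= 0:
            index[h] = np.sort(order[s:e])
    return index


def _panel_index(panel: GenomePanel, scaffold_id: str, strand: str, k: int):
    """Cached k-mer index of a scaffold (or its reverse complement)."""
    key = (scaffold_id, strand, k)
    if key not in panel._indexes:
        seq = panel.scaffolds[scaffold_id]
        if strand == "-":
            seq = reverse_complement(seq)
        panel._indexes[key] = (_kmer_index(seq, k), seq)
    return panel._indexes[key]


def _anchors(transcript: str, index: Dict[int, np.ndarray], k: int
             ) -> List[Tuple[int, int, int]]:
    """Maximal exact match anchors (qstart, tstart, length) via seed merging."""
    by_diag: Dict[int, List[int]] = {}
    for q, h in enumerate(_hash_kmers(transcript, k)):
        hits = index.get(int(h)) if h >= 0 else None
        if hits is None or len(hits) > MAX_KMER_HITS:
            continue
        for t in hits:
            by_diag.setdefault(int(t) - q, []).append(q)
    anchors = []
    for diag, qs in by_diag.items():
        qs.sort()
        start = prev = qs[0]
        for q in qs[1:]:
            if q == prev + 1:
                prev = q
            else:
                anchors.append((start, start + diag, prev - start + k))
                start = prev = q
        anchors.append((start, start + diag, prev - start + k))
    anchors.sort()
    return anchors


# ---------------------------------------------------------------------------
# chaining


def _chain_anchors(anchors: List[Tuple[int, int, int]], cfg: PipelineConfig
                   ) -> List[List[Tuple[int, int, int]]]:
    """Highest-scoring collinear chain (plus the raw DP for ties)."""
    if not anchors:
        return []
    max_tgap = cfg.epcr_max_product_bp * 5
    n = len(anchors)
    score = [a[2] for a in anchors]
    back = [-1] * n
    for i in range(n):
        qi, ti, li = anchors[i]
        for j in range(i):
            qj, tj, lj = anchors[j]
            if qj >= qi or tj >= ti:
                continue
            qgap = qi - (qj + lj)
            tgap = ti - (tj + lj)
            if qgap < -lj // 2 or qgap > MAX_QUERY_GAP:
                continue
            if tgap < qgap - 30 or tgap > max_tgap:
                continue
            cand = score[j] + li
            if cand > score[i]:
                score[i] = cand
                back[i] = j
    best = max(range(n), key=lambda i: (score[i], -anchors[i][0]))
    chain = []
    i = best
    while i != -1:
        chain.append(anchors[i])
        i = back[i]
    chain.reverse()
    return [chain]


def _matches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x == y and x != "N")


def _segment_chain(chain: List[Tuple[int, int, int]], transcript: str,
                   target: str, cfg: PipelineConfig) -> List[ExonBlock]:
    """Split a chain into exon blocks at putative introns and refine junctions."""
    # group anchors: a new block starts where the target jumps by >= min intron
    groups: List[List[Tuple[int, int, int]]] = [[chain[0]]]
    for prev, cur in zip(chain, chain[1:]):
        qgap = cur[0] - (prev[0] + prev[2])
        tgap = cur[1] - (prev[1] + prev[2])
        if tgap - qgap >= cfg.min_intron_bp:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    raw = []
    for grp in groups:
        qs, ts = grp[0][0], grp[0][1]
        qe = grp[-1][0] + grp[-1][2]
        te = grp[-1][1] + grp[-1][2]
        anchored = sum(a[2] for a in grp)
        raw.append([qs, qe, ts, te, anchored])

    # extend the outer boundaries to the transcript ends (exon conservation)
    first, last = raw[0], raw[-1]
    lead = min(first[0], first[2])
    first[0] -= lead
    first[2] -= lead
    tail = min(len(transcript) - last[1], len(target) - last[3])
    last[1] += tail
    last[3] += tail

    # refine each junction: split the unseeded query gap between the two
    # flanking exons at the position maximising base matches
    for prev, cur in zip(raw, raw[1:]):
        if cur[0] < prev[1]:  # query overlap from ambiguous anchors: trim prev
            d = prev[1] - cur[0]
            prev[1] -= d
            prev[3] -= d
            if prev[1] <= prev[0]:
                raise MalformedChainError("block emptied while trimming overlap")
        g = cur[0] - prev[1]
        if g > 0:
            region = transcript[prev[1]:cur[0]]
            left_t = target[prev[3]:prev[3] + g]
            right_t = target[cur[2] - g:cur[2]]
            best_s, best_m = 0, -1
            for s in range(g + 1):
                m = _matches(region[:s], left_t[:s]) + _matches(region[s:], right_t[s - g:] if s < g else "")
                if m > best_m:
                    best_m, best_s = m, s
            prev[1] += best_s
            prev[3] += best_s
            cur[0] -= g - best_s
            cur[2] -= g - best_s

    blocks = []
    for qs, qe, ts, te, anchored in raw:
        ident = min(1.0, anchored / max(1, qe - qs))
        blocks.append(ExonBlock((qs, qe), (ts, te), ident, "+"))
    return blocks


# ---------------------------------------------------------------------------
# public operations


def find_exon_blocks(transcript: str, scaffold: str,
                     cfg: Optional[PipelineConfig] = None) -> List[Chain]:
    """Candidate exon-block chains of a transcript on one scaffold.

    Returns the highest-scoring chain per strand (empty list when the
    transcript is too short to seed or nothing chains).
    """
    cfg = cfg or PipelineConfig()
    if len(transcript) < 2 * cfg.seed_k:
        return []
    chains = []
    for strand in "+-":
        target = scaffold if strand == "+" else reverse_complement(scaffold)
        index = _kmer_index(target, cfg.seed_k)
        anchors = _anchors(transcript.upper(), index, cfg.seed_k)
        for chain in _chain_anchors(anchors, cfg):
            blocks = _segment_chain(chain, transcript.upper(), target, cfg)
            for b in blocks:
                b.strand = strand
            score = sum(a[2] for a in chain)
            qcov = sum(b.query_interval[1] - b.query_interval[0] for b in blocks) \
                / len(transcript)
            chains.append(Chain("", strand, blocks, score, min(1.0, qcov)))
    chains.sort(key=lambda c: (-c.score, -c.query_coverage, c.strand))
    return chains


def infer_introns(hit: SplicedHit, cfg: Optional[PipelineConfig] = None
                  ) -> List[Tuple[int, int]]:
    """Derive intron sizes from adjacent exon blocks of a spliced hit.

    The genomic gap between consecutive blocks is the intron; gaps shorter
    than ``min_intron_bp`` are alignment artifacts and the flanking blocks
    are fused.  Overlapping blocks are trimmed before the gap is measured.
    Updates ``hit.blocks``/``hit.introns`` in place and returns
    ``[(junction_index, gap_bp), ...]``.
    """
    cfg = cfg or PipelineConfig()
    blocks = [ExonBlock(b.query_interval, b.target_interval, b.identity, b.strand)
              for b in hit.blocks]
    fused: List[ExonBlock] = [blocks[0]]
    for cur in blocks[1:]:
        prev = fused[-1]
        qs, qe = cur.query_interval
        ts, te = cur.target_interval
        pqs, pqe = prev.query_interval
        pts, pte = prev.target_interval
        if ts < pte:  # overlapping target blocks: trim current start
            d = pte - ts
            ts += d
            qs += d
            if qs >= qe:
                raise MalformedChainError("block emptied while trimming overlap")
        gap = ts - pte
        if gap < cfg.min_intron_bp:
            fused[-1] = ExonBlock((pqs, max(qe, pqe)), (pts, max(te, pte)),
                                  min(prev.identity, cur.identity), prev.strand)
        else:
            fused.append(ExonBlock((qs, qe), (ts, te), cur.identity, cur.strand))
    introns = []
    for idx, (prev, cur) in enumerate(zip(fused, fused[1:]), start=1):
        gap = cur.target_interval[0] - prev.target_interval[1]
        introns.append((idx, gap, prev.query_interval[1]))
    hit.blocks = fused
    hit.introns = introns
    return [(i, g) for i, g, _ in introns]


def map_gene_to_panel(gene: GeneModel, panels: Dict[str, GenomePanel],
                      cfg: Optional[PipelineConfig] = None
                      ) -> Dict[str, SplicedHit]:
    """Best spliced hit of one gene on each arm of the panel.

    Per arm the best chain across scaffolds and strands is retained
    (highest anchored score; ties broken by query coverage, then
    lexicographic scaffold id, then strand).  Arms where no chain covers
    at least ``min_query_coverage`` of the transcript are absent.
    """
    cfg = cfg or PipelineConfig()
    tx = gene.transcript_seq.upper()
    hits: Dict[str, SplicedHit] = {}
    for arm_id, panel in panels.items():
        best_key, best = None, None
        for sid in sorted(panel.scaffolds):
            for strand in "+-":
                index, target = _panel_index(panel, sid, strand, cfg.seed_k)
                anchors = _anchors(tx, index, cfg.seed_k)
                if not anchors:
                    continue
                for chain in _chain_anchors(anchors, cfg):
                    score = sum(a[2] for a in chain)
                    try:
                        blocks = _segment_chain(chain, tx, target, cfg)
                    except MalformedChainError:
                        continue
                    qcov = min(1.0, sum(
                        b.query_interval[1] - b.query_interval[0]
                        for b in blocks) / len(tx))
                    key = (-score, -qcov, sid, strand)
                    if best_key is None or key < best_key:
                        best_key = key
                        best = SplicedHit(gene.gene_id, arm_id, sid, strand,
                                          blocks, score=score, query_coverage=qcov)
        if best is not None and best.query_coverage >= cfg.min_query_coverage:
            infer_introns(best, cfg)
            hits[arm_id] = best
    return hits


def match_homologous_introns(hits: Dict[str, SplicedHit],
                             tolerance_bp: int = 12) -> List[IntronQuartet]:
    """Match introns across arms by their transcript-junction coordinate.

    The alien (V) hit anchors the matching: each of its junctions is looked
    up in every wheat arm within ``tolerance_bp`` of transcript position;
    only junctions recovered on all four arms yield a quartet.
    """
    if ALIEN_ARM not in hits or not hits[ALIEN_ARM].introns:
        return []
    quartets = []
    v_hit = hits[ALIEN_ARM]
    for idx, v_gap, v_pos in v_hit.introns:
        sizes = {ALIEN_ARM: v_gap}
        pos_ok = True
        for arm in WHEAT_ARMS:
            hit = hits.get(arm)
            if hit is None or not hit.introns:
                pos_ok = False
                break
            nearest = min(hit.introns, key=lambda it: abs(it[2] - v_pos))
            if abs(nearest[2] - v_pos) > tolerance_bp:
                pos_ok = False
                break
            sizes[arm] = nearest[1]
        if pos_ok:
            quartets.append(IntronQuartet(v_hit.gene_id, idx, sizes, v_pos))
    return quartets
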