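"""The intron-length-polymorphism filter and the pipeline funnel report.

A homologous intron qualifies as a *targeted intron* when its alien-genome
(V) size differs by at least 10% from the size of the same intron in every
wheat homoeolog (A, B and D) simultaneously.  The relative difference is
wheat-referenced by default: |V - w| / w for each wheat size w.  One
targeted intron per gene is then selected for marker design ("one genome
marker" rule), preferring the intron whose *smallest* wheat divergence is
largest — the most robustly polymorphic one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .config import PipelineConfig
from .mapping import ALIEN_ARM, WHEAT_ARMS, IntronQuartet


@dataclass
class TargetedIntron:
    quartet: IntronQuartet
    rel_diffs: Dict[str, float]
    min_rel_diff: float

    @property
    def gene_id(self) -> str:
        return self.quartet.gene_id

    @property
    def junction_index(self) -> int:
        return self.quartet.junction_index


@dataclass
class FunnelReport:
    """Stage-by-stage counts of the marker-development funnel."""

    n_genes_input: int = 0
    n_genes_hit_all_arms: int = 0
    n_genes_with_junction: int = 0
    n_introns_total: int = 0
    mean_introns_per_gene: Optional[float] = None
    n_targeted_introns: int = 0
    n_genes_with_target: int = 0
    n_markers_designed: int = 0

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        if d["mean_introns_per_gene"] is None:
            d["mean_introns_per_gene"] = "NA"
        return d


def relative_difference(v_size: int, wheat_size: int) -> float:
    """Wheat-referenced relative intron-size difference |v - w| / w."""
    if v_size <= 0 or wheat_size <= 0:
        raise ValueError("intron sizes must be positive")
    return abs(v_size - wheat_size) / wheat_size


def _rel_diff(v: int, w: int, sizes: Dict[str, int], mode: str) -> float:
    if mode == "wheat":
        return relative_difference(v, w)
    denom = max(v, w) if mode == "max" else (v + w) / 2.0
    return abs(v - w) / denom


def is_targeted_intron(quartet: IntronQuartet,
                       cfg: Optional[PipelineConfig] = None
                       ) -> Optional[TargetedIntron]:
    """Apply the >=10% criterion against every wheat arm simultaneously.

    Returns a :class:`TargetedIntron` when the quartet passes, else None.
    An incomplete quartet (any of A, B, D, V missing) is a precondition
    error.
    """
    cfg = cfg or PipelineConfig()
    missing = [a for a in (*WHEAT_ARMS, ALIEN_ARM) if a not in quartet.sizes]
    if missing:
        raise ValueError(f"incomplete quartet for {quartet.gene_id}: "
                         f"missing arms {missing}")
    v = quartet.sizes[ALIEN_ARM]
    diffs = {a: _rel_diff(v, quartet.sizes[a], quartet.sizes,
                          cfg.polymorphism_denominator)
             for a in WHEAT_ARMS}
    if all(d >= cfg.polymorphism_threshold for d in diffs.values()):
        return TargetedIntron(quartet, diffs, min(diffs.values()))
    return None


def select_marker_intron(targets: Sequence[TargetedIntron]) -> TargetedIntron:
    """Pick the single intron used for this gene's marker.

    The intron with the largest ``min_rel_diff`` wins; ties go to the
    smallest junction index.
    """
    if not targets:
        raise ValueError("no targeted introns to select from")
    return min(targets, key=lambda t: (-t.min_rel_diff, t.junction_index))


def filter_quartets(quartets: Sequence[IntronQuartet],
                    cfg: Optional[PipelineConfig] = None
                    ) -> List[TargetedIntron]:
    """All quartets passing the polymorphism criterion, input order kept."""
    cfg = cfg or PipelineConfig()
    out = []
    for q in quartets:
        t = is_targeted_intron(q, cfg)
        if t is not None:
            out.append(t)
    return out


def select_per_gene(targets: Sequence[TargetedIntron]) -> List[TargetedIntron]:
    """Apply the one-marker-per-gene rule over a list of targeted introns."""
    by_gene: Dict[str, List[TargetedIntron]] = {}
    for t in targets:
        by_gene.setdefault(t.gene_id, []).append(t)
    return [select_marker_intron(ts) for _, ts in sorted(by_gene.items())]


def build_funnel_report(n_genes_input: int, n_genes_hit_all_arms: int,
                        n_genes_with_junction: int, n_introns_total: int,
                        n_targeted_introns: int, n_genes_with_target: int,
                        n_markers_designed: int) -> FunnelReport:
    """Assemble the funnel report from stage counts.

    Mean introns per intron-containing gene is rounded to 2 decimals and
    reported as unavailable when no gene carries an intron.
    """
    mean = (round(n_introns_total / n_genes_with_junction, 2)
            if n_genes_with_junction else None)
    return FunnelReport(
        n_genes_input=n_genes_input,
        n_genes_hit_all_arms=n_genes_hit_all_arms,
        n_genes_with_junction=n_genes_with_junction,
        n_introns_total=n_introns_total,
        mean_introns_per_gene=mean,
        n_targeted_introns=n_targeted_introns,
        n_genes_with_target=n_genes_with_target,
        n_markers_designed=n_markers_designed,
    )
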