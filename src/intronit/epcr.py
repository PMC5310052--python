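"""In-silico PCR, gel band-pattern classification and bin assignment.

Markers are screened against all four genome arms by predicting every
amplicon a primer pair can generate: a primer anneals wherever it matches
the template with at most ``epcr_max_mismatch`` mismatches and a perfect
3'-terminal stretch, and any convergent forward/reverse site pair on one
scaffold within the maximum product size yields an amplicon.  Predicted
product sizes are then clustered into co-migrating gel bands, the band
pattern is typed (four distinct bands = Type I, one wheat pair merged =
Types II/III/IV by which arm is hidden, all wheat merged = Type V), and a
marker is called arm-specific when its alien (V) product forms a band of
its own.

Finally, presence/absence of specific markers across a nested series of
translocation lines places each marker into a physical bin between two
breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .config import ConfigError, PipelineConfig
from .io import GenomePanel
from .mapping import ALIEN_ARM, WHEAT_ARMS
from .primers import MarkerCandidate, PrimerPair

_ENCODE = {"A": 1, "C": 2, "G": 3, "T": 4}


@dataclass
class Amplicon:
    arm_id: str
    scaffold_id: str
    start: int
    end: int
    size: int
    f_mismatches: int
    r_mismatches: int


@dataclass
class BandPattern:
    marker_id: str
    products: Dict[str, int]
    bands: List[Tuple[Tuple[str, ...], float]]  # (member arms, mean size)
    n_bands: int
    type_label: str
    is_specific: bool


@dataclass
class LinePanel:
    """Nested translocation lines and a marker presence/absence matrix.

    ``lines`` are ordered distal to proximal: the first line retains the
    smallest distal segment of the alien arm, each later line a larger,
    nesting one.
    """

    lines: List[str]
    marker_presence: pd.DataFrame  # markers x lines, values {0, 1}


@dataclass
class BinAssignment:
    marker_id: str
    bin_index: int  # 0 = distal-most; len(lines) = beyond all breakpoints
    smallest_retaining: Optional[str]
    largest_nonretaining: Optional[str]
    consistent: bool


# ---------------------------------------------------------------------------
# primer binding and amplification


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


_LUT = np.zeros(256, dtype=np.uint8)
for _b, _v in _ENCODE.items():
    _LUT[ord(_b)] = _v


def find_binding_sites(primer: str, scaffold: str,
                       cfg: Optional[PipelineConfig] = None
                       ) -> List[Tuple[int, str, int]]:
    """All annealing sites of a primer on either strand of a template.

    A site needs <= ``epcr_max_mismatch`` total mismatches and zero
    mismatches over the 3'-terminal ``epcr_3prime_exact_bp`` bases; any
    non-ACGT template base counts as a mismatch.  Returned as
    ``(template_start, strand, mismatches)`` where strand ``+`` means the
    primer primes rightward synthesis and ``-`` leftward.
    """
    cfg = cfg or PipelineConfig()
    primer = primer.upper()
    if set(primer) - set("ACGT"):
        raise ValueError("primer must be ACGT-only")
    L = len(primer)
    if L > len(scaffold):
        return []
    t = _LUT[_encode(scaffold)]
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    sites: List[Tuple[int, str, int]] = []
    for strand in "+-":
        pseq = primer if strand == "+" else reverse_complement(primer)
        p = _LUT[_encode(pseq)]
        mismatch = windows != p
        total = mismatch.sum(axis=1)
        # the primer 3' end is the window's right edge on '+', left on '-'
        if strand == "+":
            tail_bad = mismatch[:, L - cfg.epcr_3prime_exact_bp:].any(axis=1)
        else:
            tail_bad = mismatch[:, :cfg.epcr_3prime_exact_bp].any(axis=1)
        ok = np.flatnonzero((total <= cfg.epcr_max_mismatch) & ~tail_bad)
        sites.extend((int(i), strand, int(total[i])) for i in ok)
    sites.sort()
    return sites


def simulate_pcr(pair: PrimerPair, panel: GenomePanel,
                 cfg: Optional[PipelineConfig] = None) -> List[Amplicon]:
    """Predict every amplicon of a primer pair on one genome arm.

    Each convergent combination of a rightward-priming site of one primer
    and a leftward-priming site of the other on the same scaffold gives a
    product, capped at ``epcr_max_product_bp``.
    """
    cfg = cfg or PipelineConfig()
    amplicons: List[Amplicon] = []
    for sid in sorted(panel.scaffolds):
        template = panel.scaffolds[sid]
        f_sites = find_binding_sites(pair.forward_seq, template, cfg)
        r_sites = find_binding_sites(pair.reverse_seq, template, cfg)
        for left, right, lf in ((pair.forward_seq, pair.reverse_seq, True),
                                (pair.reverse_seq, pair.forward_seq, False)):
            lsites = f_sites if lf else r_sites
            rsites = r_sites if lf else f_sites
            for lpos, lstrand, lmm in lsites:
                if lstrand != "+":
                    continue
                for rpos, rstrand, rmm in rsites:
                    if rstrand != "-" or rpos < lpos:
                        continue
                    size = rpos + len(right) - lpos
                    if size > cfg.epcr_max_product_bp:
                        continue
                    fmm, rmm_ = (lmm, rmm) if lf else (rmm, lmm)
                    amplicons.append(Amplicon(panel.arm_id, sid, lpos,
                                              lpos + size, size, fmm, rmm_))
    amplicons.sort(key=lambda a: (a.size, a.scaffold_id, a.start))
    return amplicons


# ---------------------------------------------------------------------------
# band clustering and typing


def comigrates(x: float, y: float, cfg: PipelineConfig) -> bool:
    """Whether two product sizes are unresolvable as separate gel bands."""
    return abs(x - y) <= max(cfg.comigration_abs_bp,
                             cfg.comigration_rel * (x + y) / 2.0)


def cluster_bands(products: Dict[str, int],
                  cfg: Optional[PipelineConfig] = None
                  ) -> List[Tuple[Tuple[str, ...], float]]:
    """Single-linkage clustering of product sizes into co-migrating bands.

    Returns ``(member_arms, mean_size)`` clusters, largest band first.
    """
    cfg = cfg or PipelineConfig()
    if not products:
        raise ValueError("no products to cluster")
    arms = sorted(products)
    parent = {a: a for a in arms}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(arms):
        for b in arms[i + 1:]:
            if comigrates(products[a], products[b], cfg):
                parent[find(a)] = find(b)
    groups: Dict[str, List[str]] = {}
    for a in arms:
        groups.setdefault(find(a), []).append(a)
    clusters = [(tuple(sorted(ms)), float(np.mean([products[m] for m in ms])))
                for ms in groups.values()]
    clusters.sort(key=lambda c: -c[1])
    return clusters


def classify_marker(marker_id: str, products: Dict[str, int],
                    cfg: Optional[PipelineConfig] = None) -> BandPattern:
    """Type a marker's predicted band pattern and call arm specificity.

    Specific means the V product exists and forms a band of its own.  With
    all four arms amplifying: four bands are Type I; three bands are typed
    by the wheat arm hidden inside the merged pair (B -> II, A -> III,
    D -> IV, the hidden member being the larger product of the pair); two
    bands with all wheat merged are Type V.  The published VI and VII
    labels are aliases of IV and V respectively.  A marker whose V product
    co-migrates with wheat is unclassified and not specific.
    """
    cfg = cfg or PipelineConfig()
    if ALIEN_ARM not in products:
        bands = cluster_bands(products, cfg) if products else []
        return BandPattern(marker_id, dict(products), bands, len(bands),
                           "no-V", False)
    bands = cluster_bands(products, cfg)
    v_band = next(b for b in bands if ALIEN_ARM in b[0])
    specific = len(v_band[0]) == 1
    label = "unclassified"
    if not specific:
        return BandPattern(marker_id, dict(products), bands, len(bands),
                           label, False)
    wheat_present = [a for a in WHEAT_ARMS if a in products]
    n = len(bands)
    if len(wheat_present) == 3:
        if n == 4:
            label = "I"
        elif n == 3:
            pair = next(b[0] for b in bands if len(b[0]) == 2)
            hidden = max(pair, key=lambda a: products[a])
            label = {"B": "II", "A": "III", "D": "IV"}[hidden]
        elif n == 2:
            label = "V"
    return BandPattern(marker_id, dict(products), bands, n, label, specific)


# ---------------------------------------------------------------------------
# whole-panel validation


@dataclass
class ValidationResult:
    marker: MarkerCandidate
    flag: str  # no-amplification | amplified-not-specific | specific
    pattern: Optional[BandPattern]
    amplicons: Dict[str, List[Amplicon]] = field(default_factory=dict)


def _representative(amps: List[Amplicon]) -> Amplicon:
    return min(amps, key=lambda a: (a.f_mismatches + a.r_mismatches, a.size))


def call_specific_markers(markers: Sequence[MarkerCandidate],
                          panels: Dict[str, GenomePanel],
                          cfg: Optional[PipelineConfig] = None
                          ) -> List[ValidationResult]:
    """Screen each marker against all arms and flag its status.

    ``no-amplification``: at least one template yields no amplicon;
    ``specific``: the V band stands alone; otherwise
    ``amplified-not-specific``.  Each marker's type label and specificity
    flag are recorded on the marker for table output.
    """
    cfg = cfg or PipelineConfig()
    results = []
    for marker in markers:
        amplicons = {arm: simulate_pcr(marker.primer_pair, panel, cfg)
                     for arm, panel in panels.items()}
        if any(not amps for amps in amplicons.values()):
            marker.type_label = "no-amplification"
            marker.is_specific = False
            results.append(ValidationResult(marker, "no-amplification", None,
                                            amplicons))
            continue
        products = {arm: _representative(amps).size
                    for arm, amps in amplicons.items()}
        pattern = classify_marker(marker.marker_id, products, cfg)
        flag = "specific" if pattern.is_specific else "amplified-not-specific"
        marker.type_label = pattern.type_label
        marker.is_specific = pattern.is_specific
        results.append(ValidationResult(marker, flag, pattern, amplicons))
    return results


def validation_summary(results: Sequence[ValidationResult]) -> dict:
    """Counts and the specificity success rate (percent, 2 decimals)."""
    n = len(results)
    n_specific = sum(1 for r in results if r.flag == "specific")
    n_noamp = sum(1 for r in results if r.flag == "no-amplification")
    rate = round(100.0 * n_specific / n, 2) if n else None
    return {"n_markers": n, "n_no_amplification": n_noamp,
            "n_amplified_not_specific": n - n_specific - n_noamp,
            "n_specific": n_specific, "specificity_rate_pct": rate}


# ---------------------------------------------------------------------------
# deletion-bin assignment


def assign_bins(panel: LinePanel) -> Dict[str, BinAssignment]:
    """Place markers into physical bins from nested translocation lines.

    With lines ordered distal to proximal (smallest retained segment
    first), a marker present in lines ``i..n`` but absent before sits
    between breakpoints ``i-1`` and ``i`` (bin index ``i``, 0-based, bin 0
    being distal of every breakpoint).  A marker present in a smaller
    segment but absent from a larger one violates nesting and is flagged
    inconsistent (assigned by its smallest retaining line).
    """
    lines = panel.lines
    matrix = panel.marker_presence
    if set(lines) != set(matrix.columns) or len(lines) != len(matrix.columns):
        raise ConfigError("line order does not match presence-matrix columns")
    out: Dict[str, BinAssignment] = {}
    for marker_id, row in matrix.iterrows():
        pattern = [int(row[l]) for l in lines]
        first_present = next((i for i, p in enumerate(pattern) if p), None)
        consistent = all(p == 1 for p in pattern[first_present:]) \
            if first_present is not None else True
        if first_present is None:
            out[str(marker_id)] = BinAssignment(str(marker_id), len(lines),
                                                None, lines[-1], True)
        else:
            largest_non = lines[first_present - 1] if first_present else None
            out[str(marker_id)] = BinAssignment(
                str(marker_id), first_present, lines[first_present],
                largest_non, consistent)
    return out
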