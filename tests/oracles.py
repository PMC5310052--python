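"""Independent reference implementations used only by the tests.

These deliberately share no code with the package: a quadratic
dynamic-programming spliced aligner, a position-by-position primer
binding-site scan, a pairwise-merging band clusterer, and a tiny
nearest-neighbour Tm calculator.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

NEG = -1e9


def dp_spliced_introns(transcript: str, scaffold: str, min_intron: int = 40,
                       mismatch: float = 1.0, intron_penalty: float = 2.0
                       ) -> List[int]:
    """Intron sizes of the optimal gap-free spliced alignment.

    Full O(n*m) dynamic programme: every transcript base must align to a
    scaffold base (no indels); between consecutive transcript bases the
    scaffold may jump forward by at least ``min_intron`` for a fixed
    penalty.  Global in the transcript, free start/end in the scaffold.
    """
    q = np.frombuffer(transcript.encode(), dtype=np.uint8)
    t = np.frombuffer(scaffold.encode(), dtype=np.uint8)
    n, m = len(q), len(t)
    D = np.full((n + 1, m + 1), NEG)
    D[0, :] = 0.0
    for i in range(1, n + 1):
        s = np.where(t == q[i - 1], 1.0, -mismatch)
        prev = D[i - 1]
        diag = prev[:-1]
        pref = np.maximum.accumulate(prev)
        jump = np.full(m, NEG)
        if m >= min_intron + 1:
            # query i-1 at target j-1 may follow query i-2 at any k-1 with
            # j-1-k >= min_intron  <=>  k <= j-1-min_intron
            jump[min_intron + 1:] = pref[1:m - min_intron] - intron_penalty
        D[i, 1:] = np.maximum(diag, jump) + s
    j = int(np.argmax(D[n]))
    introns = []
    for i in range(n, 1, -1):
        prev = D[i - 1]
        s = 1.0 if t[j - 1] == q[i - 1] else -mismatch
        if abs(D[i, j] - (prev[j - 1] + s)) < 1e-6:
            j -= 1
            continue
        limit = j - 1 - min_intron
        k = int(np.argmax(prev[1:limit + 1])) + 1
        introns.append(j - 1 - k)
        j = k
    introns.reverse()
    return introns


def scan_binding_sites(primer: str, template: str, max_mismatch: int,
                       three_prime_exact: int) -> List[Tuple[int, str, int]]:
    """Exhaustive position-by-position primer annealing scan."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(primer))
    out = []
    L = len(primer)
    for strand, probe in (("+", primer), ("-", rc)):
        for pos in range(len(template) - L + 1):
            window = template[pos:pos + L]
            mm = [a != b for a, b in zip(probe, window)]
            tail = mm[L - three_prime_exact:] if strand == "+" \
                else mm[:three_prime_exact]
            if sum(mm) <= max_mismatch and not any(tail):
                out.append((pos, strand, sum(mm)))
    out.sort()
    return out


def merge_cluster_sizes(products: Dict[str, int], abs_bp: float,
                        rel: float) -> List[set]:
    """Single-linkage band clustering by repeated pairwise merging."""
    clusters = [{a} for a in products]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(abs(products[a] - products[b])
                       <= max(abs_bp, rel * (products[a] + products[b]) / 2)
                       for a in clusters[i] for b in clusters[j]):
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return clusters


# unified nearest-neighbour parameters (dH kcal/mol, dS cal/mol/K)
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def nn_melting_temperature(seq: str, na_mM: float = 50.0,
                           oligo_nM: float = 250.0) -> float:
    """Independent nearest-neighbour Tm with the unified parameter set."""
    import math

    dh, ds = 0.2, -5.7  # initiation
    for base in (seq[0], seq[-1]):
        if base in "AT":
            dh += 2.2
            ds += 6.9
    for i in range(len(seq) - 1):
        pair = seq[i:i + 2]
        if pair not in _NN:
            pair = _COMP[pair[1]] + _COMP[pair[0]]
        dh += _NN[pair][0]
        ds += _NN[pair][1]
    # salt correction on entropy (SantaLucia 1998), then Tm
    ds_corr = ds + 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    ct = oligo_nM * 1e-9
    return 1000.0 * dh / (ds_corr + 1.987 * math.log(ct)) - 273.15
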