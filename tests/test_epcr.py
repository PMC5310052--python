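from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from intronit import PipelineConfig, assign_bins, call_specific_markers, \
    classify_marker, cluster_bands, find_binding_sites, simulate_pcr
from intronit.config import ConfigError
from intronit.epcr import LinePanel
from intronit.io import GenomePanel
from intronit.primers import MarkerCandidate, PrimerPair

from conftest import TABLE2_QUADS, random_seq
from oracles import merge_cluster_sizes, scan_binding_sites

COMP = str.maketrans("ACGT", "TGCA")


def rc(s):
    return s.translate(COMP)[::-1]


class TestBindingSites:
    def test_planted_site_exact(self, cfg):
        rng = np.random.default_rng(0)
        primer = "ACAGCTCATCATGCAGGACA"
        template = random_seq(rng, 300) + primer + random_seq(rng, 300)
        sites = find_binding_sites(primer, template, cfg)
        assert (300, "+", 0) in sites

    def test_three_prime_mismatch_rejected(self, cfg):
        rng = np.random.default_rng(1)
        primer = "ACAGCTCATCATGCAGGACA"
        mutated = primer[:-1] + ("G" if primer[-1] != "G" else "C")
        template = random_seq(rng, 200) + mutated + random_seq(rng, 200)
        sites = find_binding_sites(primer, template, cfg)
        assert all(not (p == 200 and s == "+") for p, s, _ in sites)

    def test_internal_mismatches_tolerated(self, cfg):
        rng = np.random.default_rng(2)
        primer = random_seq(rng, 20)
        mutated = list(primer)
        for i in (3, 8):  # two internal mismatches, 3' end intact
            mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        template = random_seq(rng, 100) + "".join(mutated) + random_seq(rng, 100)
        assert (100, "+", 2) in find_binding_sites(primer, template, cfg)

    def test_template_n_counts_as_mismatch(self, cfg):
        primer = "ACGTACGTACGTACGTACGT"
        template = "NNN" + primer.replace("A", "N", 3) + "NNN"
        assert find_binding_sites(primer, template, cfg) == []

    def test_agrees_with_exhaustive_scan(self, cfg):
        rng = np.random.default_rng(3)
        for _ in range(50):
            primer = random_seq(rng, int(rng.integers(15, 22)))
            template = random_seq(rng, 1000)
            # plant a perfect site and a 1-mismatch site
            pos = int(rng.integers(0, 900))
            template = template[:pos] + primer + template[pos + len(primer):]
            got = find_binding_sites(primer, template, cfg)
            expected = scan_binding_sites(primer, template,
                                          cfg.epcr_max_mismatch,
                                          cfg.epcr_3prime_exact_bp)
            assert got == expected


def _pair(f, r):
    return PrimerPair(f, r, 60.0, 60.0, 0, 0, 0.0)


class TestSimulatePCR:
    def test_planted_convergent_pair(self, cfg):
        rng = np.random.default_rng(4)
        f, r = random_seq(rng, 20), random_seq(rng, 22)
        insert = random_seq(rng, 441)  # 20 + 441 + 22 = 483 bp product
        template = random_seq(rng, 200) + f + insert + rc(r) + random_seq(rng, 200)
        panel = GenomePanel("V", {"s": template})
        amps = simulate_pcr(_pair(f, r), panel, cfg)
        assert [a.size for a in amps] == [483]
        assert amps[0].start == 200

    def test_divergent_sites_no_product(self, cfg):
        rng = np.random.default_rng(5)
        f, r = random_seq(rng, 20), random_seq(rng, 20)
        # outward-facing: reverse-complemented F then R on the plus strand
        template = random_seq(rng, 150) + rc(f) + random_seq(rng, 300) \
            + r + random_seq(rng, 150)
        panel = GenomePanel("A", {"s": template})
        assert simulate_pcr(_pair(f, r), panel, cfg) == []

    def test_two_forward_one_reverse_two_products(self, cfg):
        rng = np.random.default_rng(6)
        f, r = random_seq(rng, 20), random_seq(rng, 20)
        template = random_seq(rng, 100) + f + random_seq(rng, 200) + f \
            + random_seq(rng, 200) + rc(r) + random_seq(rng, 100)
        panel = GenomePanel("A", {"s": template})
        amps = simulate_pcr(_pair(f, r), panel, cfg)
        assert len(amps) == 2
        assert amps[0].size == 240 and amps[1].size == 460

    def test_oversized_product_suppressed(self):
        cfg = PipelineConfig(epcr_max_product_bp=400)
        rng = np.random.default_rng(7)
        f, r = random_seq(rng, 20), random_seq(rng, 20)
        template = f + random_seq(rng, 500) + rc(r)
        assert simulate_pcr(_pair(f, r), GenomePanel("A", {"s": template}),
                            cfg) == []


class TestClusterBands:
    def test_four_distinct_bands(self, cfg):
        sizes = {a: s + 50 for a, s in zip("ABDV", TABLE2_QUADS["CINAU687"])}
        bands = cluster_bands(sizes, cfg)
        assert len(bands) == 4

    def test_near_sizes_comigrate(self, cfg):
        sizes = {a: s + 50 for a, s in zip("ABDV", TABLE2_QUADS["CINAU646"])}
        # products 348/354/357/495: B and D merge at 4 bp / 1%
        bands = cluster_bands(sizes, cfg)
        assert len(bands) == 3
        assert ("B", "D") in [b[0] for b in bands]

    def test_all_equal_single_band(self, cfg):
        assert len(cluster_bands({a: 300 for a in "ABDV"}, cfg)) == 1

    def test_agrees_with_pairwise_merge_oracle(self, cfg):
        rng = np.random.default_rng(8)
        for _ in range(200):
            sizes = {a: int(rng.integers(100, 1200)) for a in "ABDV"}
            ours = {frozenset(b[0]) for b in cluster_bands(sizes, cfg)}
            oracle = {frozenset(c) for c in merge_cluster_sizes(
                sizes, cfg.comigration_abs_bp, cfg.comigration_rel)}
            assert ours == oracle


class TestClassification:
    def test_type_one_specific(self, cfg):
        sizes = {a: s + 50 for a, s in zip("ABDV", TABLE2_QUADS["CINAU687"])}
        pat = classify_marker("m", sizes, cfg)
        assert (pat.n_bands, pat.type_label, pat.is_specific) == (4, "I", True)

    def test_wheat_triplet_merged_still_specific(self, cfg):
        pat = classify_marker("m", {"A": 300, "B": 301, "D": 302, "V": 450}, cfg)
        assert pat.n_bands == 2
        assert pat.type_label == "V"
        assert pat.is_specific

    def test_v_comigrating_not_specific(self, cfg):
        pat = classify_marker("m", {"A": 200, "B": 300, "D": 400, "V": 400}, cfg)
        assert not pat.is_specific
        assert pat.type_label == "unclassified"

    def test_missing_v_product(self, cfg):
        pat = classify_marker("m", {"A": 200, "B": 300, "D": 400}, cfg)
        assert pat.type_label == "no-V"
        assert not pat.is_specific

    def test_three_band_labels_by_hidden_arm(self, cfg):
        # B merges into A's band -> B hidden -> Type II
        pat = classify_marker("m", {"A": 300, "B": 302, "D": 400, "V": 500}, cfg)
        assert (pat.n_bands, pat.type_label) == (3, "II")
        # D merges with B (D larger) -> D hidden -> Type IV
        pat = classify_marker("m", {"A": 200, "B": 398, "D": 400, "V": 500}, cfg)
        assert (pat.n_bands, pat.type_label) == (3, "IV")

    def test_specificity_threshold_monotone(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            sizes = {a: int(rng.integers(100, 800)) for a in "ABDV"}
            flags = []
            for rel in (0.005, 0.02, 0.08):
                cfg = PipelineConfig(comigration_rel=rel)
                flags.append(classify_marker("m", sizes, cfg).is_specific)
            # once lost at a permissive threshold, specificity never returns
            for lo, hi in zip(flags, flags[1:]):
                assert lo or not hi


class TestCallSpecific:
    def _marker_on(self, template_by_arm, f, r):
        panels = {a: GenomePanel(a, {f"{a}_s": t})
                  for a, t in template_by_arm.items()}
        marker = MarkerCandidate("ITM0001", "g", 1, _pair(f, r),
                                 {a: 100 for a in template_by_arm})
        return marker, panels

    def test_identical_products_not_specific(self, cfg):
        rng = np.random.default_rng(10)
        f, r = random_seq(rng, 20), random_seq(rng, 20)
        locus = f + random_seq(rng, 300) + rc(r)
        templates = {a: random_seq(rng, 100) + locus + random_seq(rng, 100)
                     for a in "ABDV"}
        marker, panels = self._marker_on(templates, f, r)
        (res,) = call_specific_markers([marker], panels, cfg)
        assert res.flag == "amplified-not-specific"

    def test_no_amplification_when_v_lacks_site(self, cfg):
        rng = np.random.default_rng(11)
        f, r = random_seq(rng, 20), random_seq(rng, 20)
        locus = f + random_seq(rng, 300) + rc(r)
        templates = {a: random_seq(rng, 100) + locus + random_seq(rng, 100)
                     for a in "ABD"}
        templates["V"] = random_seq(rng, 600)
        marker, panels = self._marker_on(templates, f, r)
        (res,) = call_specific_markers([marker], panels, cfg)
        assert res.flag == "no-amplification"
        assert marker.is_specific is False

    def test_flags_partition(self, small_bundle, cfg):
        from intronit.pipeline import run_pipeline_in_memory
        from intronit.epcr import validation_summary
        res = run_pipeline_in_memory(small_bundle.genes, small_bundle.panels, cfg)
        summary = validation_summary(res.results)
        assert summary["n_no_amplification"] + summary["n_specific"] \
            + summary["n_amplified_not_specific"] == summary["n_markers"]


class TestBins:
    def _panel(self, pattern_by_marker, lines=("L1", "L2", "L3")):
        df = pd.DataFrame(pattern_by_marker, index=list(lines)).T
        return LinePanel(list(lines), df)

    def test_present_everywhere_distal(self):
        out = assign_bins(self._panel({"m1": [1, 1, 1]}))
        assert out["m1"].bin_index == 0

    def test_absent_everywhere_proximal(self):
        out = assign_bins(self._panel({"m1": [0, 0, 0]}))
        assert out["m1"].bin_index == 3

    def test_present_only_in_largest(self):
        out = assign_bins(self._panel({"m1": [0, 0, 1]}))
        a = out["m1"]
        assert a.bin_index == 2
        assert a.smallest_retaining == "L3"
        assert a.largest_nonretaining == "L2"
        assert a.consistent

    def test_inconsistent_pattern_flagged(self):
        out = assign_bins(self._panel({"m1": [1, 0, 1]}))
        assert not out["m1"].consistent

    def test_mismatched_lines_rejected(self):
        panel = self._panel({"m1": [1, 1, 1]})
        panel.lines = ["L1", "L2", "LX"]
        with pytest.raises(ConfigError):
            assign_bins(panel)
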