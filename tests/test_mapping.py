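from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from intronit import PipelineConfig
from intronit.io import GenomePanel
from intronit.mapping import (ExonBlock, SplicedHit, find_exon_blocks,
                              infer_introns, map_gene_to_panel,
                              match_homologous_introns)
from intronit.simulate import FamilyParams, generate_family

from conftest import FIG1_QUAD, make_gene, random_seq
from oracles import dp_spliced_introns


def build_locus(rng, exon_lens, intron_lens, flank=300):
    """A transcript and a scaffold realizing the given exon/intron layout."""
    exons = [random_seq(rng, n) for n in exon_lens]
    parts = [random_seq(rng, flank)]
    for i, e in enumerate(exons):
        parts.append(e)
        if i < len(intron_lens):
            parts.append(random_seq(rng, intron_lens[i]))
    parts.append(random_seq(rng, flank))
    return "".join(exons), "".join(parts)


class TestFindExonBlocks:
    def test_contiguous_substring_single_block(self):
        rng = np.random.default_rng(0)
        tx, scaffold = build_locus(rng, [300], [])
        (chain, *_) = find_exon_blocks(tx, scaffold)
        assert len(chain.blocks) == 1
        assert chain.blocks[0].query_interval == (0, 300)
        assert chain.blocks[0].identity == pytest.approx(1.0)

    def test_two_exons_with_468bp_intron(self):
        rng = np.random.default_rng(1)
        tx, scaffold = build_locus(rng, [150, 150], [468])
        chain = find_exon_blocks(tx, scaffold)[0]
        hit = SplicedHit("g", "V", "s", chain.strand, chain.blocks)
        assert infer_introns(hit) == [(1, 468)]
        assert len(hit.blocks) == 2

    def test_strand_symmetry(self):
        rng = np.random.default_rng(2)
        tx, scaffold = build_locus(rng, [120, 140, 100], [200, 350])
        fwd = find_exon_blocks(tx, scaffold)[0]
        rev = find_exon_blocks(tx, reverse_complement(scaffold))[0]
        hf = SplicedHit("g", "A", "s", fwd.strand, fwd.blocks)
        hr = SplicedHit("g", "A", "s", rev.strand, rev.blocks)
        assert infer_introns(hf) == infer_introns(hr)
        assert {fwd.strand, rev.strand} == {"+", "-"}

    def test_too_short_transcript_empty(self):
        assert find_exon_blocks("ACGTACGT", "ACGT" * 100) == []


class TestInferIntrons:
    def _hit(self, blocks):
        return SplicedHit("g", "A", "s", "+",
                          [ExonBlock(q, t, 1.0, "+") for q, t in blocks])

    def test_gap_arithmetic(self):
        hit = self._hit([((0, 100), (900, 1000)), ((100, 200), (1415, 1515))])
        assert infer_introns(hit) == [(1, 415)]

    def test_small_gap_fused(self):
        hit = self._hit([((0, 100), (0, 100)), ((100, 200), (110, 210))])
        assert infer_introns(hit) == []
        assert len(hit.blocks) == 1

    def test_three_blocks_two_introns(self):
        hit = self._hit([((0, 100), (0, 100)), ((100, 200), (300, 400)),
                         ((200, 300), (600, 700))])
        assert infer_introns(hit) == [(1, 200), (2, 200)]
        assert [j for j, _, _ in hit.introns] == [1, 2]


class TestMapGeneToPanel:
    def make_quartet_panel(self, rng, intron_sizes_by_arm, exon_lens=(180, 160)):
        exons = [random_seq(rng, n) for n in exon_lens]
        tx = "".join(exons)
        panels = {}
        for arm, sizes in intron_sizes_by_arm.items():
            parts = [random_seq(rng, 400)]
            for i, e in enumerate(exons):
                parts.append(e)
                if i < len(sizes):
                    parts.append(random_seq(rng, sizes[i]))
            parts.append(random_seq(rng, 400))
            panels[arm] = GenomePanel(arm, {f"{arm}_s1": "".join(parts)})
        return make_gene("g1", tx), panels

    def test_worked_example_quartet(self):
        rng = np.random.default_rng(3)
        a, b, d, v = FIG1_QUAD
        gene, panels = self.make_quartet_panel(
            rng, {"A": [a], "B": [b], "D": [d], "V": [v]})
        hits = map_gene_to_panel(gene, panels)
        assert len(hits) == 4
        (quartet,) = match_homologous_introns(hits)
        assert quartet.sizes == {"A": 658, "B": 367, "D": 415, "V": 468}
        assert quartet.junction_index == 1

    def test_gene_absent_from_one_arm(self):
        rng = np.random.default_rng(4)
        gene, panels = self.make_quartet_panel(
            rng, {"A": [100], "B": [120], "D": [140], "V": [160]})
        panels["V"] = GenomePanel("V", {"V_s1": random_seq(rng, 3000)})
        hits = map_gene_to_panel(gene, panels)
        assert set(hits) == {"A", "B", "D"}
        assert match_homologous_introns(hits) == []

    def test_tie_break_deterministic_under_permutation(self):
        rng = np.random.default_rng(5)
        tx = random_seq(rng, 300)
        seg = random_seq(rng, 200) + tx + random_seq(rng, 200)
        panel1 = GenomePanel("A", {"s1": seg, "s2": seg})
        panel2 = GenomePanel("A", {"s2": seg, "s1": seg})
        h1 = map_gene_to_panel(make_gene("g", tx), {"A": panel1})["A"]
        h2 = map_gene_to_panel(make_gene("g", tx), {"A": panel2})["A"]
        assert h1.scaffold_id == h2.scaffold_id == "s1"


class TestJunctionMatching:
    def _hit(self, arm, introns):
        return SplicedHit("g", arm, "s", "+", [], introns=introns)

    def test_matching_within_tolerance(self):
        hits = {a: self._hit(a, [(1, 100 + i * 10, 150 + off)])
                for i, (a, off) in enumerate([("A", 0), ("B", 3), ("D", -3),
                                              ("V", 2)])}
        (q,) = match_homologous_introns(hits, tolerance_bp=12)
        assert q.sizes["V"] == 130

    def test_missing_junction_on_one_arm(self):
        hits = {"A": self._hit("A", [(1, 100, 150)]),
                "B": self._hit("B", [(1, 100, 150), (2, 90, 400)]),
                "D": self._hit("D", [(1, 100, 150), (2, 95, 402)]),
                "V": self._hit("V", [(1, 100, 151), (2, 80, 399)])}
        quartets = match_homologous_introns(hits)
        assert [q.junction_index for q in quartets] == [1]

    def test_no_v_hit_no_quartets(self):
        hits = {"A": self._hit("A", [(1, 100, 150)])}
        assert match_homologous_introns(hits) == []


class TestParameterRecovery:
    """The mapper must recover generator ground truth exactly."""

    @pytest.mark.parametrize("subst", [0.0, 0.03])
    def test_intron_sizes_recovered(self, subst):
        params = FamilyParams(substitution_rate={a: subst for a in "ABDV"},
                              n_exons_range=(2, 5),
                              intron_len_range=(60, 500))
        rng = np.random.default_rng(7)
        for i in range(5):
            fam = generate_family(f"g{i}", params, targeted=True, rng=rng)
            # transcript from the D segment (no substitutions on D)
            gene_tx = _transcript_from_segment(fam, "D")
            for arm in "ABDV":
                panel = GenomePanel(arm, {"s": fam.segments[arm]})
                hits = map_gene_to_panel(make_gene(fam.gene_id, gene_tx),
                                         {arm: panel})
                assert arm in hits
                sizes = [g for _, g, _ in hits[arm].introns]
                assert sizes == fam.intron_sizes[arm]


def _transcript_from_segment(fam, arm):
    seg = fam.segments[arm]
    parts, cur = [], 0
    for i, L in enumerate(fam.exon_lengths):
        parts.append(seg[cur:cur + L])
        cur += L
        if i < len(fam.intron_sizes[arm]):
            cur += fam.intron_sizes[arm][i]
    return "".join(parts)


class TestAgainstDPOracle:
    """Seed-chain mapper vs a quadratic-DP spliced aligner."""

    def test_intron_sizes_match_oracle(self, cfg):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_introns = int(rng.integers(1, 4))
            exon_lens = rng.integers(60, 160, n_introns + 1)
            intron_lens = rng.integers(60, 400, n_introns)
            tx, scaffold = build_locus(rng, exon_lens.tolist(),
                                       intron_lens.tolist(), flank=150)
            chain = find_exon_blocks(tx, scaffold, cfg)[0]
            hit = SplicedHit("g", "A", "s", chain.strand, chain.blocks)
            ours = [g for _, g in infer_introns(hit, cfg)]
            oracle = dp_spliced_introns(tx, scaffold, cfg.min_intron_bp)
            assert ours == [g for g in oracle if g >= cfg.min_intron_bp]
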