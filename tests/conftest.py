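from __future__ import annotations

import numpy as np
import pytest

from intronit import GeneModel, PipelineConfig
from intronit.simulate import FamilyParams, generate_panel

# Table-2-style worked examples: six published markers with their per-arm
# intron sizes (A, B, D, V); all six pass the 10% criterion.
TABLE2_QUADS = {
    "CINAU687": (632, 545, 687, 433),
    "CINAU648": (269, 308, 281, 233),
    "CINAU737": (339, 146, 340, 119),
    "CINAU665": (639, 575, 576, 508),
    "CINAU735": (1583, 1600, 939, 659),
    "CINAU646": (298, 304, 307, 445),
}

# worked example from the schematic: intron 7 of one gene family
FIG1_QUAD = (658, 367, 415, 468)


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_bundle():
    """A 20-family panel with default (2% exon divergence) noise."""
    return generate_panel(20, fraction_targeted=0.4, fraction_intronless=0.1,
                          seed=11)


@pytest.fixture(scope="session")
def clean_bundle():
    """A noise-free 12-family panel (no substitutions anywhere)."""
    params = FamilyParams(substitution_rate={a: 0.0 for a in "ABDV"})
    return generate_panel(12, fraction_targeted=0.5, fraction_intronless=0.0,
                          seed=5, params=params)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_gene(gene_id: str, seq: str, source: str = "test",
              start_pos=None) -> GeneModel:
    return GeneModel(gene_id, source, gene_id, "+", [(0, len(seq))], seq,
                     start_pos=start_pos)
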