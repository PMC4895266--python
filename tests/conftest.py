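"""Shared fixtures: small hand-built genes and a deterministic simulated gene."""

import numpy as np
import pytest

from nmfp.binning import enumerate_bins
from nmfp.gene_model import GeneModel, Isoform, Subexon
from nmfp.simulate import SimConfig, make_gene


@pytest.fixture
def gene3() -> GeneModel:
    """Three contiguous subexons [0,100), [100,200), [200,300)."""
    return GeneModel(
        "g3",
        "chr1",
        "+",
        [Subexon(1, 0, 100), Subexon(2, 100, 200), Subexon(3, 200, 300)],
    )


@pytest.fixture
def gene3_introns() -> GeneModel:
    """Three intron-separated subexons of 100 bp each."""
    return GeneModel(
        "g3i",
        "chr1",
        "+",
        [Subexon(1, 0, 100), Subexon(2, 300, 400), Subexon(3, 600, 700)],
    )


@pytest.fixture
def scheme3(gene3):
    return enumerate_bins(gene3)


@pytest.fixture
def scheme3_introns(gene3_introns):
    return enumerate_bins(gene3_introns)


@pytest.fixture
def sim_gene():
    """The default 8-exon simulated gene at a fixed seed."""
    cfg = SimConfig(seed=5)
    return make_gene(cfg), cfg


def iso(gene_id: str, bits: str, label: str = "") -> Isoform:
    return Isoform.from_string(gene_id, bits, label or bits)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
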