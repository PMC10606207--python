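import numpy as np
import pandas as pd
import pytest

from lnck.io import GeneModel, TranscriptModel
from lnck.simulate import SimConfig, generate_annotation, generate_expression, generate_samples


def gene(gene_id, chrom, start, end, strand, biotype="coding", exons=None):
    """One-transcript gene helper."""
    tx = TranscriptModel(gene_id + "_t1", exons or [(start, end)])
    return GeneModel(gene_id, chrom, start, end, strand, biotype, [tx])


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=7, n_coding=300, n_lnc=150)


@pytest.fixture(scope="session")
def sim_annotation(sim_cfg):
    return generate_annotation(sim_cfg)


@pytest.fixture(scope="session")
def sim_samples(sim_cfg):
    return generate_samples(sim_cfg)


@pytest.fixture(scope="session")
def sim_expression(sim_cfg, sim_annotation, sim_samples):
    genes, _ = sim_annotation
    return generate_expression(sim_cfg, genes, sim_samples)


@pytest.fixture
def four_sample_meta():
    """One line, two conditions, two replicates."""
    return pd.DataFrame(
        {
            "sample_id": ["L_WW_1", "L_WW_2", "L_WS_1", "L_WS_2"],
            "line_id": "L1",
            "generation": "RIL",
            "tolerance": "D",
            "condition": ["WW", "WW", "WS", "WS"],
            "replicate": [1, 2, 1, 2],
        }
    )
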