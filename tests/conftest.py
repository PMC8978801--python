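import numpy as np
import pandas as pd
import pytest

import scznet as sz
from scznet.pipeline import run_region

SIM_SEED, KB_SEED, PIPE_SEED = 11, 12, 13


def make_matrix(values, genes, samples, labels, region="test"):
    """Small-matrix helper for hand-built cases."""
    return sz.ExpressionMatrix(
        values=pd.DataFrame(np.asarray(values, dtype=float),
                            index=genes, columns=samples),
        labels=pd.Series(labels, index=samples),
        region=region,
    )


@pytest.fixture(scope="session")
def sim_data():
    """Seeded standard-scenario expression matrix + ground truth."""
    return sz.generate_expression(sz.SimulationConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def knowledgebase(sim_data):
    """Seeded knowledgebase consistent with the simulated matrix."""
    matrix, truth = sim_data
    pool, disease_db, pathway_db, interactions = sz.generate_knowledgebase(
        sz.KnowledgebaseConfig(seed=KB_SEED), truth, expressed_genes=matrix.genes
    )
    return pool, disease_db, pathway_db, interactions


@pytest.fixture(scope="session")
def pipeline_result(sim_data, knowledgebase):
    """Full pipeline run on the standard synthetic scenario."""
    matrix, _ = sim_data
    pool, disease_db, pathway_db, interactions = knowledgebase
    return run_region(matrix, pool, disease_db, pathway_db, interactions,
                      seed=PIPE_SEED)
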