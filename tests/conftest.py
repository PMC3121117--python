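import logging

import numpy as np
import pytest

from glycolink import (
    ExpressionMatrix,
    PipelineConfig,
    SampleAnnotation,
    SimulationDesign,
    simulate_all,
)

logging.getLogger("glycolink").setLevel(logging.WARNING)


def make_matrix(values, gene_ids=None, classes=None, lineages=None):
    """Small annotated expression matrix for hand-built examples."""
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    classes = classes or ["SC"] * s
    lineages = lineages or ["X"] * s
    sample_ids = [f"s{j}" for j in range(s)]
    ann = {
        sid: SampleAnnotation(sample_id=sid, lineage=lineages[j],
                              cell_class=classes[j], line_id=f"L{j}",
                              passage=1)
        for j, sid in enumerate(sample_ids)
    }
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids,
                            values=values, annotations=ann)


@pytest.fixture(scope="session")
def default_bundle():
    """One full synthetic study at the default design and seed."""
    return simulate_all(SimulationDesign(), seed=20750)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20750)
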