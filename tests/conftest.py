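import numpy as np
import pandas as pd
import pytest

from hetdr.graph import MaskMatrix, assemble_graph
from hetdr.model import ModelConfig
from hetdr.pipeline import prepare_inputs
from hetdr.simulate import generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small planted cohort: fast enough for end-to-end training in tests."""
    return generate_cohort(
        n_drugs=12, n_cells=16, n_genes=30, targets_per_drug=1,
        effect_size=2.0, noise_sd=0.5, dti_visible_fraction=0.5, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_inputs(tiny_cohort):
    return prepare_inputs(
        tiny_cohort.response, tiny_cohort.expression,
        tiny_cohort.fingerprints, tiny_cohort.dti_known,
    )


@pytest.fixture(scope="session")
def tiny_graph(tiny_inputs):
    n, m = tiny_inputs.labels.shape
    return assemble_graph(
        tiny_inputs.labels, tiny_inputs.acg, tiny_inputs.adg,
        MaskMatrix.all_visible(n, m), tiny_inputs.gene_ids,
    )


@pytest.fixture
def fast_config():
    """Few-epoch configuration for smoke-level training tests."""
    return ModelConfig(hidden_size=20, n_heads=5, epochs=5, seed=3)


@pytest.fixture
def random_response():
    rng = np.random.default_rng(11)
    vals = 10.0 ** rng.normal(0, 1, size=(6, 20))
    return pd.DataFrame(
        vals,
        index=[f"D{i}" for i in range(6)],
        columns=[f"C{j}" for j in range(20)],
    )
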