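import numpy as np
import pytest

import oncotyper as ot


@pytest.fixture(scope="session")
def tiny_cohort():
    """The canned tiny cohort (3 types x 30 samples, 404 features) plus its matrix."""
    config = ot.default_config("tiny")
    variants, cnv, labels, truth = ot.simulate_cohort(config)
    schema = ot.schema_for(config)
    matrix = ot.assemble_matrix(variants, cnv, labels, schema)
    return {
        "config": config,
        "variants": variants,
        "cnv": cnv,
        "labels": labels,
        "truth": truth,
        "schema": schema,
        "matrix": matrix,
    }


@pytest.fixture(scope="session")
def tiny_xy(tiny_cohort):
    m = tiny_cohort["matrix"]
    y = np.array([tiny_cohort["labels"].mapping[s] for s in m.samples])
    return m.values, y


@pytest.fixture
def small_mlp_config():
    return ot.MlpConfig(
        hidden_layers=2,
        units_per_layer=64,
        learning_rate=1e-3,
        batch_size=32,
        max_epochs=60,
        seed=0,
    )
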