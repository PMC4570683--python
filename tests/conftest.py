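import numpy as np
import pandas as pd
import pytest

from mitocoex import ExpressionMatrix, ModuleSpec, SimulationConfig
from mitocoex import generate_design, generate_expression, normalize


def make_matrix(values, genes=None, samples=None, state="centered", origin=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    origin_series = pd.Series(origin, index=genes) if origin is not None else None
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            state=state, origin=origin_series)


@pytest.fixture
def planted_dataset():
    """2,000-gene / 32-sample dataset with one 60-gene planted module."""
    config = SimulationConfig(
        n_genes=2000,
        module_specs=(ModuleSpec(size=60, loading=1.0, label="module1"),),
        noise_sd=1.0,
        seed=42,
    )
    design = generate_design(config)
    return generate_expression(design, config)


@pytest.fixture
def planted_centered(planted_dataset):
    return normalize(planted_dataset.matrix)
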