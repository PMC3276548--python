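import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirderep import MIR124, generate_dataset, scenario

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mirna():
    return MIR124


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene default-scenario dataset shared across read-only tests."""
    return generate_dataset(scenario("default", seed=11, n_genes=300))


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size default-scenario dataset shared across read-only tests."""
    return generate_dataset(scenario("default", seed=0))


def toy_matrix(values: dict[str, list[float]], genes=None):
    """Small ExpressionMatrix helper: values maps sample -> column."""
    from mirderep import ExpressionMatrix

    df = pd.DataFrame(values)
    if genes is not None:
        df.index = pd.Index(genes, name="gene_id")
    samples = pd.DataFrame({
        "sample": list(values),
        "genotype": ["wildtype" if s.startswith("wt") else "mutant"
                     for s in values],
        "replicate": [int(s.split("_")[1]) for s in values],
    })
    return ExpressionMatrix(df, samples)
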