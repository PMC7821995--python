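import numpy as np
import pandas as pd
import pytest

from amenbn.variables import DataTable, VariableSpec


def continuous_table(cols: dict) -> DataTable:
    """DataTable of all-continuous columns."""
    return DataTable(
        [VariableSpec(k, "continuous") for k in cols], pd.DataFrame(cols)
    )


def mixed_table(cols: dict, discrete: dict) -> DataTable:
    """DataTable with ``discrete`` mapping column name -> level tuple."""
    specs = [
        VariableSpec(k, "discrete", tuple(discrete[k]))
        if k in discrete
        else VariableSpec(k, "continuous")
        for k in cols
    ]
    return DataTable(specs, pd.DataFrame(cols))


@pytest.fixture(scope="session")
def chain_table() -> DataTable:
    """Linear-Gaussian chain A -> B -> C (unit coefficients, unit noise)."""
    rng = np.random.default_rng(5)
    A = rng.normal(size=2000)
    B = A + rng.normal(size=2000)
    C = B + rng.normal(size=2000)
    return continuous_table({"A": A, "B": B, "C": C})


@pytest.fixture(scope="session")
def feed_sample():
    """One mid-sized synthetic feed dataset plus its generating network."""
    from amenbn.simulate import GeneratorConfig, simulate_feed_dataset

    return simulate_feed_dataset(GeneratorConfig(n=1500, seed=42))
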