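import numpy as np
import pandas as pd
import pytest

from daposcope.core import NORMAL, ExpressionMatrix
from daposcope.synthetic import PlantedEffect, SyntheticScenario


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scenario():
    """Tiny three-group scenario with one gene planted up in SII."""
    return SyntheticScenario(
        seed=7, n_genes=40, n_samples_per_group=10,
        groups=(NORMAL, "SI", "SII"),
        planted_de={"G01": PlantedEffect(("SII",), "up", 2.0)},
    )


@pytest.fixture
def two_group_matrix(rng):
    """60 genes x (10 normal + 10 tumour), no true effects."""
    values = pd.DataFrame(
        rng.poisson(100, size=(60, 20)),
        index=[f"g{i:02d}" for i in range(60)],
        columns=[f"n{i}" for i in range(10)] + [f"t{i}" for i in range(10)],
    )
    stages = pd.Series([NORMAL] * 10 + ["SII"] * 10, index=values.columns)
    return ExpressionMatrix(values, stages)


def random_membership(rng, n_genes=12, stages=("SI", "SII", "SIII", "SIV")):
    """Random signed stage-membership matrix with no all-zero rows."""
    vals = rng.integers(-1, 2, size=(n_genes, len(stages)))
    vals[(vals == 0).all(axis=1), 0] = 1
    return pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                        columns=list(stages))
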