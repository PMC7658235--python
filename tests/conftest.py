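import numpy as np
import pandas as pd
import pytest

from azasig import ExpressionMatrix, PhenotypeTable
from azasig.simulate import (
    ModuleSpec,
    SimulationConfig,
    simulate_discovery_cohort,
)


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A fast discovery design: 400 genes, 60 planted, 14+9 samples."""
    params = dict(
        n_genes=400,
        modules=(
            ModuleSpec("RESPIRATION", 25, "up_in_responders", 1.0),
            ModuleSpec("APOPTOSIS", 10, "up_in_responders", 1.5),
            ModuleSpec("WNT", 25, "up_in_nonresponders", 1.0),
        ),
        n_decoy_sets=10,
        decoy_set_size_range=(15, 40),
        n_validation_samples=60,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def planted_cohort():
    return simulate_discovery_cohort(small_config())


@pytest.fixture()
def tiny_matrix():
    """3 genes x 6 samples with exact log2 values via 2**y - 1."""
    log2 = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 5.0],
            "s2": [2.0, 2.0, 5.0],
            "s3": [3.0, 2.0, 5.0],
            "s4": [4.0, 2.0, 5.0],
            "s5": [5.0, 2.0, 5.0],
            "s6": [6.0, 2.0, 5.0],
        },
        index=["gA", "gConst", "gFlat"],
    )
    return ExpressionMatrix(np.exp2(log2) - 1.0)


@pytest.fixture()
def tiny_phenotypes():
    return PhenotypeTable(
        pd.DataFrame(
            {"group": ["responder"] * 3 + ["non_responder"] * 3},
            index=pd.Index([f"s{i}" for i in range(1, 7)], name="sample_id"),
        )
    )
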