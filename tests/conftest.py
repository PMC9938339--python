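import importlib.resources as ir
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

import survalid as sv


@pytest.fixture(scope="session")
def model_def_dir() -> Path:
    return Path(ir.files("survalid") / "model_defs")


@pytest.fixture
def toy_model() -> sv.ModelDefinition:
    """Three-predictor stroke-specific toy model."""
    from survalid.model import Predictor, TransformSpec

    return sv.ModelDefinition(
        name="toy3",
        outcome_label="stroke",
        horizon=10.0,
        predictors=[
            Predictor(name="age", covariate="age", transform=TransformSpec(type="identity"),
                      coefficient=0.05),
            Predictor(name="sbp", covariate="sbp", transform=TransformSpec(type="identity"),
                      coefficient=0.02),
            Predictor(name="smoker", covariate="smoker", transform=TransformSpec(type="indicator"),
                      coefficient=0.6),
        ],
        centring_means={"age": 70.0, "sbp": 140.0, "smoker": 0.2},
        baseline_survival=0.9,
        outcome_fraction=1.0,
    )


@pytest.fixture
def small_cohort() -> sv.Cohort:
    rng = np.random.default_rng(42)
    n = 40
    df = pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(n)],
            "time": rng.uniform(0.5, 10.0, n),
            "event": rng.integers(0, 3, n),
            "age": rng.uniform(60, 80, n),
            "sbp": rng.normal(140, 15, n),
            "smoker": rng.integers(0, 2, n),
        }
    )
    return sv.Cohort(df)


@pytest.fixture(scope="session")
def default_synth():
    """Moderate competing-risks cohort reused across tests."""
    cfg = sv.default_scenario(n=4000, seed=101)
    return cfg, sv.generate_cohort(cfg)
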