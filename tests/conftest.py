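import numpy as np
import pandas as pd
import pytest

from nanopotency.datasets import (
    CompoundSpec,
    ExperimentDesign,
    PotencyArchetype,
    generate_apical_dataset,
)


@pytest.fixture(scope="session")
def zinc() -> CompoundSpec:
    return CompoundSpec("ZnO NP", "ZnO", "Zn", 1, form_code=2, pps_nm=22.0,
                        ssa_m2_per_g=27.0, solubility_pct=19.3)


@pytest.fixture(scope="session")
def exp3_decrease() -> PotencyArchetype:
    """The reference viability curve: 100 * exp(-0.002 x)."""
    return PotencyArchetype("exp3", a=100.0, b=-0.002, d=1.0, sigma=0.0,
                            direction="decrease")


@pytest.fixture(scope="session")
def design_1tp() -> ExperimentDesign:
    return ExperimentDesign((0.0, 50.0, 100.0, 200.0, 400.0, 800.0),
                            replicates=3, timepoints_h=(24.0,), seed=11)


@pytest.fixture(scope="session")
def noisefree_exp3_slice(zinc, exp3_decrease, design_1tp) -> pd.DataFrame:
    ds = generate_apical_dataset(
        [zinc], {zinc.id: {"viability_24h": exp3_decrease}}, design_1tp,
        endpoints=["viability_24h"],
    )
    return pd.DataFrame({
        "concentration": ds.table["concentration_ug_per_ml"],
        "response": ds.table["response"],
    })


@pytest.fixture(scope="session")
def planted_two_group_matrix() -> pd.DataFrame:
    """8 compounds x 7 endpoints; two archetypes separated by 5x the noise SD."""
    rng = np.random.default_rng(42)
    sigma = 0.2
    a = rng.normal(0.0, sigma, size=(4, 7))
    b = rng.normal(5 * sigma, sigma, size=(4, 7))
    X = np.vstack([a, b])
    return pd.DataFrame(X, index=[f"cmpd{i}" for i in range(8)],
                        columns=[f"ep{j}" for j in range(7)])
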