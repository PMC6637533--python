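import numpy as np
import pandas as pd
import pytest

from nbsides.data import TrialDataset, prepare_analysis_set
from nbsides.simulate import ScenarioConfig, scenario_library, simulate_trial


@pytest.fixture(scope="session")
def planted_trial():
    """One full-size trial with a planted FeNO threshold interaction."""
    data, truth = simulate_trial(scenario_library()["feno_threshold"], seed=20240901)
    return data, truth


@pytest.fixture(scope="session")
def planted_prepared(planted_trial):
    data, truth = planted_trial
    return prepare_analysis_set(data), truth


@pytest.fixture(scope="session")
def null_prepared():
    """A smaller trial with an overall effect but no biomarker structure."""
    cfg = ScenarioConfig(name="null_small", n_total=400, all_comers_rr=0.85,
                         endpoints={})
    data, _ = simulate_trial(cfg, seed=77)
    return prepare_analysis_set(data)


@pytest.fixture()
def tiny_participants():
    """Hand-built 12-participant table covering all four arms."""
    rng = np.random.default_rng(5)
    n = 12
    return pd.DataFrame(
        {
            "participant_id": [f"T{i:02d}" for i in range(n)],
            "arm": ["tralo_q2w", "placebo_q2w", "tralo_q4w", "placebo_q4w"] * 3,
            "feno_ppb": np.round(rng.lognormal(3.0, 0.8, n), 1),
            "periostin_ng_ml": np.round(rng.lognormal(3.1, 0.5, n), 1),
            "eos_cells_ul": np.round(rng.lognormal(5.3, 0.9, n), 0),
            "dpp4_ng_ml": np.round(rng.lognormal(5.5, 0.3, n), 0),
            "ige_iu_ml": np.round(rng.lognormal(5.0, 1.2, n), 1),
            "region": ["europe", "asia_pacific"] * 6,
            "age_years": np.round(rng.uniform(14, 70, n), 1),
            "prior_exacerbations": rng.integers(1, 5, n),
            "exacerbation_count": rng.integers(0, 4, n),
            "followup_years": np.round(rng.uniform(0.5, 1.0, n), 3),
        }
    )


@pytest.fixture()
def tiny_dataset(tiny_participants):
    return TrialDataset(tiny_participants)
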