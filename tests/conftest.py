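import numpy as np
import pandas as pd
import pytest

from pucase import GeneratorConfig, PUDataset, generate_pu_dataset
from pucase.datagen import strong_shift_cost_features


@pytest.fixture(scope="session")
def small_dataset() -> PUDataset:
    """Moderate-overlap PU table, 800 cases, default generator profile."""
    return generate_pu_dataset(GeneratorConfig(n_cases=800, seed=42))


@pytest.fixture(scope="session")
def separable_dataset() -> PUDataset:
    """Strong-shift, fully labeled (c=1): classes nearly separable, s = y."""
    cfg = GeneratorConfig(
        n_cases=600,
        class_prior=0.25,
        label_frequency=1.0,
        cost_features=strong_shift_cost_features(),
        seed=7,
    )
    return generate_pu_dataset(cfg)


def toy_dataset(frame_dict: dict, feature_columns: list[str]) -> PUDataset:
    """Hand-built PU dataset from a column dict; fills cohort defaults."""
    frame = pd.DataFrame(frame_dict)
    n = len(frame)
    defaults = {
        "y": np.nan,
        "explicit_flag": frame.get("s", pd.Series(np.zeros(n))),
        "implicit_flag": 0,
        "age_band": "50-54",
        "length_of_stay_days": 3,
        "total_costs": 1000.0,
        "has_main_diagnosis": True,
        "has_drg": True,
    }
    for col, val in defaults.items():
        if col not in frame.columns:
            frame[col] = val
    return PUDataset(frame=frame, feature_columns=feature_columns)
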