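import numpy as np
import pandas as pd
import pytest
from datetime import datetime

from cagephys.events import ExperimentMetadata
from cagephys.simulate import CohortConfig, GroupParams, simulate_cohort


@pytest.fixture(scope="session")
def meta_noon():
    """Experiment starting at 10:00 with a two-group, four-animal roster."""
    return ExperimentMetadata(
        t0_clock=datetime(2020, 1, 6, 10, 0, 0),
        roster={"a1": "wt", "a2": "wt", "b1": "ko", "b2": "ko"},
    )


@pytest.fixture
def tiny_events():
    """Three visits / five nosepokes exercising all three visit classes."""
    visits = pd.DataFrame(
        {
            "visit_id": [1, 2, 3],
            "animal_tag": ["a1", "a1", "a2"],
            "corner": [2, 3, 2],
            "start_time_s": [100.0, 300.0, 150.0],
            "end_time_s": [130.0, 330.0, 170.0],
            "module_label": ["PPL"] * 3,
        }
    )
    nosepokes = pd.DataFrame(
        {
            "visit_id": [1, 1, 2, 3, 3],
            "side": ["LEFT", "LEFT", "RIGHT", "LEFT", "RIGHT"],
            "time_s": [101.0, 105.0, 301.0, 151.0, 152.0],
            "door_opened": [True, False, False, False, False],
            "lick_count": [8, 2, 0, 0, 0],
            "lick_duration_s": [1.0, 0.3, 0.0, 0.0, 0.0],
            "contact_time_s": [1.2, 0.4, 0.2, 0.1, 0.1],
        }
    )
    return visits, nosepokes


@pytest.fixture(scope="session")
def small_cohort():
    """A 2x3-animal, 3-day simulated cohort with its ground truth."""
    cfg = CohortConfig(
        groups={"wt": GroupParams(), "ko": GroupParams(mesor=2.0)},
        n_per_group=3,
        duration_days=3.0,
        seed=42,
    )
    visits, nosepokes, meta, truth = simulate_cohort(cfg)
    return cfg, visits, nosepokes, meta, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
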