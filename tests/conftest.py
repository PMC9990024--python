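import numpy as np
import pandas as pd
import pytest

from sitqc import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20230307)


@pytest.fixture
def config():
    """Paper-emulating defaults with a fixed seed."""
    return SimulationConfig(seed=20230307)


@pytest.fixture
def small_cages():
    """Tiny hand-built competition table: one number per arm is easy to check."""
    return pd.DataFrame(
        {
            "arm": ["Hn", "Hn", "Hs", "Hs", "Ho", "Ho"],
            "replicate": [1, 2, 1, 2, 1, 2],
            "n_fertile_males": [50, 50, 0, 0, 50, 50],
            "n_sterile_males": [0, 0, 50, 50, 50, 50],
            "n_females": [50] * 6,
            "eggs_total": [1000, 1000, 1000, 1000, 1000, 1000],
            "eggs_hatched": [400, 400, 100, 100, 250, 250],
        }
    )


@pytest.fixture
def flight_trials():
    """Three durations with escape counts on an exact logistic line plus noise-free controls."""
    rows = []
    for treatment, duration, p in [("2_25", 25, 0.20), ("2_50", 50, 0.10), ("2_100", 100, 0.02)]:
        for rep in (1, 2):
            rows.append(
                {
                    "treatment": treatment,
                    "replicate": rep,
                    "second_chill_min": duration,
                    "n_loaded": 50,
                    "n_escaped": int(round(50 * p)),
                }
            )
    rows.append(
        {
            "treatment": "C_2_25",
            "replicate": 1,
            "second_chill_min": np.nan,
            "n_loaded": 50,
            "n_escaped": 15,
        }
    )
    return pd.DataFrame(rows)
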