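import numpy as np
import pandas as pd
import pytest

from urgentrace import DEFAULT_PARAMS, TrialDesign, simulate_trials


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def default_tables(params):
    """One 12k-trial table per trial type under the default parameters."""
    rng = np.random.default_rng(2024)
    return {
        t: simulate_trials(params, TrialDesign(proportions={t: 1.0}), 12_000, rng)
        for t in ("congruent", "symmetric", "incongruent")
    }


@pytest.fixture()
def toy_table():
    """20 hand-placed trials for exhaustive enumeration checks."""
    pts = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100,
           110, 120, 130, 140, 150, 160, 170, 180, 190, 200]
    correct = [0, 1, 0, 1, 1, 0, 1, 1, 0, 1,
               1, 1, 0, 1, 1, 1, 1, 0, 1, 1]
    gap = 100.0
    return pd.DataFrame(
        {
            "trial_type": "symmetric",
            "gap_ms": gap,
            "rt_ms": [p + gap for p in pts],
            "pt_ms": [float(p) for p in pts],
            "correct": [bool(c) for c in correct],
            "valid": True,
        }
    )
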