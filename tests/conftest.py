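import logging

import numpy as np
import pandas as pd
import pytest

from dietcvd.catalog import default_catalog
from dietcvd.lipids import derive_lipid_panel
from dietcvd.pipeline import prepare_stage, score_cohort
from dietcvd.simulate import SimulationConfig, simulate_cohort

logging.getLogger("dietcvd").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """One fixed small cohort shared across tests (n=800, seed 42)."""
    return simulate_cohort(SimulationConfig(n_participants=800, seed=42))


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    """Scored, lipid-derived and exclusion-filtered view of the small cohort."""
    scores = score_cohort(small_cohort.intakes, small_cohort.nutrients)
    lipids = derive_lipid_panel(small_cohort.lipids)
    ids, log = prepare_stage(small_cohort, lipids)
    return {"scores": scores, "lipids": lipids, "ids": ids, "log": log}


@pytest.fixture()
def toy_risk_table():
    """Hand-sized counting-process table with a handful of events."""
    rng = np.random.default_rng(7)
    n = 120
    x = rng.standard_normal(n)
    t = rng.exponential(1 / (0.05 * np.exp(0.4 * x)))
    stop = np.minimum(np.maximum(t, 0.01), 32.0)
    event = (t <= 32.0).astype(int)
    return pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "start": 0.0,
            "stop": stop,
            "event": event,
            "x": x,
        }
    )
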