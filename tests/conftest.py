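import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from radpipe.synthetic import SimulationConfig, gen_timecourse

TIMEPOINTS = (0.25, 2.0, 7.0, 12.0, 24.0, 48.0, 72.0, 96.0)


@pytest.fixture(scope="session")
def small_timecourse():
    """150-gene simulated time course with 20% DE genes."""
    cfg = SimulationConfig(n_genes=150, prop_de=0.2, effect_sd=1.0, seed=11)
    return gen_timecourse(cfg)


@pytest.fixture(scope="session")
def null_timecourse():
    """No-treatment-effect simulation (all nulls)."""
    cfg = SimulationConfig(n_genes=400, prop_de=0.0, seed=13)
    return gen_timecourse(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_design(timepoints=TIMEPOINTS, n_reps=3):
    rows = []
    for cond in ("control", "treated"):
        for ti, t in enumerate(timepoints):
            for r in range(1, n_reps + 1):
                rows.append((f"{cond}_t{ti}_r{r}", cond, t, r))
    return pd.DataFrame(
        rows, columns=["sample", "condition", "time_h", "replicate"]
    ).set_index("sample")
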