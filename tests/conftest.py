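import warnings

import numpy as np
import pandas as pd
import pytest

import cyclefate as cf


@pytest.fixture(autouse=True)
def _quiet_protocol_warnings():
    # protocol-length advisories are expected in several scenario tests
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="chase window shorter")
        warnings.filterwarnings("ignore", message="pulse width")
        yield


@pytest.fixture
def homeostatic_config():
    """Constant T=20 h, pp-dd=0, full growth fraction, no apoptosis."""
    return cf.SimConfig(initial_count=500, t_end=48.0, seed=11)


@pytest.fixture
def pooled_counts():
    """Average P/D trajectories over several runs of a mildly growing
    population with quiescence and apoptosis (constant parameters)."""
    sched = cf.ScheduleSet(
        T_mean=cf.constant(20.0),
        ppdd=cf.constant(0.15),
        gamma=cf.constant(0.8),
        apoptosis_rate=cf.constant(0.005),
    )
    frames = []
    for ss in np.random.SeedSequence(7).spawn(10):
        cfg = cf.SimConfig(initial_count=500, t_end=48.0, schedules=sched)
        frames.append(cf.run(cfg, rng=np.random.default_rng(ss)).frame)
    t = frames[0]["time_h"].to_numpy()
    P = np.mean([f["P"].to_numpy() for f in frames], axis=0)
    D = np.mean([f["D"].to_numpy() for f in frames], axis=0)
    counts = cf.CountsTimeSeries(pd.DataFrame({"time_h": t, "P": P, "D": D}))
    truth = {"T": 20.0, "ppdd": 0.15, "gamma": 0.8, "apoptosis_rate": 0.005}
    return counts, truth
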