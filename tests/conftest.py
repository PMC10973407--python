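import numpy as np
import pytest

import mutltrace as mt

DT2MIN = mt.ImagingConfig(frame_interval_s=120.0)


@pytest.fixture(scope="session")
def bimodal_experiment():
    """Balanced short/long mixture at 2-min frames (failure prob boosted to 0.3
    so both lifetime modes carry comparable mass)."""
    params = mt.SimulationParams(
        error_rate_per_min=0.064, failure_prob=0.3, tau_short_s=40.0,
        doubling_time_min=26.6, n_lineages=100, window_generations=30, seed=0,
    )
    traces, foci = mt.simulate_experiment(params, DT2MIN)
    return params, traces, foci


@pytest.fixture(scope="session")
def wt_longterm_experiment():
    """Wild-type-like long-term run: 1% repair failure, 2-min frames."""
    params = mt.SimulationParams(
        error_rate_per_min=0.064, failure_prob=0.01, tau_short_s=40.0,
        doubling_time_min=26.6, n_lineages=150, window_generations=100, seed=1,
    )
    traces, foci = mt.simulate_experiment(params, DT2MIN)
    return params, traces, foci


@pytest.fixture(scope="session")
def fine_dt_spans():
    """~5000 observed spans of Exp(40 s) foci imaged every 7.5 s, via the
    imaging pipeline on a single dense trace."""
    n = 5600
    rng = np.random.default_rng(99)
    onsets = np.sort(rng.uniform(0.0, 10.0 * n, size=n))
    trace = mt.LineageTrace(
        lineage_id=0, window_min=10.0 * n + 60.0, doubling_time_min=26.6,
        onset_times_min=onsets, unrepaired=np.zeros(n, bool),
        lifetimes_min=rng.exponential(40.0 / 60.0, size=n),
        q_state=np.zeros(n, np.int8),
    )
    foci = mt.apply_imaging(trace, mt.ImagingConfig(frame_interval_s=7.5))
    return foci
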