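import pytest
from hypothesis import settings

from tirsim.engine import SimConfig, run_simulation

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from tirsim.experiments import (build_model, delta_correlation,
                                extract_intervals)


@pytest.fixture(scope="session")
def cal():
    from tirsim.experiments import calibration
    return calibration()


def run_corr(name: str, sigma_global: float, sigma_local: float,
             n_runs: int, seed: int, duration: float = 1.2):
    """Monte-Carlo delta-correlation for one zoo model at one noise cell."""
    model = build_model(name).model_copy(deep=True)
    model.noise.sigma_global = sigma_global
    model.noise.sigma_local = sigma_local
    config = SimConfig(dt=0.001, duration=duration, seed=seed,
                       n_runs=n_runs, record_timeseries=False,
                       stop_when_quiescent=True)
    _, events = run_simulation(model, config)
    return delta_correlation(extract_intervals(events, model))
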