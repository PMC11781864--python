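import numpy as np
import pytest

from contextmod import (AnalysisConfig, SessionConfig, exemplar_spec,
                        generate_session, untuned_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_session():
    """A small mixed session reused by read-only tests: two tuned
    (context-invariant) units, one untuned, one near-silent."""
    config = SessionConfig(n_units=4, n_trials_encoding=12, n_trials_vp=10,
                           n_trials_recall=12, rng_seed=7)
    specs = [exemplar_spec(),
             exemplar_spec(tuned_identity=2),
             untuned_spec(),
             untuned_spec(baseline_rate=0.01)]
    return generate_session(config, specs)


def step_trace(cfg, intervals, high=30.0, low=0.0,
               span=(-1.0, 1.2)):
    """Build a RateTrace that is ``high`` inside the given time intervals
    and ``low`` elsewhere (bin centers on the standard 1 ms grid)."""
    from contextmod.responses import RateTrace
    dt = cfg.rate_dt
    n = int(round((span[1] - span[0]) / dt))
    times = span[0] + (np.arange(n) + 0.5) * dt
    rate = np.full(n, low)
    for a, b in intervals:
        rate[(times >= a) & (times < b)] = high
    return RateTrace(times=times, rate=rate, n_trials=1, kernel_sigma=cfg.kernel_sigma)
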