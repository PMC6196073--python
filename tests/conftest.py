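import numpy as np
import pytest

from oppokin.synthetic import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact but complete synthetic session: 2 participants x 12 tasks
    x 2 trials, default noise.  Session-scoped; treat as read-only."""
    cfg = SimConfig(seed=42, n_participants=2, trials_per_task=2)
    recs, manifest, truth = simulate_session(cfg)
    return cfg, recs, manifest, truth


@pytest.fixture(scope="session")
def small_results(small_session):
    from oppokin.pipeline import run_analyze

    _, recs, _, _ = small_session
    return run_analyze(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
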