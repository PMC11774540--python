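import dataclasses

import pytest

from groupitizing import default_params, simulate_experiment


@pytest.fixture(scope="session")
def small_trials():
    """Six simulated participants at calibrated defaults (shared, read-only)."""
    return simulate_experiment(default_params(), n_participants=6, seed=11)


@pytest.fixture(scope="session")
def clean_params():
    """Defaults without lapses (for parameter-recovery style checks)."""
    return dataclasses.replace(default_params(), lapse_rate=0.0)
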