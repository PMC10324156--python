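import pytest

from swdreduce import DesignConfig, SweepGrid, run_removal, run_sweep


@pytest.fixture(scope="session")
def trial_4x5_exchangeable():
    """4-cluster, 5-period trial; exchangeable ICC 0.14, 90 per cell."""
    return DesignConfig(T=5, m=90, rho=0.14, r=1.0, structure="exchangeable", effect_size=0.25)


@pytest.fixture(scope="session")
def trial_4x5_decay():
    """Same trial under discrete-time decay: ICC 0.15, CAC 0.95."""
    return DesignConfig(
        T=5, m=90, rho=0.15, r=0.95, structure="discrete_time_decay", effect_size=0.35
    )


@pytest.fixture(scope="session")
def large_decay():
    """9-cluster, 10-period trial; decay ICC 0.05, CAC 0.95, 50 per cell."""
    return DesignConfig(
        T=10, m=50, rho=0.05, r=0.95, structure="discrete_time_decay", effect_size=0.2
    )


@pytest.fixture(scope="session")
def trial_4x5_exchangeable_trace(trial_4x5_exchangeable):
    return run_removal(trial_4x5_exchangeable)


@pytest.fixture(scope="session")
def trial_4x5_decay_trace(trial_4x5_decay):
    return run_removal(trial_4x5_decay)


@pytest.fixture(scope="session")
def large_decay_trace(large_decay):
    return run_removal(large_decay)


@pytest.fixture(scope="session")
def full_sweep():
    """The default 36-configuration checkpoint sweep (shared; ~6 s)."""
    return run_sweep(SweepGrid())
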