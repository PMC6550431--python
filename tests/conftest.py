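import copy

import pytest

import her2ce as h


@pytest.fixture(scope="session")
def base():
    return h.builtin_base_case()


@pytest.fixture()
def base_copy(base):
    return copy.deepcopy(base)


@pytest.fixture(scope="session")
def base_microsim(base):
    """Full-size base-case run of all four arms, shared across tests.

    Seed is fixed once for the whole suite; every arm uses the same patient
    streams (common random numbers).
    """
    return {arm: h.simulate_arm(base, arm, n=10_000, seed=20_260_928) for arm in h.ARM_IDS}


@pytest.fixture(scope="session")
def base_trace(base):
    return {arm: h.trace_summary(base, arm) for arm in h.ARM_IDS}
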