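import dataclasses

import pytest

import kinestim as ks


@pytest.fixture(scope="session")
def default_protocol():
    return ks.StimProtocol()


@pytest.fixture(scope="session")
def small_protocol():
    """Four short blocks: keeps full-session tests fast."""
    return ks.StimProtocol(block_length=24)


@pytest.fixture(scope="session")
def noiseless_model():
    """All stochastic variation off except the decrement."""
    return ks.KinematicsModel(
        duration_sd=0.0, noise_cv=0.0, position_noise_sd=0.0
    )


@pytest.fixture(scope="session")
def small_session(small_protocol):
    """One noisy session under the small protocol, with ground truth."""
    targets = ks.synthetic_data.generate_target_sequence(
        small_protocol.n_blocks * small_protocol.block_length, seed=11
    )
    trace, truth = ks.synthetic_data.generate_kinematics(
        targets, ks.KinematicsModel(), small_protocol, seed=12
    )
    session = ks.closed_loop.run_closed_loop_session(
        trace, small_protocol, truth=truth
    )
    return trace, truth, session


@pytest.fixture(scope="session")
def full_session(default_protocol):
    """One noisy 4 x 96 session under the default protocol."""
    targets = ks.synthetic_data.generate_target_sequence(384, seed=21)
    trace, truth = ks.synthetic_data.generate_kinematics(
        targets, ks.KinematicsModel(), default_protocol, seed=22
    )
    session = ks.closed_loop.run_closed_loop_session(
        trace, default_protocol, truth=truth
    )
    return trace, truth, session


@pytest.fixture(scope="session")
def reinforced_model():
    return dataclasses.replace(ks.KinematicsModel(), reinforcement_delta=0.05)
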