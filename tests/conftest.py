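import numpy as np
import pytest

from clef import SignalTrace, SubjectModel, analyze_session, generate_session


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_session():
    """One moderate synthetic session shared (read-only) across tests."""
    subject = SubjectModel(subject_id="fix01", seed=3)
    return generate_session(subject, n_bar_bites=40, n_feeding_cycles=20, fs=2000.0)


@pytest.fixture(scope="session")
def small_result(small_session):
    s = small_session
    return analyze_session(s.emg, s.force, s.manifest)


def make_trace(samples, fs=1000.0, channel="emg", units="V", t0=0.0):
    return SignalTrace(np.asarray(samples, dtype=float), fs=fs, t0=t0, channel=channel, units=units)
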