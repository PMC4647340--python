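import numpy as np
import pytest

from gaitpipe.synthetic import NoiseLevels, SessionParams, generate_session


@pytest.fixture(scope="session")
def zero_noise_session():
    """In-memory synthetic session with no measurement noise."""
    params = SessionParams(noise=NoiseLevels.zero())
    truth, acqs = generate_session(None, params, seed=11, write=False)
    return params, truth, acqs


@pytest.fixture(scope="session")
def written_session(tmp_path_factory):
    """Synthetic session with realistic noise, written as C3D + configs."""
    root = tmp_path_factory.mktemp("session")
    params = SessionParams()
    truth, acqs = generate_session(root, params, seed=42, write=True)
    session_dir = root / "InputData" / params.subject / params.session
    return params, truth, acqs, session_dir


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
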