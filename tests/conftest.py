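import numpy as np
import pytest

from igreceptor import build_fixture, build_profiles


@pytest.fixture(scope="session")
def profiles3():
    """Three-family profile set at the default divergence."""
    return build_profiles(11, ["famA", "famB", "famC"])


@pytest.fixture(scope="session")
def default_bundle():
    """The default 77-ORF / 26-gene fixture (no reads)."""
    return build_fixture(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
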