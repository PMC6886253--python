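import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ppimm.fixtures import FixtureSpec, make_end_to_end_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """A small but fully wired fixture bundle shared across tests."""
    return make_end_to_end_fixture(
        FixtureSpec(n_proteins=40, length_range=(40, 80), p_in=0.5, p_out=0.02, seed=7)
    )


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return small_bundle.write(out)
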