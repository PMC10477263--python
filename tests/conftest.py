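import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cobbkit import phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def straight_case():
    """Straight spine: no curve, no shear — every inclination exactly 0."""
    params = phantom.PhantomParams(centerline_modes=[], endplate_shear_sd=0.0, seed=0)
    return phantom.generate_case(params, render=False)


@pytest.fixture()
def curved_case():
    """A generic S-curved phantom with shear noise."""
    params = phantom.PhantomParams(
        centerline_modes=[(32.0, 0.9, 0.4), (10.0, 2.0, 1.1)],
        endplate_shear_sd=1.5,
        seed=7,
    )
    return phantom.generate_case(params, render=False)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small rendered dataset shared by training-path tests."""
    from cobbkit.data import load_manifest

    root = tmp_path_factory.mktemp("phantom_ds")
    phantom.make_dataset(14, root / "ds", seed=11, split=(10, 2, 2))
    return load_manifest(root / "ds")
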