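import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from hrfcount import SceneParams, generate_bscan


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def clean_scene():
    """20 well-separated high-contrast foci, no confounders, speckle off."""
    params = SceneParams(n_foci=20, n_vessels=0, n_exudates=0,
                        speckle=False, seed=11)
    return generate_bscan(params)


@pytest.fixture(scope="session")
def exudate_scene():
    """5 foci plus 2 bright exudates, speckle off."""
    params = SceneParams(n_foci=5, n_vessels=0, n_exudates=2,
                        speckle=False, seed=11)
    return generate_bscan(params)


@pytest.fixture(scope="session")
def speckled_scene():
    return generate_bscan(SceneParams(seed=11))
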