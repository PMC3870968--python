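import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from plpmine import fixtures
from plpmine.engine import calibrate_evalues

CALIBRATION_N = 200
CALIBRATION_SEED = 11


def _ensure_calibrated(profile, seed):
    if profile.calibration is None:
        profile.calibration = calibrate_evalues(profile, CALIBRATION_N, 400, seed=seed)
    return profile


@pytest.fixture(scope="session")
def search_profile():
    """The packaged fold type I search profile, Gumbel-calibrated."""
    return _ensure_calibrated(fixtures.search_profile(), CALIBRATION_SEED)


@pytest.fixture(scope="session")
def scr_profile():
    return fixtures.scr_profile()


@pytest.fixture(scope="session")
def domain_library(search_profile):
    """Calibrated annotation library (PLP search profile + mini profiles)."""
    lib = {"PLP_typeI": search_profile}
    for i, label in enumerate(fixtures.AUX_LABELS):
        lib[label] = _ensure_calibrated(fixtures.aux_profile(label), CALIBRATION_SEED + 1 + i)
    return lib


@pytest.fixture(scope="session")
def family_profiles():
    return {f: fixtures.family_profile(f) for f in fixtures.FAMILIES}


@pytest.fixture(scope="session")
def references():
    return fixtures.reference_sequences()


@pytest.fixture()
def rng():
    return np.random.default_rng(20251231)
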