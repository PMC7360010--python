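import numpy as np
import pytest

import petlimit as pl
from petlimit.study import analyze_detection, quantify_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, shared (read-only) across tests."""
    return pl.generate_study(pl.StudyConfig(seed=1))


@pytest.fixture(scope="session")
def quantified_wells(default_study):
    return quantify_study(default_study)


@pytest.fixture(scope="session")
def detection_reports(quantified_wells):
    return {
        s: analyze_detection(quantified_wells, s) for s in ("petct", "petmri")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
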