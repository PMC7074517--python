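import numpy as np
import pytest

import fusionda as fd


@pytest.fixture(scope="session")
def default_panel():
    return fd.build_default_panel()


@pytest.fixture(scope="session")
def cohort28():
    """Default-sized cohort (16 cases / 12 controls), fixed seed."""
    return fd.generate_cohort(fd.CohortConfig(n_case=16, n_control=12, seed=7))


@pytest.fixture(scope="session")
def null_overrides(default_panel):
    """Effect overrides that equalize the arms of every discriminant analyte."""
    return {
        a.name: (a.control_median, a.control_iqr)
        for a in default_panel
        if a.discriminant
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
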