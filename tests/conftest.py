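import warnings

import pytest

from codtip.data_model import AnalysisConfig
from codtip.pipeline import analyse_table
from codtip.synthetic_data import make_tipping_fixture

warnings.filterwarnings("ignore", message="state coefficient omega1")
warnings.filterwarnings("ignore", message="constant covariate")


@pytest.fixture(scope="session")
def tipping_table():
    """The packaged 49-year tipping fixture (seed 7)."""
    return make_tipping_fixture(seed=7)


@pytest.fixture(scope="session")
def tipping_report(tipping_table):
    """Full three-stage analysis of the tipping fixture."""
    return analyse_table(tipping_table, AnalysisConfig(seed=7))


@pytest.fixture(scope="session")
def recovery_results():
    """Cusp parameter-recovery study (50 seeds, n = 500), shared between the
    recovery and model-selection checks."""
    from codtip.harness import cusp_recovery_study

    return cusp_recovery_study(n_seeds=50, n=500, seed=1)
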