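import dataclasses

import numpy as np
import pytest

from dopanet.config import AnalysisConfig, CohortConfig, ConsensusSettings
from dopanet.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve-subject cohort for fast pipeline-level tests."""
    cfg = dataclasses.replace(CohortConfig(), n_subjects=12, seed=123)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Full-size default cohort (51 subjects) with planted effects."""
    return simulate_cohort(CohortConfig(seed=5))


@pytest.fixture(scope="session")
def planted_report(planted_cohort):
    """Full analysis of the default cohort, data-driven network detection."""
    from dopanet.pipeline import run_analysis
    acfg = AnalysisConfig(network_detection="consensus",
                          consensus=ConsensusSettings(n_iter=200),
                          n_boot=999, seed=5)
    return run_analysis(planted_cohort, acfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
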