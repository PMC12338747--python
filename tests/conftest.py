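import pytest

from trioscope.pipeline import run_pipeline
from trioscope.simulate import study_preset, simulate_cohort


def small_config(seed: int = 7, n_families: int = 3):
    """A scaled-down preset for fast end-to-end tests."""
    cfg = study_preset(seed=seed)
    cfg.n_families = n_families
    cfg.confounders.recurrent_sites = 6.0
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_result(small_cohort):
    return run_pipeline(cohort=small_cohort)
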