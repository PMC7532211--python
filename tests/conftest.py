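import warnings

import pytest

from iraescreen.simulate import (
    CohortConfig,
    OmicsConfig,
    SimulationConfig,
)

# the generators warn about truncation-adjacent situations only in edge
# configurations; unit fixtures keep output quiet
warnings.filterwarnings("ignore", category=FutureWarning)


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A scaled-down simulation: 6 cancer types, small report volumes.

    Keeps unit tests fast while exercising every code path; the full-size
    reference configuration is reserved for the acceptance suite.
    """
    types = {"LUAD": 400, "SKCM": 300, "KIRC": 250, "COAD": 200,
             "GBM": 160, "UCS": 140}
    ror = {"LUAD": 3.3, "SKCM": 2.4, "KIRC": 1.8, "COAD": 1.2,
           "GBM": 0.9, "UCS": 0.65}
    defaults = dict(
        cancer_types=types,
        planted_ror=ror,
        comparator_size=4000,
        n_excluded_decoys=9,
        omics=OmicsConfig(n_null_features=40, samples_per_type=30),
        cohort=CohortConfig(),
    )
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)


@pytest.fixture
def config():
    return small_config()


@pytest.fixture
def report_frame(config):
    from iraescreen.simulate import gen_reports

    frame, truth = gen_reports(config)
    return frame, truth


@pytest.fixture
def omics_bundle(config):
    from iraescreen.simulate import gen_omics

    return gen_omics(config)
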