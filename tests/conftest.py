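import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from capnolung import (
    EstimatorConfig,
    SubjectParameters,
    VentilationPattern,
)
from capnolung.virtual_subject import initial_state, run_stream


@pytest.fixture
def params() -> SubjectParameters:
    return SubjectParameters()


@pytest.fixture
def pattern() -> VentilationPattern:
    return VentilationPattern.for_weight(24.0)


@pytest.fixture
def est_config(params) -> EstimatorConfig:
    return EstimatorConfig(hb=params.hb)


def stream_frame(records) -> pd.DataFrame:
    """Breath-record list -> estimator input frame."""
    return pd.DataFrame(
        {
            "breath_index": [r.index for r in records],
            "dt_min": [r.dt_min for r in records],
            "vtco2_l": [r.vtco2_l for r in records],
            "faco2": [r.faco2 for r in records],
        }
    )


@pytest.fixture
def constant_physiology_stream(params, pattern):
    """Noiseless breaths at fixed EPBF/CvCO2: exactly identifiable."""
    state = initial_state(params, pattern, 1.0)
    records, truth, state = run_stream(
        params, pattern, 45, state, venous_dynamics=False
    )
    return records, truth, state
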