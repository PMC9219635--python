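import logging

import numpy as np
import pytest

from anuran_erp.paradigm import (
    ReflexiveParams,
    VoluntaryParams,
    build_reflexive_schedule,
    build_voluntary_schedule,
)
from anuran_erp.synth import REGIONS, SubjectProfile

logging.getLogger("anuran_erp").setLevel(logging.ERROR)

STIMS = ("conspecific_call", "pure_tone", "screech_call", "white_noise")


def clean_profile(
    n1=-10.0,
    spn_slope=-2.0,
    noise_sd=0.0,
    artifact_rate=0.0,
    latency=70.0,
    subject_id=0,
    sex="female",
    **kw,
):
    """A deterministic subject with uniform injected component parameters."""
    return SubjectProfile(
        subject_id=subject_id,
        sex=sex,
        n1_amplitude_uV={(r, s): n1 for r in REGIONS for s in STIMS},
        spn_slope_uV_per_s={(r, s): spn_slope for r in REGIONS for s in STIMS},
        n1_latency_ms=latency,
        noise_sd_uV=noise_sd,
        artifact_rate=artifact_rate,
        **kw,
    )


@pytest.fixture
def tiny_voluntary():
    """One 3-cycle voluntary session without familiarization: 8 slots."""
    params = VoluntaryParams(familiarization_presentations=0, cycle_lengths=(3,), n_blocks=1)
    return build_voluntary_schedule("conspecific_call", params, seed=0)


@pytest.fixture
def small_voluntary():
    """A short multi-cycle session with familiarization."""
    params = VoluntaryParams(
        familiarization_presentations=4, cycle_lengths=(3, 4, 5, 6), n_blocks=2, break_ms=5000.0
    )
    return build_voluntary_schedule("pure_tone", params, seed=7)


@pytest.fixture
def small_reflexive():
    return build_reflexive_schedule("screech_call", ReflexiveParams(n_per_stimulus=20), seed=5)
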