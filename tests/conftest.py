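import numpy as np
import pytest
from hypothesis import settings

from lastseen import Gompertz, Weibull

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

# the study parameter sets: four aging strengths per family, three levels of
# the age-independent mortality term
WEIBULL_SHAPES = (1.25, 1.5, 2.0, 3.0)
GOMPERTZ_RATES = (0.05, 0.1, 0.2, 0.5)
M0_VALUES = (0.0, 0.2, 0.5)

STUDY_WEIBULL = [Weibull(m0=m0, b=1.0, c=c) for c in WEIBULL_SHAPES for m0 in M0_VALUES]
STUDY_GOMPERTZ = [Gompertz(m0=m0, theta=0.2, lam=lam) for lam in GOMPERTZ_RATES for m0 in M0_VALUES]
STUDY_MODELS = STUDY_WEIBULL + STUDY_GOMPERTZ
BASE_MODELS = [m for m in STUDY_MODELS if m.m0 == 0.0]


def model_id(model):
    if model.family == "weibull":
        return f"weibull-c{model.c}-m0{model.m0}"
    return f"gompertz-lam{model.lam}-m0{model.m0}"


@pytest.fixture
def rng():
    return np.random.default_rng(20220606)
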