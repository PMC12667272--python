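import numpy as np
import pytest

from diazoquant import LabelingEnvironment


@pytest.fixture
def env() -> LabelingEnvironment:
    """Study-condition labelling: a_N2=0.025, a_DIC=0.05, 1-day incubation."""
    return LabelingEnvironment(a_n2=0.025, a_dic=0.05, t_days=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
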