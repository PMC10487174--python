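import numpy as np
import pytest

from hi3.sart import CANONICAL_DIGITS, N_TRIALS, NOGO_DIGIT, SartSession


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_session(rt_on_go=400.0, rt_on_nogo=0.0, subject_id="s1") -> SartSession:
    """A complete canonical session with uniform reaction times per trial type."""
    digits = CANONICAL_DIGITS.copy()
    rt = np.where(digits == NOGO_DIGIT, rt_on_nogo, rt_on_go).astype(float)
    return SartSession(digits, rt, subject_id=subject_id)


@pytest.fixture
def perfect_session():
    """All GO trials answered, all NO-GO trials withheld."""
    return make_session(rt_on_go=400.0, rt_on_nogo=0.0)


@pytest.fixture
def nonresponsive_session():
    """No key press on any of the 207 trials."""
    return make_session(rt_on_go=0.0, rt_on_nogo=0.0)
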