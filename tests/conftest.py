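import numpy as np
import pytest

from platformtrial import EffectSpec, TrendSpec, TrialDesign


@pytest.fixture
def base_design() -> TrialDesign:
    """The study's reference design: K=1, n0=n1=550, add 275 at timing 0.5."""
    return TrialDesign(K=1, n_arm=(550, 550), timing=0.5, n_new=275)


@pytest.fixture
def small_design() -> TrialDesign:
    """A miniature design for fast Monte-Carlo checks."""
    return TrialDesign(K=1, n_arm=(40, 40), timing=0.5, n_new=20)


@pytest.fixture
def effects() -> EffectSpec:
    return EffectSpec.uniform(1, 0.15)


@pytest.fixture
def no_trend() -> TrendSpec:
    return TrendSpec("none")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_922)
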