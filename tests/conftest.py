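import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import promotif as pm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def uniform_bg():
    return pm.BackgroundModel.uniform()


@pytest.fixture
def sharp_pwm(uniform_bg):
    """A sharp 10-mer whose consensus is the unique maximum-score word."""
    pfm = pm.simulate_pwms(1, 10, 0.97, seed=11)[0]
    return pm.pfm_to_pwm(pfm, uniform_bg, 1.0)


def random_pfm(rng, length):
    counts = rng.integers(1, 30, size=(4, length)).astype(float)
    return pm.PositionFrequencyMatrix(f"RND{length}", f"rnd{length}", counts)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_hit(tf="TFX", gene="G1", start=-100, strand="+", tier="lenient",
             matrix=None, length=10, pvalue=None):
    end = start + length - 1
    if start < 0 <= end:
        end += 1
    if end == 0:
        end = 1
    return pm.MotifHit(
        matrix or f"MX_{tf}", tf, gene, start, end, strand, 10.0,
        pvalue if pvalue is not None else (1e-6 if tier == "stringent" else 3e-5),
        tier,
    )
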