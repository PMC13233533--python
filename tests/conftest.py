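import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from xdomcf import RatingMatrix, SyntheticConfig  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_matrix():
    """4 items x 3 participants, complete, raw monetary."""
    vals = np.array([[1.0, 2.0, 4.0],
                     [2.0, 1.0, 3.0],
                     [3.0, 4.0, 2.0],
                     [4.0, 3.0, 1.0]])
    return RatingMatrix(vals, ["i1", "i2", "i3", "i4"], ["p1", "p2", "p3"],
                        "art", "raw_monetary")


@pytest.fixture
def small_cfg():
    """Reduced cohort for fast end-to-end runs."""
    return SyntheticConfig(
        n_participants=12, n_male=5,
        items_per_domain={"art": 80, "face_male": 40, "face_female": 40, "scene": 80},
        rank_block=40, seed=0)


def normalized_random(rng, m=20, n=5, domain="art"):
    """Helper: random z-scored matrix."""
    from xdomcf import zscore_normalize
    vals = rng.standard_normal((m, n))
    rm = RatingMatrix(vals, [f"i{k}" for k in range(m)],
                      [f"p{k}" for k in range(n)], domain, "raw_monetary")
    return zscore_normalize(rm)
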