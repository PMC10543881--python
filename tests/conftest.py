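import numpy as np
import pytest

from fraglift.io_profiles import FragmentProfile, LengthHistogram, normalize
from fraglift.synthetic import SimConfig, mixture_density


@pytest.fixture
def small_sim_config() -> SimConfig:
    """Down-scaled fragment budget for fast histogram simulation."""
    return SimConfig(n_fragments=100_000)


@pytest.fixture
def healthy_profile() -> FragmentProfile:
    """Noise-free profile of a tumour-free sample (exact mixture density)."""
    return profile_from_density(0.0)


@pytest.fixture
def tumour_profile() -> FragmentProfile:
    return profile_from_density(0.4)


def profile_from_density(theta: float, config: SimConfig | None = None):
    """Exact (infinite-depth) fragment profile at tumour fraction theta."""
    config = config or SimConfig()
    p = mixture_density(theta, config)
    p = p / p.sum()
    return FragmentProfile(
        sample_id=f"exact-{theta}",
        support=config.support,
        p=p,
        logp=np.log(p),
        pseudocount=0.0,
    )


def profile_from_logp(logp: np.ndarray, support=(50, 400)) -> FragmentProfile:
    """Build a profile with a prescribed logp shape (shifted to normalize).

    Adding a constant to logp corresponds to rescaling p, so the shape of
    logp is preserved up to that constant.
    """
    lo, hi = support
    assert logp.size == hi - lo + 1
    p = np.exp(logp - logp.max())
    p = p / p.sum()
    return FragmentProfile(
        sample_id="synthetic-logp",
        support=support,
        p=p,
        logp=np.log(p),
        pseudocount=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
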