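import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_pole(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def view_pole(config, rng: np.random.Generator) -> np.ndarray:
    """Viewing pole rule used by the pipeline (chain middle / plaque
    centre / random for isotropic classes)."""
    if config.pattern_class == "associated_chain":
        return config.centers[config.n_domains // 2]
    if config.pattern_class == "associated_plaque":
        return config.centers[0]
    return random_pole(rng)


@pytest.fixture
def hexagon_with_center() -> np.ndarray:
    """Perfect planar hexagon of unit circumradius plus its centre."""
    angles = np.arange(6) * np.pi / 3.0
    ring = np.column_stack([np.cos(angles), np.sin(angles)])
    return np.vstack([[0.0, 0.0], ring])


@pytest.fixture
def small_lattice():
    from vesiclepatterns import synth

    return synth.make_lattice(30, 0.17, 12.0, jitter=0.03, seed=3)
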