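import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from endplate.profiles import Profile
from endplate.synthetic import SyntheticEndplateSpec, generate_surface

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def semicircle() -> Profile:
    """Lower semicircle of radius 5 between (-5, 0) and (5, 0)."""
    th = np.linspace(np.pi, 2 * np.pi, 721)
    s, h = 5 * np.cos(th), 5 * np.sin(th)
    order = np.argsort(s)
    return Profile(s[order], h[order], plane="sagittal")


@pytest.fixture
def parabola() -> Profile:
    """h(s) = -2 (1 - (s/10)^2) on [-10, 10]: chord 20, depth 2."""
    s = np.linspace(-10, 10, 401)
    return Profile(s, -2 * (1 - (s / 10) ** 2), plane="sagittal")


@pytest.fixture(scope="session")
def uniform_surface():
    """Noise-free uniform-concave plate, sagittal depth 2, coronal flat."""
    spec = SyntheticEndplateSpec(depth_sagittal=2.0, depth_coronal=0.0,
                                 shape_class_coronal="flat")
    return spec, generate_surface(spec)


@pytest.fixture(scope="session")
def biconcave_surface():
    """Noise-free plate with sagittal depth 2 and coronal depth 3."""
    spec = SyntheticEndplateSpec(depth_sagittal=2.0, depth_coronal=3.0)
    return spec, generate_surface(spec)
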