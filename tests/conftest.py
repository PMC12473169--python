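import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def hemisphere_sections():
    """Noiseless six-section acquisition of a 10 mm hemisphere."""
    from hemisurf.phantom import AcquisitionPlan, hemisphere, sample_sections

    return sample_sections(hemisphere(10.0), AcquisitionPlan())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def poly_surface_sections():
    """Sections sampled exactly from a low-degree polynomial surface."""
    from hemisurf.io import RadialSection, SectionSet

    def f(x, y):
        return 2.0 + 0.5 * y - x**2 + 0.01 * x**3 * y**2

    xs = np.linspace(-5, 5, 25)
    secs = tuple(
        RadialSection(angle=a, xs=xs, zs=f(xs, a))
        for a in np.arange(6) * np.pi / 6
    )
    return SectionSet(sections=secs), f
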