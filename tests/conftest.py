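import numpy as np
import pytest

from mnphotodose import (
    ArrayGeometry,
    EmitterDisk,
    RenderSpec,
    render_angle_set,
    sample_profiles,
    summarize,
)


@pytest.fixture(scope="session")
def geometry():
    return ArrayGeometry()


@pytest.fixture(scope="session")
def unit_disk():
    """R = σ = I0 = r0 = 1, no attenuation."""
    return EmitterDisk(R=1.0, sigma=1.0, I0=1.0, r0=1.0, alpha=0.0)


@pytest.fixture(scope="session")
def default_spec(geometry):
    return RenderSpec(geometry=geometry, seed=123)


@pytest.fixture(scope="session")
def rendered_set(default_spec):
    """One seeded default angle set (0, 24, 31, 57, 77 deg), rendered once."""
    return render_angle_set(default_spec)


@pytest.fixture(scope="session")
def angle_summaries(rendered_set, default_spec):
    """Central-window summaries for the resolvable angles of the default set."""
    from mnphotodose import UnresolvableProjectionError

    summaries = []
    for img in rendered_set:
        rng = np.random.default_rng([456, int(img.angle_deg)])
        try:
            line = sample_profiles(img, default_spec.geometry, "line", rng=rng)
            mn = sample_profiles(img, default_spec.geometry, "MN", rng=rng)
        except UnresolvableProjectionError:
            continue
        summaries.append(summarize(line, mn))
    return summaries
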