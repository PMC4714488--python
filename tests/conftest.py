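import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fermiperf as fp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """Single-slice, coarse phantom: fast to fit, still realistic geometry."""
    return fp.PhantomSpec(
        shape=(48, 48),
        pixel_spacing_mm=1.8,
        slice_labels=("mid",),
        endo_radii_mm=(16.0,),
        epi_radii_mm=(25.0,),
        n_frames=40,
        seed=42,
    )


@pytest.fixture(scope="session")
def aif_curve():
    return fp.generate_aif(fp.AifSpec(), 60, 1.0)


def conv_double_sum(aif, h, dt):
    """Independent O(n^2) causal rectangle-rule convolution oracle."""
    n = len(aif)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(i + 1):
            acc += aif[j] * h[i - j]
        out[i] = acc * dt
    return out
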