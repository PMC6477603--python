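import numpy as np
import pytest

from spatula import (
    LayerSpec,
    RoughSurface,
    SpectrumSpec,
    build_kernel,
    generate_heightfield,
)


@pytest.fixture(scope="session")
def spec_small():
    """Desk-scale roughness recipe on a 128 grid: lambda_s=4a, lambda_r=32a."""
    return SpectrumSpec.from_wavelengths(32.0, 4.0, 0.8)


@pytest.fixture(scope="session")
def surface128(spec_small):
    return generate_heightfield(spec_small, 128, 1.0, seed=3)


@pytest.fixture(scope="session")
def halfspace_kernel128():
    return build_kernel(LayerSpec.half_space(1.0), 128, 1.0)


@pytest.fixture()
def flat64():
    return RoughSurface(heights=np.zeros((64, 64)), spacing=1.0)


def cosine_substrate(n=128, waves=4, h0=0.05, spacing=1.0):
    """Single-mode substrate h = h0 (cos(qx) - 1): max 0, analytic oracles."""
    x = np.arange(n) * spacing
    q = 2 * np.pi * waves / (n * spacing)
    h = h0 * (np.cos(q * x)[:, None] * np.ones((1, n)) - 1.0)
    return RoughSurface(heights=h, spacing=spacing), q, h0
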