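import numpy as np
import pytest

from meibseg import (PhantomSpec, builtin_style, generate_dataset,
                     generate_phantom)


@pytest.fixture(scope="session")
def style_a():
    return builtin_style("deviceA")


@pytest.fixture(scope="session")
def style_b():
    return builtin_style("deviceB")


@pytest.fixture(scope="session")
def phantom(style_a):
    return generate_phantom(PhantomSpec(atrophy_frac=0.3, seed=5), style_a)


@pytest.fixture(scope="session")
def small_phantom(style_a):
    """A 64x64 phantom for fast geometric tests."""
    return generate_phantom(
        PhantomSpec(height=64, width=64, n_glands=6, atrophy_frac=0.25, seed=2),
        style_a)


@pytest.fixture(scope="session")
def phantom_pool_a(style_a):
    return generate_dataset(20, None, style_a, seed=11)


@pytest.fixture(scope="session")
def phantom_pool_b(style_b):
    return generate_dataset(20, None, style_b, seed=12)
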