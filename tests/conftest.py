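"""Shared fixtures: small synthetic genomes sized for fast IR detection."""

import numpy as np
import pytest

from plastrep import CassetteParams, Scenario, SynthConfig, generate_plastome


def small_config(seed=0, **kwargs):
    """Reduced genome (19.5 kb) with the same quadripartite structure as a
    full plastome; IR detection is size-independent."""
    defaults = dict(seed=seed, lsc_len=9_000, ssc_len=2_500, ir_len=4_000)
    defaults.update(kwargs)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_genome():
    return generate_plastome(small_config(seed=42))


@pytest.fixture(scope="session")
def full_size_genome():
    """One genome at realistic plastome scale (157 kb)."""
    return generate_plastome(SynthConfig(seed=1, lsc_len=85_000,
                                         ssc_len=18_000, ir_len=27_000))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
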