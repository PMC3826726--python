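"""Shared fixtures: all data is generated programmatically at test time."""

import numpy as np
import pytest

from mgescan import SimConfig, default_config, simulate_strain_pair
from mgescan.synthetic import ImplantSpec, random_dna


@pytest.fixture(scope="session")
def cohort_pair():
    """Full default strain pair (seven elements per strain)."""
    return simulate_strain_pair(default_config(seed=1))


@pytest.fixture(scope="session")
def small_pair():
    """Fast two-element pair on a 300-kb chromosome."""
    cfg = SimConfig(
        seed=11,
        replicons=(("chromosome", 300_000, "linear", 0.61),),
        implants=(
            ImplantSpec("ice", "ICE", 30_000, 77, 46, "CAT"),
            ImplantSpec("gi", "GI", 12_000, 77, 77, "CCG", strains=("A",)),
        ),
        orthologs=tuple(),
        unique_a=0, unique_b=0,
    )
    return simulate_strain_pair(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_seq(rng):
    return random_dna(rng, 5000, 0.5)
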