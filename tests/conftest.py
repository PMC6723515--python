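"""Shared fixtures: the echinoderm code and ready-made S/L gene pairs."""

import numpy as np
import pytest

from stopswitch.mito_translate import load_code
from stopswitch.synth import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def echinoderm():
    return load_code("echinoderm_mt")


@pytest.fixture(scope="session")
def standard_code():
    return load_code("standard")


def make_sl_pair(seed: int = 0, **overrides):
    """One (s_region, l_region) pair from the default gene geometry.

    Zero substitution rate by default so the pair differs only at the
    focal base.
    """
    cfg = SimulationConfig(
        seed=seed, n_taxa=3, subst_rate=overrides.pop("subst_rate", 0.0),
        scenario="persistence", **overrides,
    )
    ds = generate_dataset(cfg)
    for regions in ds.cds_by_taxon.values():
        if len(regions) == 2:
            return regions[0], regions[1]
    raise AssertionError("no polymorphic taxon in the dataset")


@pytest.fixture(scope="session")
def sl_pair():
    return make_sl_pair(seed=0)


@pytest.fixture(scope="session")
def default_dataset():
    """A persistence dataset at the default study conditions."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
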