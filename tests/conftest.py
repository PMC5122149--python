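"""Shared fixtures: small simulated datasets reused across test modules.

Everything is generated programmatically at test time; module/session
scoping keeps the expensive bootstrap-bearing fixtures to one build each.
"""

import numpy as np
import pytest

from chsphylo.simulate import (EventRates, FixtureConfig, generate_class_dataset,
                               generate_dataset)


@pytest.fixture(scope="session")
def std_dataset():
    """Standard two-group dataset: 12 taxa, 3 planted transfers, CDS with
    donor/host G+C contrast, co-transferred operon, outgroup pair."""
    return generate_dataset(FixtureConfig(n_forced_hgt=3), 2024)


@pytest.fixture(scope="session")
def dup_dataset():
    """Dataset with duplications and losses on top of the transfers."""
    cfg = FixtureConfig(rates=EventRates(duplication_rate=0.6,
                                         loss_rate=0.15),
                        n_forced_hgt=2, n_decayed=3)
    return generate_dataset(cfg, 77)


@pytest.fixture(scope="session")
def class_dataset():
    """Three planted classes at >=0.4 between / <=0.1 within divergence."""
    return generate_class_dataset(FixtureConfig(), 31, n_classes=3,
                                  within_depth=0.05, between_stem=0.2)


@pytest.fixture(scope="session")
def two_family_dataset():
    """Two families (CHS-like vs HAS-like) plus outgroup, for chimera work."""
    return generate_class_dataset(FixtureConfig(), 57, n_classes=2,
                                  within_depth=0.05, between_stem=0.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
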