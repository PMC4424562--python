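"""Shared synthetic fixtures (generated at test time; nothing on disk)."""

from __future__ import annotations

import numpy as np
import pytest

from epiremodel import simulate as sim

SEED = 11


@pytest.fixture(scope="session")
def genome():
    return sim.make_genome(seed=SEED)


@pytest.fixture(scope="session")
def truth(genome):
    return sim.make_truth(genome, seed=SEED + 1)


@pytest.fixture(scope="session")
def samples():
    return sim.default_sample_sheet()


@pytest.fixture(scope="session")
def mbd_counts(genome, samples, truth):
    return sim.simulate_mbd_counts(genome, samples, truth, seed=SEED + 2)


@pytest.fixture(scope="session")
def chip_samples():
    return sim.chip_sample_sheet()


@pytest.fixture(scope="session")
def chip_data(genome, chip_samples, truth):
    return sim.simulate_chip_counts(genome, chip_samples, truth, seed=SEED + 3)


@pytest.fixture(scope="session")
def expression(genome, chip_samples, truth):
    return sim.simulate_expression(genome, chip_samples, truth, seed=SEED + 4)


@pytest.fixture(scope="session")
def probe_layout(genome):
    return sim.make_probe_layout(genome, seed=SEED + 5)


@pytest.fixture(scope="session")
def beta_data(probe_layout, truth):
    return sim.simulate_beta_matrix(probe_layout, truth, seed=SEED + 6)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
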