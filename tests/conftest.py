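"""Shared fixtures: named synthetic datasets and a small bank of trained models."""

import numpy as np
import pytest

from rbpsvm import simulate as sim
from rbpsvm import svm as svm_mod
from rbpsvm.kernel import KernelConfig


@pytest.fixture(scope="session")
def separable_fixture():
    return sim.make_fixture("separable")


@pytest.fixture(scope="session")
def imbalanced_fixture():
    return sim.make_fixture("imbalanced-15pct")


@pytest.fixture(scope="session")
def null_fixture():
    return sim.make_fixture("null")


@pytest.fixture(scope="session")
def disorder_fixture():
    return sim.make_fixture("disorder-toy")


@pytest.fixture(scope="session")
def curation_fixture():
    return sim.make_fixture("curation-toy")


@pytest.fixture(scope="session")
def small_planted():
    """A small, quickly trainable planted-signal dataset (60 + 140)."""
    config = sim.SimConfig(
        n_pos=60,
        n_neg=140,
        planted_pos_kmers=sim.POS_KMERS,
        lambda_pos=20.0,
        planted_neg_kmers=sim.NEG_KMERS,
        lambda_neg=20.0,
        length_range=(50, 300),
        seed=401,
    )
    records, truth, _ = sim.generate(config)
    return records, truth


@pytest.fixture(scope="session")
def toy_model(small_planted):
    """One representative trained model (k=3, normalized, class-weighted)."""
    records, _ = small_planted
    return svm_mod.train(
        records, KernelConfig(k=3), cost=1.0, weights=(1.8, 0.2), seed=0
    )


@pytest.fixture(scope="session")
def model_bank(small_planted):
    """Models across kernel settings for the dual-feasibility / Eq-reconstruction sweeps."""
    records, _ = small_planted
    bank = []
    for k, normalized, cost, weights in [
        (2, True, 1.0, (1.0, 1.0)),
        (3, True, 1.0, (1.8, 0.2)),
        (3, False, 0.5, (1.0, 0.1)),
        (3, True, 10.0, (1.4, 0.5)),
    ]:
        model = svm_mod.train(
            records,
            KernelConfig(k=k, normalized=normalized),
            cost=cost,
            weights=weights,
            seed=0,
        )
        bank.append((model, records))
    return bank


@pytest.fixture(scope="session")
def heldout_sequences():
    """50 unlabeled sequences never seen by any trained model."""
    records, _, _ = sim.generate(
        sim.SimConfig(n_pos=25, n_neg=25, length_range=(50, 300), seed=777)
    )
    return [r.sequence for r in records]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
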