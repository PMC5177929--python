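import numpy as np
import pytest

from stressmir.structure import EnergyModel, WATSON_CRICK_WOBBLE, energy_of_structure


@pytest.fixture(scope="session")
def energy_model():
    return EnergyModel.default()


def enumerate_structures(seq):
    """Yield every properly nested pairing of ``seq`` (min hairpin loop 3).

    Independent brute-force generator used as the folding oracle.
    """

    def gen(i, limit):
        if i >= limit:
            yield []
            return
        for rest in gen(i + 1, limit):
            yield rest
        for j in range(i + 4, limit):
            if seq[i] + seq[j] in WATSON_CRICK_WOBBLE:
                for inner in gen(i + 1, j):
                    for rest in gen(j + 1, limit):
                        yield [(i, j)] + inner + rest

    yield from gen(0, len(seq))


def brute_force_mfe(seq, model):
    """Exhaustive minimum over all nested structures (oracle for fold_mfe)."""
    best = 0.0
    for pairs in enumerate_structures(seq):
        e = energy_of_structure(seq, pairs, model)
        if e < best:
            best = e
    return best


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A compact simulated study shared by integration-style unit tests."""
    from stressmir.simulate import simulate_study

    out = tmp_path_factory.mktemp("study")
    return simulate_study(
        out, n_mirnas=8, n_rfam=10, n_chloro=10, n_sirna=20, seed=123,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
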