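import math

import pytest

import alchex as ax


@pytest.fixture(scope="session")
def harmonic_pair():
    return ax.make_harmonic_ladder(3, 1.0, math.e ** 2, 300.0, seed=11)


@pytest.fixture(scope="session")
def lj_pair():
    return ax.make_lj_mutation(2, 0.03, 0.0, 0.0, seed=7)


@pytest.fixture(scope="session")
def double_well_pair():
    return ax.make_double_well_mutation(4.5, 5.0, 300.0, seed=3)


@pytest.fixture(scope="session")
def insertion_pair():
    return ax.make_insertion_mutation(3, seed=5)


@pytest.fixture(scope="session")
def charge_pair():
    base = ax.make_lj_mutation(3, 0.0, 0.0, -1.0, seed=9)
    return ax.make_charge_change_mutation(base, 1.0)


@pytest.fixture(scope="session")
def harmonic_hybrid(harmonic_pair):
    return ax.build_hybrid(harmonic_pair)


@pytest.fixture(scope="session")
def insertion_hybrid(insertion_pair):
    return ax.build_hybrid(insertion_pair)


@pytest.fixture(scope="session")
def harmonic_record(harmonic_hybrid):
    """Short AREX run on the harmonic ladder, shared by estimation and
    diagnostics tests."""
    return ax.run_arex(harmonic_hybrid, ax.LambdaProtocol.linear(6),
                       ax.AlchemicalParams(), n_iterations=200,
                       steps_per_iteration=15, temperature=300.0, seed=21)


def random_configuration(hybrid, rng, scale=0.08):
    return hybrid.positions0 + rng.normal(0.0, scale, size=(hybrid.n_atoms, 3))
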