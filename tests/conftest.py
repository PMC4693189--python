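import numpy as np
import pytest
import scipy.sparse as sp

from diufba import (DiurnalConfig, MetabolicNetwork, Phase, build_toy_model,
                    scenario)


@pytest.fixture
def scenario1():
    return scenario(1)


@pytest.fixture
def scenario2():
    return scenario(2)


@pytest.fixture
def toy1(scenario1):
    """(network, config) for the reference 1 h / 1 h scenario."""
    return build_toy_model(scenario1)


@pytest.fixture
def toy2(scenario2):
    return build_toy_model(scenario2)


@pytest.fixture
def tiny_network():
    """Single irreversible reaction A -> B."""
    return MetabolicNetwork(
        species_ids=["A", "B"],
        reaction_ids=["R1"],
        stoich=sp.csc_matrix(np.array([[-1.0], [1.0]])),
        lb=np.array([0.0]), ub=np.array([10.0]),
        objective_coeffs=np.array([1.0]))


def random_network(rng: np.random.Generator, n_species: int = 4,
                   n_internal: int = 5) -> MetabolicNetwork:
    """A small random network with one bounded import and one export per
    species plus random internal conversions.  All bounds are finite and
    contain zero, so every phase FBA is feasible and bounded."""
    species = [f"M{i}" for i in range(n_species)]
    rids, lbs, ubs, cols = [], [], [], []
    mat = sp.dok_matrix((n_species, 2 * n_species + n_internal))
    j = 0
    for i in range(n_species):
        mat[i, j] = 1.0
        rids.append(f"EX_in_{i}")
        lbs.append(0.0)
        ubs.append(float(rng.uniform(0.5, 3.0)))
        j += 1
        mat[i, j] = -1.0
        rids.append(f"EX_out_{i}")
        lbs.append(0.0)
        ubs.append(10.0)
        j += 1
    for k in range(n_internal):
        a, b = rng.choice(n_species, size=2, replace=False)
        mat[a, j] = -1.0
        mat[b, j] = float(rng.uniform(0.3, 1.0))
        rids.append(f"R{k}")
        lbs.append(0.0)
        ubs.append(10.0)
        j += 1
    return MetabolicNetwork(
        species_ids=species, reaction_ids=rids, stoich=mat.tocsc(),
        lb=np.array(lbs), ub=np.array(ubs),
        objective_coeffs=np.zeros(len(rids)))


def two_phase_config(objective_reaction: str) -> DiurnalConfig:
    """Decoupled (no carry-over) two-phase config with unit durations and
    the same per-phase objective reaction."""
    return DiurnalConfig(
        phases=[Phase("light", 1.0), Phase("dark", 1.0)],
        carryover_species=[],
        exportable_species=[],
        objective={("light", objective_reaction): 1.0,
                   ("dark", objective_reaction): 1.0})
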