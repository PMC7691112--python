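"""Shared fixtures: small hand-built trees and a reusable mid-size
synthetic species with its clonal and recombining simulations."""

import pytest

from corephylo import SimConfig, evolve, random_species, read_newick


@pytest.fixture
def quartet_tree():
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def five_leaf_tree():
    # unrooted shape (AB)(CD)E
    return read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")


@pytest.fixture(scope="session")
def species20():
    """20-taxon synthetic species, low divergence, resolvable topology."""
    return random_species(
        seed=1301, n=20, length=50_000, divergence=0.015, min_internal_branch=0.005
    )


@pytest.fixture(scope="session")
def clonal_result(species20):
    return evolve(
        SimConfig(tree=species20.tree, params=species20.params, rho=0.0, rng_seed=42)
    )


@pytest.fixture(scope="session")
def recombining_result(species20):
    return evolve(
        SimConfig(tree=species20.tree, params=species20.params, rho=1.0, rng_seed=42)
    )
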