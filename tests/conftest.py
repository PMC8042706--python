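import numpy as np
import pytest

from ohnoshift.synthetic import SimConfig, make_roles, simulate_cohort, simulate_species_tree


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_singleton_trees=12, n_ohnolog_trees=24)


@pytest.fixture(scope="session")
def species_tree(small_config):
    return simulate_species_tree(small_config)


@pytest.fixture(scope="session")
def roles(small_config):
    return make_roles(small_config)


@pytest.fixture(scope="session")
def cohort(small_config):
    return simulate_cohort(small_config)


def random_newick(rng: np.random.Generator, n_tips: int, prefix: str = "T") -> str:
    """Random rooted binary tree with uniform-ish branch lengths, built by
    sequential joining (independent of the package's tree builders)."""
    nodes = [f"{prefix}{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.05, 1.5, size=2)
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"
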