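import pytest

from coextinct import (
    HostParasiteNetwork,
    SynthConfig,
    Tree,
    simulate_network,
    simulate_tree,
)


@pytest.fixture
def toy_tree():
    """3-tip tree ((A:1,B:1):2,C:3): the worked example used throughout."""
    return Tree.from_newick("((A:1,B:1):2,C:3);")


@pytest.fixture
def toy_net(toy_tree):
    attrs = {
        "A": {"iucn_status": "LC", "domesticated": False, "extinct": False},
        "B": {"iucn_status": "EN", "domesticated": False, "extinct": False},
        "C": {"iucn_status": "LC", "domesticated": False, "extinct": False},
    }
    return HostParasiteNetwork(
        {"P1": frozenset({"A", "B", "C"}), "P2": frozenset({"C"})}, attrs
    )


def random_tree(seed, n_tips=None, death=0.0):
    """Seeded birth-death tree helper shared across test modules."""
    import random

    if n_tips is None:
        n_tips = random.Random(seed).randint(4, 60)
    cfg = SynthConfig(
        n_tips=n_tips,
        tree_model="birth_death" if death > 0 else "yule",
        death_rate=death,
        seed=seed,
    )
    return simulate_tree(cfg)


def random_network(seed, n_tips=10, n_parasites=8, phi=2.0):
    cfg = SynthConfig(
        n_tips=n_tips, n_parasites=n_parasites, phi=phi, seed=seed
    )
    tree = simulate_tree(cfg)
    return tree, simulate_network(tree, cfg)
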