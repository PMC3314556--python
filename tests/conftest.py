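import random

import pytest

from magscreen import PresenceProfile, parse_newick
from magscreen.synthetic import build_actinobacteria_fixture, simulate_species_tree


@pytest.fixture(scope="session")
def mscl_fixture():
    """186-tip Actinobacterial tree with the mscL absence pattern."""
    return build_actinobacteria_fixture()


@pytest.fixture
def cherry():
    return parse_newick("(A,B);")


@pytest.fixture
def caterpillar6():
    return parse_newick("(((((A,B),C),D),E),F);")


def random_profile(tree, rng: random.Random, gene_id: str = "g") -> PresenceProfile:
    """Random nonempty possessor set over a tree's tips."""
    tips = tree.tip_ids()
    k = rng.randint(1, len(tips))
    return PresenceProfile(gene_id, frozenset(rng.sample(tips, k)), tuple(tips))


def random_tree(rng: random.Random, max_tips: int = 50):
    n = rng.randint(4, max_tips)
    return simulate_species_tree(n, seed=rng.randrange(2**31))
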