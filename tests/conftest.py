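import numpy as np
import pytest

from paleorange.characters import BiomeRegionSpace, DiscreteCharacterData, StateSpace
from paleorange.geography import EpochGraphStack
from paleorange.trees import read_tree


@pytest.fixture
def three_tip_tree():
    return read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_tree():
    return read_tree("(((A:1,B:1):2,C:3):2,(D:4,E:4):1);")


@pytest.fixture
def abc_space():
    return StateSpace(["X", "Y", "Z"])


@pytest.fixture
def two_epoch_stack(abc_space):
    """2 epochs x 3 states, fully connected in all dispersal modes."""
    full = 1 - np.eye(3, dtype=np.uint8)
    feats = {m: np.stack([full, full]) for m in ("short", "medium", "long")}
    return EpochGraphStack(space=abc_space, boundaries=[100.0, 50.0, 0.0],
                           features=feats)


@pytest.fixture
def small_br_space():
    return BiomeRegionSpace(("tropical", "warm-temperate"), ("R1", "R2"))


def random_tree(rng, n_tips, scale=1.0):
    """Random coalescent-ish ultrametric tree for randomized suites."""
    from paleorange.simulate import simulate_tree
    return simulate_tree(0.5 / scale, 0.0, n_tips, rng)


def enumerate_loglik(tree, data, process, root_freqs=None):
    """Brute-force likelihood: sum over all internal-state assignments.

    Independent of the pruning implementation: walks every combination
    of internal node states and multiplies per-branch transition
    probabilities from per-branch matrix products.
    """
    import itertools

    S = process.n_states
    pi = (np.full(S, 1.0 / S) if root_freqs is None
          else np.asarray(root_freqs, float) / np.sum(root_freqs))
    tips = tree.tips()
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    P = {v: process.branch_matrix(float(tree.ages[tree.parent[v]]),
                                  float(tree.ages[v]))
         for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    tip_sets = {t: sorted(data[tree.labels[t]]) for t in tips}
    total = 0.0
    for assign in itertools.product(range(S), repeat=len(internals)):
        states = dict(zip(internals, assign))
        for tip_combo in itertools.product(*(tip_sets[t] for t in tips)):
            states.update(dict(zip(tips, tip_combo)))
            p = pi[states[tree.root]]
            for v in range(tree.n_nodes):
                if tree.parent[v] >= 0:
                    p *= P[v][states[tree.parent[v]], states[v]]
            total += p
    return np.log(total) if total > 0 else -np.inf
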