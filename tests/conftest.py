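"""Shared fixtures and independent oracles (brute-force enumeration)."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gaptree import trees
from gaptree.gap_coding import CharacterDescriptor, GapCharacterMatrix
from gaptree.likelihood import cfn_prob, discrete_gamma_rates


def binary_matrix(taxa, rows) -> GapCharacterMatrix:
    """Build a GapCharacterMatrix from per-taxon state rows (0/1/-1)."""
    states = np.array(rows, dtype=np.int8)
    chars = [CharacterDescriptor(None, j, j + 1, 1) for j in range(states.shape[1])]
    return GapCharacterMatrix(list(taxa), chars, states)


def brute_force_fitch(tree: trees.Tree, states: dict[str, int | None], n_states: int = 2) -> int:
    """Minimum changes over all internal-node state assignments (oracle
    for Fitch; missing tips contribute nothing)."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    best = 10**9
    for labelling in itertools.product(range(n_states), repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), labelling))
        cost = 0
        for n in tree.postorder():
            if n.parent is None:
                continue
            parent_state = assign[id(n.parent)]
            if n.is_leaf:
                s = states[n.label]
                if s is None:
                    continue
            else:
                s = assign[id(n)]
            cost += s != parent_state
        best = min(best, cost)
    return best


def brute_force_cfn_likelihood(tree: trees.Tree, states: dict[str, int], gamma_shape=None, ncat=4) -> float:
    """Likelihood of one binary character by summing over all ancestral
    state assignments, averaged over discrete-Γ categories."""
    rates = (
        discrete_gamma_rates(gamma_shape, ncat) if gamma_shape is not None else np.ones(1)
    )
    internals = [n for n in tree.postorder() if not n.is_leaf]
    total = 0.0
    for rate in rates:
        acc = 0.0
        for labelling in itertools.product((0, 1), repeat=len(internals)):
            assign = dict(zip((id(n) for n in internals), labelling))
            p = 0.5
            for n in tree.postorder():
                if n.parent is None:
                    continue
                sp = assign[id(n.parent)]
                P = cfn_prob(n.length * rate)
                if n.is_leaf:
                    s = states[n.label]
                    if s == -1:
                        continue
                    p *= P[sp, s]
                else:
                    p *= P[sp, assign[id(n)]]
            acc += p
        total += acc / len(rates)
    return total


def min_max_steps_over_trees(taxa, states_row) -> tuple[int, int]:
    """(min, max) Fitch steps of one character over every binary topology
    (oracle for the retention-index bounds)."""
    lo, hi = 10**9, -1
    smap = {t: (None if s == -1 else int(s)) for t, s in zip(taxa, states_row)}
    for topo in trees.enumerate_topologies(list(taxa)):
        steps = brute_force_fitch(topo, smap)
        lo, hi = min(lo, steps), max(hi, steps)
    return lo, hi


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tree5():
    return trees.parse_newick("((a:0.1,b:0.2):0.15,(c:0.1,d:0.3):0.05,e:0.2);")


@pytest.fixture(scope="session")
def fixture_suite():
    from gaptree.synthetic_data import make_fixture_suite

    return make_fixture_suite(seed=11)
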