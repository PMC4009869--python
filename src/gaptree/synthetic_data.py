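"""Sequence simulation with substitutions and indels on a known tree.

The simulator emulates the statistical structure of large non-coding
nuclear alignments: indel events roughly an order of magnitude rarer than
substitutions, an excess of 1-bp indels over longer ones (geometric length
distribution), a bias of deletions over insertions, and lineage-specific
rate multipliers shared between the substitution and indel processes so
that fast lineages are fast for both.

Homology is tracked exactly: every inserted column receives a globally
unique identifier, so the emitted alignment is the *true* alignment
(independent insertions never share a column) and every gap span descends
from logged deletion events or from absence of an insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .gap_coding import CharacterDescriptor, GapCharacterMatrix, simple_indel_coding
from .io_formats import Alignment
from .likelihood import ModelSpec, _gtr_eigen, cfn_prob, discrete_gamma_rates
from .trees import Tree, unroot, yule_tree

_BASES = "ACGT"


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study-like defaults: indel events at one tenth the substitution
    rate, deletions twice as common as insertions, geometric indel lengths
    with mean ~1.7 columns, and moderate lineage rate heterogeneity."""

    tree: Tree
    substitution_model: ModelSpec = field(default_factory=lambda: ModelSpec("gtr"))
    indel_rate_ratio: float = 0.1
    deletion_bias: float = 2.0
    length_geometric_p: float = 0.6
    lineage_rate_sd: float = 0.3
    root_length: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.indel_rate_ratio < 0:
            raise SimulationError("indel_rate_ratio must be >= 0")
        if self.deletion_bias < 1:
            raise SimulationError("deletion_bias must be >= 1 (deletions at least as common)")
        if not (0 < self.length_geometric_p <= 1):
            raise SimulationError("length_geometric_p must be in (0, 1]")
        if self.root_length < 1:
            raise SimulationError("root_length must be >= 1")
        if self.lineage_rate_sd < 0:
            raise SimulationError("lineage_rate_sd must be >= 0")


@dataclass
class SimulationResult:
    alignment: Alignment
    tree: Tree
    events: pd.DataFrame
    edge_rate_multipliers: dict[str, float]


def simulate_evolution(config: SimulationConfig) -> SimulationResult:
    """Evolve a sequence down ``config.tree``.

    Substitutions and indels compete as exponential processes along each
    edge; the edge length (expected substitutions per site) is scaled by a
    lognormal lineage multiplier applied to both processes.
    """
    rng = np.random.default_rng(config.seed)
    tree = unroot(config.tree.copy())
    model = config.substitution_model
    if model.family != "gtr":
        raise SimulationError("sequence simulation requires a gtr-family model")
    freqs = model.frequencies()
    lam, right, left = _gtr_eigen(model)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    Q = np.zeros((4, 4))
    for (i, j), s in zip(pairs, model.exchangeabilities()):
        Q[i, j] = s * freqs[j]
        Q[j, i] = s * freqs[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -(freqs * np.diag(Q)).sum()
    leave_rate = -np.diag(Q)

    next_id = [config.root_length]
    global_order: list[int] = list(range(config.root_length))
    root_bases = rng.choice(4, size=config.root_length, p=freqs)
    root_seq = list(zip(range(config.root_length), (int(b) for b in root_bases)))

    events: list[dict] = []
    multipliers: dict[str, float] = {}
    node_names: dict[int, str] = {}
    counter = [0]

    def name_of(node) -> str:
        if id(node) not in node_names:
            if node.is_leaf:
                node_names[id(node)] = node.label
            else:
                node_names[id(node)] = f"node{counter[0]}"
                counter[0] += 1
        return node_names[id(node)]

    def evolve_edge(seq: list[tuple[int, int]], node) -> list[tuple[int, int]]:
        seq = list(seq)
        mult = (
            float(rng.lognormal(-0.5 * config.lineage_rate_sd**2, config.lineage_rate_sd))
            if config.lineage_rate_sd > 0
            else 1.0
        )
        edge = name_of(node)
        multipliers[edge] = mult
        tau = node.length * mult
        elapsed = 0.0
        while True:
            if not seq:
                raise SimulationError(
                    "all sites deleted; reduce rates or increase root_length"
                )
            bases = np.array([b for _, b in seq])
            site_rates = leave_rate[bases]
            r_sub = float(site_rates.sum())
            r_indel = config.indel_rate_ratio * len(seq)
            total = r_sub + r_indel
            elapsed += rng.exponential(1.0 / total)
            if elapsed >= tau:
                break
            if rng.random() < r_sub / total:
                site = int(rng.choice(len(seq), p=site_rates / r_sub))
                b = seq[site][1]
                probs = Q[b].copy()
                probs[b] = 0.0
                new = int(rng.choice(4, p=probs / probs.sum()))
                seq[site] = (seq[site][0], new)
                continue
            length = int(rng.geometric(config.length_geometric_p))
            if rng.random() < config.deletion_bias / (1.0 + config.deletion_bias):
                start = int(rng.integers(len(seq)))
                removed = seq[start : start + length]
                del seq[start : start + length]
                events.append(
                    {
                        "edge": edge,
                        "type": "deletion",
                        "length": len(removed),
                        "columns": tuple(cid for cid, _ in removed),
                    }
                )
            else:
                pos = int(rng.integers(len(seq) + 1))
                new_ids = list(range(next_id[0], next_id[0] + length))
                next_id[0] += length
                new_bases = rng.choice(4, size=length, p=freqs)
                if pos == 0:
                    anchor = global_order.index(seq[0][0])
                else:
                    anchor = global_order.index(seq[pos - 1][0]) + 1
                global_order[anchor:anchor] = new_ids
                seq[pos:pos] = list(zip(new_ids, (int(b) for b in new_bases)))
                events.append(
                    {
                        "edge": edge,
                        "type": "insertion",
                        "length": length,
                        "columns": tuple(new_ids),
                    }
                )
        return seq

    leaf_seqs: dict[str, dict[int, int]] = {}

    def recurse(node, seq):
        if node.is_leaf:
            leaf_seqs[node.label] = dict(seq)
            return
        for child in node.children:
            recurse(child, evolve_edge(seq, child))

    recurse(tree.root, root_seq)

    present = [
        cid for cid in global_order if any(cid in s for s in leaf_seqs.values())
    ]
    taxa = sorted(leaf_seqs)
    rows = []
    for t in taxa:
        s = leaf_seqs[t]
        rows.append("".join(_BASES[s[cid]] if cid in s else "-" for cid in present))
    alignment = Alignment(taxa, rows, {"locus1": (0, len(present))})
    return SimulationResult(
        alignment,
        tree,
        pd.DataFrame(events, columns=["edge", "type", "length", "columns"]),
        multipliers,
    )


def simulate_binary_characters(
    tree: Tree,
    n_characters: int,
    seed: int = 0,
    variable_only: bool = True,
    gamma_shape: Optional[float] = None,
    informative_only: bool = False,
    n_informative: Optional[int] = None,
) -> GapCharacterMatrix:
    """Simulate binary characters directly under the CFN model on a fixed
    tree, optionally conditioned on being variable (the acquisition regime
    of gap characters) or parsimony-informative.

    ``n_informative`` keeps generating (conditioned) characters until the
    matrix contains that many parsimony-informative ones — the natural way
    to emulate a gap matrix quoted by its informative count, which also
    carries its share of autapomorphic characters."""
    rng = np.random.default_rng(seed)
    tree = unroot(tree)
    taxa = tree.taxa
    leaves = {id(n): n.label for n in tree.leaves()}
    columns: list[dict[str, int]] = []
    edge_nodes = [n for n in tree.preorder() if n.parent is not None]
    got_informative = 0

    def done() -> bool:
        if n_informative is not None:
            return got_informative >= n_informative
        return len(columns) >= n_characters

    while not done():
        rate = (
            float(rng.gamma(gamma_shape, 1.0 / gamma_shape))
            if gamma_shape is not None
            else 1.0
        )
        assign = {id(tree.root): int(rng.random() < 0.5)}
        for node in edge_nodes:
            sp = assign[id(node.parent)]
            p_same = (1.0 + np.exp(-2.0 * node.length * rate)) / 2.0
            assign[id(node)] = sp if rng.random() < p_same else 1 - sp
        states = {leaves[k]: v for k, v in assign.items() if k in leaves}
        ones = sum(states.values())
        if variable_only and ones in (0, len(taxa)):
            continue
        if informative_only and (ones < 2 or len(taxa) - ones < 2):
            continue
        columns.append(states)
        got_informative += 2 <= ones <= len(taxa) - 2
    chars = [CharacterDescriptor(None, j, j + 1, 1) for j in range(len(columns))]
    states = np.array(
        [[col[t] for col in columns] for t in taxa], dtype=np.int8
    )
    return GapCharacterMatrix(taxa, chars, states)


# ---------------------------------------------------------------------------
# fixtures


SIC_TOY_ALIGNMENT = Alignment(
    ["s1", "s2", "s3", "s4"],
    ["ACCGTA", "AC--TA", "A---TA", "ACCGTA"],
)


def make_fixture_suite(seed: int = 0) -> dict:
    """Deterministic small datasets with known truth:

    a. the hand-workable simple-indel-coding toy alignment;
    b. an 8-taxon variable-only binary matrix with its generating tree;
    c. a two-partition nucleotide+gap fixture from the full simulator;
    d. a matrix pair with unequal informative-character counts.
    """
    rng = np.random.default_rng(seed)
    taxa8 = [f"t{i}" for i in range(8)]
    true_tree = unroot(yule_tree(taxa8, rng, mean_edge=0.15))
    # recovery experiments need resolvable internal edges
    for e in true_tree.edges():
        e.length = max(e.length, 0.05)

    binary = simulate_binary_characters(
        true_tree,
        2000,
        seed=int(rng.integers(2**31 - 1)),
        variable_only=True,
        n_informative=2000,
    )

    sim = simulate_evolution(
        SimulationConfig(
            tree=true_tree,
            root_length=1500,
            seed=int(rng.integers(2**31 - 1)),
        )
    )
    gap_matrix = simple_indel_coding(sim.alignment)

    n_info = (binary.states == 1).sum()
    small = binary.subset(np.sort(rng.choice(binary.n_characters, size=binary.n_characters // 2, replace=False)))

    return {
        "sic_toy": {
            "alignment": SIC_TOY_ALIGNMENT,
            "expected_characters": [(1, 4), (2, 4)],
            "expected_states": {
                (2, 4): {"s1": 0, "s2": 1, "s3": -1, "s4": 0},
                (1, 4): {"s1": 0, "s2": 0, "s3": 1, "s4": 0},
            },
        },
        "binary_recovery": {"matrix": binary, "true_tree": true_tree},
        "combined": {
            "alignment": sim.alignment,
            "gap_matrix": gap_matrix,
            "true_tree": true_tree,
            "events": sim.events,
        },
        "jackknife_pair": {"large": binary, "small": small},
        "seed": seed,
    }
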