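"""Parsimony scoring, ratchet search, bootstrap and homoplasy indices.

Characters are scored with Fitch's algorithm, vectorised over characters
with bitmask state sets (missing data = the full state set).  Tree search
is hill climbing by nearest-neighbour interchange (optionally plus
subtree-prune-regraft), escaped from local optima by the parsimony
ratchet: alternate rounds in which a random subset of the informative
characters is upweighted (weight 2) with rounds under the original
weights, keeping the best equal-weight trees seen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .gap_coding import GapCharacterMatrix, informative_indices
from .io_formats import Alignment
from .trees import Tree, nni_neighbors, random_topology, spr_neighbors, star_tree, unroot

CharacterData = Union[GapCharacterMatrix, Alignment]

_IUPAC_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8, "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "-": 15, "?": 15,
}


def state_sets(data: CharacterData) -> tuple[list[str], np.ndarray]:
    """Bitmask state-set encoding (taxa x characters) for Fitch scoring.

    Binary matrices use bits {1,2}; nucleotide alignments use 4 bits with
    ambiguity codes expanded and gap/missing as the full set.
    """
    if isinstance(data, GapCharacterMatrix):
        sets = np.where(
            data.states == -1, 3, np.where(data.states == 1, 2, 1)
        ).astype(np.uint8)
        return list(data.taxa), sets
    sets = np.array(
        [[_IUPAC_MASK[c] for c in seq] for seq in data.sequences], dtype=np.uint8
    )
    if sets.size == 0:
        sets = sets.reshape(len(data.taxa), 0)
    return list(data.taxa), sets


def _fitch_steps(tree: Tree, taxa: list[str], sets: np.ndarray) -> np.ndarray:
    """Per-character minimum state changes on ``tree`` (Fitch)."""
    index = {t: i for i, t in enumerate(taxa)}
    nchar = sets.shape[1]
    steps = np.zeros(nchar, dtype=np.int64)

    def rec(node):
        if node.is_leaf:
            try:
                return sets[index[node.label]]
            except KeyError:
                raise ValueError(f"tip {node.label!r} absent from matrix") from None
        acc = rec(node.children[0])
        for child in node.children[1:]:
            other = rec(child)
            inter = acc & other
            empty = inter == 0
            steps[empty] += 1
            acc = np.where(empty, acc | other, inter)
        return acc

    rec(tree.root)
    return steps


def fitch_length(tree: Tree, data: CharacterData, character_index: int) -> int:
    """Minimum number of changes for one character on a fixed tree."""
    taxa, sets = state_sets(data)
    column = sets[:, [character_index]]
    if (column == column.max()).all() and column.max() in (3, 15):
        warnings.warn("character is entirely missing; 0 steps")
    return int(_fitch_steps(tree, taxa, column)[0])


def treelength(
    tree: Tree, data: CharacterData, weights: Optional[np.ndarray] = None
) -> int:
    """Sum of Fitch lengths over characters (optionally weighted)."""
    taxa, sets = state_sets(data)
    steps = _fitch_steps(tree, taxa, sets)
    if weights is None:
        return int(steps.sum())
    return int((steps * weights).sum())


@dataclass
class RatchetConfig:
    iterations: int = 100
    perturb_fraction: float = 0.2
    trees_held_per_iteration: int = 1
    swap: str = "nni"
    seed: int = 0
    max_trees_held: int = 50

    def __post_init__(self):
        if not (0 < self.perturb_fraction < 1):
            raise ValueError("perturb_fraction must be in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.swap not in ("nni", "spr"):
            raise ValueError("swap must be 'nni' or 'spr'")


@dataclass
class SearchResult:
    trees: list[Tree]
    length: int

    @property
    def tree(self) -> Tree:
        return self.trees[0]


def _neighbors(tree: Tree, swap: str) -> Iterable[Tree]:
    yield from nni_neighbors(tree)
    if swap == "spr":
        yield from spr_neighbors(tree)


def _hill_climb(
    tree: Tree, taxa: list[str], sets: np.ndarray, weights: np.ndarray, swap: str
) -> tuple[Tree, int]:
    current = unroot(tree)
    current_len = int((_fitch_steps(current, taxa, sets) * weights).sum())
    while True:
        best, best_len = None, current_len
        for nb in _neighbors(current, swap):
            ln = int((_fitch_steps(nb, taxa, sets) * weights).sum())
            if ln < best_len:
                best, best_len = nb, ln
        if best is None:
            return current, current_len
        current, current_len = best, best_len


def ratchet_search(
    data: CharacterData,
    config: Optional[RatchetConfig] = None,
    start_tree: Optional[Tree] = None,
) -> SearchResult:
    """Parsimony ratchet: perturbed-weight and equal-weight hill-climbing
    rounds, keeping all distinct topologies at the best equal-weight length.
    Deterministic given ``config.seed``."""
    config = config or RatchetConfig()
    taxa, sets = state_sets(data)
    rng = np.random.default_rng(config.seed)
    equal = np.ones(sets.shape[1], dtype=np.int64)

    if len(taxa) < 4:
        tree = star_tree(taxa)
        return SearchResult([tree], int(_fitch_steps(tree, taxa, sets).sum()))

    if isinstance(data, GapCharacterMatrix):
        informative = informative_indices(data)
    else:
        informative = _informative_columns(sets)
    if informative.size == 0:
        informative = np.arange(sets.shape[1])

    current = start_tree.copy() if start_tree is not None else random_topology(taxa, rng)
    current, current_len = _hill_climb(current, taxa, sets, equal, config.swap)
    best_len = current_len
    best: dict[frozenset, Tree] = {current.canonical_topology(): current}

    n_perturb = max(1, round(config.perturb_fraction * informative.size))
    for _ in range(config.iterations):
        weights = equal.copy()
        chosen = rng.choice(informative, size=n_perturb, replace=False)
        weights[chosen] = 2
        perturbed, _ = _hill_climb(current, taxa, sets, weights, config.swap)
        candidate, cand_len = _hill_climb(perturbed, taxa, sets, equal, config.swap)
        if cand_len < best_len:
            best_len = cand_len
            best = {candidate.canonical_topology(): candidate}
        elif cand_len == best_len and len(best) < config.max_trees_held:
            best.setdefault(candidate.canonical_topology(), candidate)
        current = candidate
    return SearchResult(list(best.values()), best_len)


def _informative_columns(sets: np.ndarray) -> np.ndarray:
    """Columns where >= 2 unambiguous states each occur in >= 2 taxa."""
    out = []
    for j in range(sets.shape[1]):
        col = sets[:, j]
        counts = [(col == 1 << b).sum() for b in range(4)]
        if sum(1 for c in counts if c >= 2) >= 2:
            out.append(j)
    return np.array(out, dtype=int)


def mp_bootstrap(
    data: CharacterData,
    replicates: int,
    config: Optional[RatchetConfig] = None,
    seed: Optional[int] = None,
):
    """Nonparametric bootstrap under the parsimony criterion.

    Characters are resampled with replacement; each replicate is analysed
    with the ratchet and contributes the majority-rule consensus of its
    best trees; returns bipartition frequencies."""
    from .treecompare import SupportTable
    from .trees import majority_rule_bipartitions

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config = config or RatchetConfig(iterations=5)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    nchar = (
        data.n_characters if isinstance(data, GapCharacterMatrix) else data.n_columns
    )
    taxa_set = None
    for rep in range(replicates):
        idx = rng.integers(0, nchar, size=nchar)
        resampled = _resample(data, idx)
        rep_config = RatchetConfig(
            iterations=config.iterations,
            perturb_fraction=config.perturb_fraction,
            swap=config.swap,
            seed=int(rng.integers(2**31 - 1)),
            max_trees_held=config.max_trees_held,
        )
        result = ratchet_search(resampled, rep_config)
        taxa_set = set(result.tree.taxa)
        for b in majority_rule_bipartitions(result.trees):
            counts[b] = counts.get(b, 0) + 1
    support = {b: c / replicates for b, c in counts.items()}
    return SupportTable(
        support,
        taxa=frozenset(taxa_set or []),
        provenance={"method": "mp_bootstrap", "replicates": replicates, "seed": seed},
    )


def _resample(data: CharacterData, idx: np.ndarray) -> CharacterData:
    if isinstance(data, GapCharacterMatrix):
        return GapCharacterMatrix(
            list(data.taxa),
            [data.characters[i] for i in idx],
            data.states[:, idx],
        )
    return data.subset_columns(list(idx))


# ---------------------------------------------------------------------------
# homoplasy


@dataclass
class HomoplasyIndices:
    per_character: pd.DataFrame
    ensemble_ci: Optional[float]
    ensemble_ri: Optional[float]
    n_excluded: int


def _minmax_steps(sets_col: np.ndarray) -> tuple[int, int]:
    """(s_min, g): minimum steps on any tree and maximum (star-tree) steps
    for one character, from unambiguous state counts."""
    col = sets_col[np.isin(sets_col, [1, 2, 4, 8])]
    if col.size == 0:
        return 0, 0
    counts = np.array([(col == 1 << b).sum() for b in range(4)])
    observed = counts[counts > 0]
    s_min = len(observed) - 1
    g = int(col.size - observed.max())
    return s_min, g


def homoplasy_indices(tree: Tree, data: CharacterData) -> HomoplasyIndices:
    """Per-character and ensemble consistency/retention indices on a fixed
    tree.  Characters with ``g == s_min`` carry no homoplasy information and
    are excluded from the ensemble sums."""
    taxa, sets = state_sets(data)
    steps = _fitch_steps(tree, taxa, sets)
    rows = []
    for j in range(sets.shape[1]):
        s_min, g = _minmax_steps(sets[:, j])
        s = int(steps[j])
        ci = s_min / s if s > 0 else np.nan
        ri = (g - s) / (g - s_min) if g > s_min else np.nan
        rows.append((j, s, s_min, g, ci, ri))
    table = pd.DataFrame(
        rows, columns=["character", "s", "s_min", "g", "ci", "ri"]
    )
    included = table[table.g > table.s_min]
    n_excluded = len(table) - len(included)
    if included.empty or included.s.sum() == 0:
        warnings.warn("no characters with potential homoplasy; ensemble indices undefined")
        return HomoplasyIndices(table, None, None, n_excluded)
    ens_ci = float(included.s_min.sum() / included.s.sum())
    ens_ri = float(
        (included.g.sum() - included.s.sum())
        / (included.g.sum() - included.s_min.sum())
    )
    return HomoplasyIndices(table, ens_ci, ens_ri, n_excluded)
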