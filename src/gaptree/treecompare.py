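"""Congruence and information-content measures between trees and datasets.

Bipartitions are stored canonically as the tip block not containing the
alphabetically first taxon.  Support tables map bipartitions to bootstrap
proportions in [0, 1]; a bipartition absent from a table has support 0
(an unresolved clade lends no support).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .gap_coding import GapCharacterMatrix, informative_indices
from .io_formats import Alignment
from .trees import Tree, TreeError, robinson_foulds as _rf

CharacterData = Union[GapCharacterMatrix, Alignment]

Bipartition = frozenset  # canonical tip block


@dataclass
class SupportTable:
    """Bipartition -> bootstrap proportion, with provenance."""

    support: dict[Bipartition, float]
    taxa: frozenset[str] = frozenset()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = {b: v for b, v in self.support.items() if not (0 <= v <= 1)}
        if bad:
            raise ValueError(f"support values outside [0,1]: {bad}")

    def get(self, bipartition: Bipartition) -> float:
        return self.support.get(bipartition, 0.0)

    def bipartitions(self) -> set[Bipartition]:
        return set(self.support)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two trees' internal-edge bipartition sets."""
    return _rf(t1, t2)


def compare_support(
    a: SupportTable,
    b: SupportTable,
    high: float = 0.70,
    low: float = 0.50,
) -> pd.DataFrame:
    """Classify every bipartition in either table by the well-supported /
    poorly-supported thresholds (>=high in one and <low in the other)."""
    if a.taxa and b.taxa and a.taxa != b.taxa:
        raise TreeError("support tables cover different tip sets")
    rows = []
    for bip in sorted(a.bipartitions() | b.bipartitions(), key=sorted):
        sa, sb = a.get(bip), b.get(bip)
        if sa >= high and sb < low:
            cls = "a-high-b-low"
        elif sb >= high and sa < low:
            cls = "b-high-a-low"
        elif sa >= high and sb >= high:
            cls = "concordant"
        else:
            cls = "neither"
        rows.append(
            {
                "bipartition": "|".join(sorted(bip)),
                "support_a": sa,
                "support_b": sb,
                "class": cls,
            }
        )
    return pd.DataFrame(rows, columns=["bipartition", "support_a", "support_b", "class"])


def _count_informative(data: CharacterData) -> int:
    if isinstance(data, GapCharacterMatrix):
        return int(informative_indices(data).size)
    from .parsimony import state_sets, _informative_columns

    _, sets = state_sets(data)
    return int(_informative_columns(sets).size)


def jackknife_equalized_support(
    large: CharacterData,
    small: CharacterData,
    bootstrap_fn: Callable[[CharacterData, int], SupportTable],
    n_jackknife: int = 100,
    seed: int = 0,
) -> SupportTable:
    """Average bootstrap support of the larger matrix after equalising its
    number of parsimony-informative characters to the smaller's.

    Each jackknife pseudomatrix keeps all uninformative characters and a
    without-replacement subsample of the informative ones; every
    pseudomatrix is bootstrapped with ``bootstrap_fn(data, seed)`` and the
    per-bipartition supports are averaged."""
    n_large = _count_informative(large)
    n_small = _count_informative(small)
    if n_large < n_small:
        raise ValueError(
            f"larger matrix has fewer informative characters ({n_large} < {n_small})"
        )
    rng = np.random.default_rng(seed)
    if n_large == n_small:
        import warnings

        warnings.warn("equal informative counts; plain bootstrap of the larger matrix")
        # seed passed through unchanged: this degenerate case must equal
        # the plain bootstrap exactly
        return bootstrap_fn(large, seed)
    if not isinstance(large, GapCharacterMatrix):
        raise NotImplementedError("jackknife equalisation requires a character matrix")
    informative = informative_indices(large)
    uninformative = np.setdiff1d(np.arange(large.n_characters), informative)
    totals: dict[Bipartition, float] = {}
    taxa = frozenset(large.taxa)
    for _ in range(n_jackknife):
        keep = rng.choice(informative, size=n_small, replace=False)
        idx = np.sort(np.concatenate([uninformative, keep]))
        pseudo = large.subset(idx)
        table = bootstrap_fn(pseudo, int(rng.integers(2**31 - 1)))
        for bip, val in table.support.items():
            totals[bip] = totals.get(bip, 0.0) + val
    support = {b: v / n_jackknife for b, v in totals.items()}
    return SupportTable(
        support,
        taxa=taxa,
        provenance={"method": "jackknife_equalized", "n_jackknife": n_jackknife, "seed": seed},
    )


def gap_rate_convert(
    gap_tree: Tree, n_gap_characters_including_invariants: int, n_nucleotide_sites: int
) -> Tree:
    """Rescale branch lengths from changes per gap character (including the
    augmented invariant characters) to gap changes per nucleotide site:
    multiply by the gap-matrix size and divide by the nucleotide-matrix
    size."""
    if n_gap_characters_including_invariants <= 0 or n_nucleotide_sites <= 0:
        raise ValueError("matrix sizes must be positive")
    return gap_tree.scale_lengths(
        n_gap_characters_including_invariants / n_nucleotide_sites
    )


@dataclass
class BranchLengthComparison:
    pairs: pd.DataFrame
    correlation: Optional[float]
    n_unmatched: int


def branch_length_compare(tA: Tree, tB: Tree) -> BranchLengthComparison:
    """Pair branch lengths of two trees edge-by-edge (edges matched by
    bipartition, tip edges by tip label) and report a Spearman rank
    correlation.  Edges present in only one tree are counted, not paired."""
    if set(tA.taxa) != set(tB.taxa):
        raise TreeError("tip sets differ")

    def edge_lengths(tree: Tree) -> dict:
        all_taxa = frozenset(tree.taxa)
        ref = min(all_taxa)
        out = {}
        below: dict[int, frozenset] = {}
        for n in tree.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.label])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
            if n.parent is None:
                continue
            block = below[id(n)]
            side = block if ref not in block else all_taxa - block
            if 0 < len(side) < len(all_taxa):
                out[side] = out.get(side, 0.0) + n.length
        return out

    ea, eb = edge_lengths(tA), edge_lengths(tB)
    shared = sorted(set(ea) & set(eb), key=sorted)
    n_unmatched = len(set(ea) ^ set(eb))
    pairs = pd.DataFrame(
        {
            "bipartition": ["|".join(sorted(b)) for b in shared],
            "length_a": [ea[b] for b in shared],
            "length_b": [eb[b] for b in shared],
        }
    )
    import warnings

    n_tips = len(tA.taxa)
    internal = [b for b in shared if 1 < len(b) < n_tips - 1]
    if not internal:
        warnings.warn("no shared internal edges; correlation over tip edges only")
    if len(pairs) < 3:
        warnings.warn("too few shared edges; correlation undefined")
        return BranchLengthComparison(pairs, None, n_unmatched)
    rho = stats.spearmanr(pairs.length_a, pairs.length_b).statistic
    if not np.isfinite(rho):
        warnings.warn("degenerate branch lengths; correlation undefined")
        return BranchLengthComparison(pairs, None, n_unmatched)
    return BranchLengthComparison(pairs, float(rho), n_unmatched)
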