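"""Lightweight phylogenetic tree structure shared by all analysis modules.

Trees are held rooted for traversal but interpreted as unrooted topologies:
the root is an arbitrary internal node (a trifurcation for a fully resolved
unrooted binary tree) and every comparison (bipartitions, canonical forms,
Robinson-Foulds) is rooting-invariant.  Branch lengths are expected changes
per character.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional, Sequence

import dendropy


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, {self.length:g}, {len(self.children)} ch)"


class Tree:
    """Tip-labelled branching structure with non-negative branch lengths.

    ``had_missing_lengths`` is set by the Newick parser when one or more
    edges carried no length annotation (they default to 0).
    """

    def __init__(self, root: Node, had_missing_lengths: bool = False):
        self.root = root
        self.had_missing_lengths = had_missing_lengths
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a Newick string; absent branch lengths default to 0."""
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"Newick parse failure: {exc}") from exc
        missing = False

        def convert(dnode) -> Node:
            nonlocal missing
            label = dnode.taxon.label if dnode.taxon is not None else None
            length = dnode.edge.length
            if length is None:
                length = 0.0
                if dnode.parent_node is not None:
                    missing = True
            node = Node(label, length)
            for dchild in dnode.child_nodes():
                node.add(convert(dchild))
            return node

        tree = cls(convert(dtree.seed_node), had_missing_lengths=missing)
        tree.suppress_unifurcations()
        return tree

    def copy(self) -> "Tree":
        def dup(n: Node) -> Node:
            m = Node(n.label, n.length)
            for c in n.children:
                m.add(dup(c))
            return m

        return Tree(dup(self.root), self.had_missing_lengths)

    # -- invariants --------------------------------------------------------

    def _validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate tip labels")
        if any(not lab for lab in labels):
            raise TreeError("empty tip label")
        for n in self.postorder():
            if n.length < 0:
                raise TreeError(f"negative branch length on {n.label or 'internal'}")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return sorted(n.label for n in self.leaves())

    def n_tips(self) -> int:
        return len(self.leaves())

    def edges(self) -> list[Node]:
        """Every non-root node identifies the edge to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    def total_length(self) -> float:
        return sum(n.length for n in self.edges())

    def scale_lengths(self, factor: float) -> "Tree":
        out = self.copy()
        for n in out.edges():
            n.length *= factor
        return out

    # -- topology manipulation --------------------------------------------

    def suppress_unifurcations(self) -> None:
        """Collapse degree-2 nodes (merging edge lengths)."""
        changed = True
        while changed:
            changed = False
            for n in list(self.postorder()):
                if n.parent is not None and len(n.children) == 1:
                    child = n.children[0]
                    child.length += n.length
                    parent = n.parent
                    idx = parent.children.index(n)
                    parent.children[idx] = child
                    child.parent = parent
                    changed = True
            if len(self.root.children) == 1 and not self.root.is_leaf:
                old = self.root
                self.root = old.children[0]
                self.root.parent = None
                self.root.length = 0.0
                changed = True

    def reroot_at(self, node: Node) -> None:
        """Make ``node`` the traversal root without changing the unrooted
        topology or any path length.  ``node`` must be internal."""
        if node is self.root:
            return
        if node.is_leaf:
            raise TreeError("cannot root at a leaf")
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        # edge child->parent keeps its length after the flip
        lengths = [n.length for n in path]
        for i, (child, parent) in enumerate(zip(path[:-1], path[1:])):
            parent.children.remove(child)
            child.add(parent)
            parent.length = lengths[i]
        node.parent = None
        node.length = 0.0
        self.root = node
        self.suppress_unifurcations()

    # -- serialization -----------------------------------------------------

    def newick(self, include_lengths: bool = True, precision: int = 10) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                core = _quote_label(n.label)
            else:
                core = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if include_lengths and n.parent is not None:
                core += f":{n.length:.{precision}g}"
            return core

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.n_tips()} tips)"

    # -- bipartitions ------------------------------------------------------

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Unrooted bipartitions, each stored as the tip block NOT containing
        the alphabetically first taxon (canonical form)."""
        all_taxa = frozenset(self.taxa)
        ref = min(all_taxa)
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                block = frozenset([n.label])
            else:
                block = frozenset().union(*(below[id(c)] for c in n.children))
            below[id(n)] = block
            if n.parent is None:
                continue
            side = block if ref not in block else all_taxa - block
            if len(side) == 0 or len(side) == len(all_taxa):
                continue
            trivial = len(side) == 1 or len(side) == len(all_taxa) - 1
            if trivial and not include_trivial:
                continue
            out.add(side)
        return out

    def canonical_topology(self) -> frozenset[frozenset[str]]:
        """Rooting-invariant topology identifier."""
        return frozenset(self.bipartitions()) | frozenset(
            frozenset([t]) for t in self.taxa
        )

    def is_same_topology(self, other: "Tree") -> bool:
        return (
            set(self.taxa) == set(other.taxa)
            and self.bipartitions() == other.bipartitions()
        )


def _quote_label(label: str) -> str:
    if any(c in label for c in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# tree generation


def star_tree(taxa: Sequence[str]) -> Tree:
    root = Node()
    for t in taxa:
        root.add(Node(t, 0.0))
    return Tree(root)


def random_topology(taxa: Sequence[str], rng) -> Tree:
    """Uniform random unrooted binary topology by sequential tip insertion."""
    taxa = list(taxa)
    if len(taxa) < 3:
        return star_tree(taxa)
    root = Node()
    for t in taxa[:3]:
        root.add(Node(t, 0.0))
    tree = Tree(root)
    for t in taxa[3:]:
        edge = tree.edges()[rng.integers(len(tree.edges()))]
        _insert_tip_on_edge(edge, t)
    return tree


def _insert_tip_on_edge(edge: Node, label: str) -> None:
    parent = edge.parent
    mid = Node(None, edge.length / 2)
    idx = parent.children.index(edge)
    parent.children[idx] = mid
    mid.parent = parent
    edge.length /= 2
    mid.add(edge)
    mid.add(Node(label, 0.0))


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[Tree]:
    """Yield every unrooted binary topology on ``taxa`` (use only for n<=8:
    there are (2n-5)!! of them)."""
    taxa = list(taxa)
    if len(taxa) <= 3:
        yield star_tree(taxa)
        return
    base = star_tree(taxa[:3])
    stack = [(base, 3)]
    while stack:
        tree, k = stack.pop()
        if k == len(taxa):
            yield tree
            continue
        for i in range(len(tree.edges())):
            t2 = tree.copy()
            _insert_tip_on_edge(t2.edges()[i], taxa[k])
            stack.append((t2, k + 1))


def yule_tree(taxa: Sequence[str], rng, mean_edge: float = 0.1) -> Tree:
    """Random topology with exponential branch lengths (mean ``mean_edge``)."""
    tree = random_topology(taxa, rng)
    for e in tree.edges():
        e.length = float(rng.exponential(mean_edge))
    return tree


def parse_newick(text: str) -> Tree:
    return Tree.from_newick(text)


def unroot(tree: Tree) -> Tree:
    """Return a copy in unrooted representation (root of degree >= 3 where
    the topology allows it)."""
    t = tree.copy()
    if len(t.root.children) == 2:
        internal = next((c for c in t.root.children if not c.is_leaf), None)
        if internal is not None:
            t.reroot_at(internal)
    return t


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    if set(t1.taxa) != set(t2.taxa):
        raise TreeError("tip sets differ")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2)


def nni_neighbors(tree: Tree) -> Iterator[Tree]:
    """All nearest-neighbour-interchange neighbours of an unrooted tree.

    For each internal edge the two alternative arrangements of the four
    incident subtrees are produced."""
    tree = unroot(tree)
    internal_edges = [
        (i, e)
        for i, e in enumerate(tree.edges())
        if not e.is_leaf and e.parent is not None
    ]
    for idx, _ in internal_edges:
        for alt in (0, 1):
            t2 = tree.copy()
            edge = t2.edges()[idx]
            parent = edge.parent
            if parent is not t2.root:
                t2.reroot_at(parent)
                # re-locate the edge after rerooting: same tip block below
                block = _tip_block(edge)
                edge = next(
                    c
                    for c in t2.root.children
                    if not c.is_leaf and _tip_block(c) == block
                )
                parent = t2.root
            others = [c for c in parent.children if c is not edge]
            swap_with = others[alt % len(others)]
            sub = edge.children[1]
            parent.children[parent.children.index(swap_with)] = sub
            edge.children[1] = swap_with
            sub.parent, swap_with.parent = parent, edge
            yield t2


def spr_neighbors(tree: Tree, max_moves: Optional[int] = None) -> Iterator[Tree]:
    """Subtree-prune-regraft neighbours (each non-root edge pruned and
    reattached to every non-adjacent edge)."""
    n_edges = len(tree.edges())
    count = 0
    for prune_i in range(n_edges):
        for graft_i in range(n_edges):
            if prune_i == graft_i:
                continue
            t2 = _try_spr(tree, prune_i, graft_i)
            if t2 is not None:
                count += 1
                yield t2
                if max_moves is not None and count >= max_moves:
                    return


def _try_spr(tree: Tree, prune_i: int, graft_i: int) -> Optional[Tree]:
    t2 = tree.copy()
    edges = t2.edges()
    sub, target = edges[prune_i], edges[graft_i]
    # target must not lie inside the pruned subtree, nor be its sibling edge
    node = target
    while node is not None:
        if node is sub:
            return None
        node = node.parent
    parent = sub.parent
    if target.parent is parent and len(parent.children) <= 2:
        return None
    parent.children.remove(sub)
    t2.suppress_unifurcations()
    if t2.root.is_leaf or len(t2.root.children) < 2:
        return None
    # suppression may have detached `target` (it was the pruned node's
    # parent or the old root); such moves regraft on a vanished edge
    node = target
    while node.parent is not None:
        if node not in node.parent.children:
            return None
        node = node.parent
    if node is not t2.root:
        return None
    mid = Node(None, target.length / 2)
    tparent = target.parent
    if tparent is None:
        return None
    idx = tparent.children.index(target)
    tparent.children[idx] = mid
    mid.parent = tparent
    target.length /= 2
    mid.add(target)
    mid.add(sub)
    out = Tree(t2.root)
    if out.n_tips() != tree.n_tips():
        return None
    return unroot(out)


def _tip_block(node: Node) -> frozenset[str]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.label)
        stack.extend(n.children)
    return frozenset(out)


def majority_rule_bipartitions(
    trees: Sequence[Tree], threshold: float = 0.5
) -> set[frozenset[str]]:
    """Bipartitions present in more than ``threshold`` of the trees."""
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for b in t.bipartitions():
            counts[b] = counts.get(b, 0) + 1
    n = len(trees)
    return {b for b, c in counts.items() if c > threshold * n}
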