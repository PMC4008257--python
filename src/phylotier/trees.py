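"""Trees: newick I/O, neighbor joining, patristic distances, consensus.

Thin object layer over :mod:`dendropy`.  All topology comparisons in this
package go through *splits* (bipartitions of the leaf set, canonicalised as
the side not containing the lexicographically smallest leaf), which makes
edge identity stable across bootstrap replicates and taxon deletions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "TreeError",
    "DistanceMatrix",
    "parse_newick",
    "write_newick",
    "neighbor_joining",
    "patristic_distances",
    "restrict_to_taxa",
    "strict_consensus",
]


class TreeError(ValueError):
    """Raised for malformed trees or incompatible tree operations."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal.

    Non-comparable pairs are stored as ``nan`` and flagged by
    :meth:`incomparable_pairs`.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise TreeError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise TreeError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite, self.values, 0.0).T,
            atol=1e-9,
        ):
            raise TreeError("distance matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values) < -1e-12:
                raise TreeError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def incomparable_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def drop(self, labels: Iterable[str]) -> "DistanceMatrix":
        drop = set(labels)
        keep = [i for i, l in enumerate(self.labels) if l not in drop]
        return DistanceMatrix(
            [self.labels[i] for i in keep], self.values[np.ix_(keep, keep)]
        )


class Tree:
    """Unrooted (optionally root-marked) phylogeny with branch lengths."""

    def __init__(self, dtree: dendropy.Tree):
        labels = [l.taxon.label for l in dtree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf label(s): {', '.join(dup)}")
        # canonical unrooted form: collapse a bifurcating seed node so every
        # physical edge appears exactly once
        if len(labels) >= 3 and len(dtree.seed_node.child_nodes()) == 2:
            dtree.deroot()
            dtree.is_rooted = False
        self._t = dtree

    # -- construction / I/O ---------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise TreeError(f"newick parse error: {exc}") from exc
        return cls(dtree)

    def to_newick(self, include_support: bool = True) -> str:
        s = self._t.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_internal_node_labels=not include_support,
        )
        return s.strip()

    def copy(self) -> "Tree":
        return Tree(self._t.clone(depth=1))

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._t

    # -- basic queries ----------------------------------------------------
    @property
    def leaves(self) -> list[str]:
        return sorted(l.taxon.label for l in self._t.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._t.leaf_node_iter())

    def has_branch_lengths(self) -> bool:
        for edge in self._t.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                return False
        return True

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self._t.preorder_edge_iter() if e.tail_node
        )

    def _leafset_below(self, node) -> frozenset:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def splits(self, include_trivial: bool = False) -> set[frozenset]:
        """Canonical splits: each bipartition is represented by the side
        *not* containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaves)
        if not all_leaves:
            return set()
        anchor = min(all_leaves)
        out: set[frozenset] = set()
        for node in self._t.preorder_node_iter():
            if node.parent_node is None:
                continue
            below = self._leafset_below(node)
            side = below if anchor not in below else all_leaves - below
            if not side or side == all_leaves:
                continue
            if not include_trivial and (len(side) < 2 or len(side) > len(all_leaves) - 2):
                continue
            out.add(side)
        return out

    def is_clade(self, taxa: Iterable[str]) -> bool:
        """True iff ``taxa`` forms one side of some branch (monophyly in the
        unrooted sense); single leaves and the full leaf set count as clades."""
        taxa = frozenset(taxa)
        all_leaves = frozenset(self.leaves)
        if not taxa <= all_leaves:
            raise TreeError(f"taxa not in tree: {sorted(taxa - all_leaves)}")
        if len(taxa) <= 1 or taxa == all_leaves or len(taxa) == len(all_leaves) - 1:
            return True
        anchor = min(all_leaves)
        canon = taxa if anchor not in taxa else all_leaves - taxa
        return canon in self.splits(include_trivial=True)

    def attachment_split(self, leaf: str) -> tuple[frozenset, frozenset]:
        """The bipartition (over all other leaves) of the edge onto which
        ``leaf`` is attached: remove the leaf, suppress its degree-2 parent,
        and report the two sides of the merged edge."""
        node = None
        for l in self._t.leaf_node_iter():
            if l.taxon.label == leaf:
                node = l
                break
        if node is None:
            raise TreeError(f"no leaf named {leaf!r}")
        parent = node.parent_node
        if parent is None:
            raise TreeError("cannot compute attachment of the only node")
        others = frozenset(self.leaves) - {leaf}
        side_a: set = set()
        for child in parent.child_nodes():
            if child is node:
                continue
            side_a |= self._leafset_below(child)
        side_b = others - side_a
        if not side_b:
            # parent was the root: split among its remaining children
            children = [c for c in parent.child_nodes() if c is not node]
            side_a = frozenset(self._leafset_below(children[0]))
            side_b = others - side_a
        return frozenset(side_a), frozenset(side_b)

    # -- module operations (method forms) ---------------------------------
    def patristic_distances(self) -> DistanceMatrix:
        return patristic_distances(self)

    def restrict_to_taxa(self, taxa: Iterable[str]) -> "Tree":
        return restrict_to_taxa(self, taxa)

    def __repr__(self):
        return f"<Tree {self.n_leaves} leaves>"


def parse_newick(text: str) -> Tree:
    return Tree.from_newick(text)


def write_newick(tree: Tree, include_support: bool = True) -> str:
    return tree.to_newick(include_support=include_support)


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; negative length estimates clamped to 0.

    Exact inverse of path-length (patristic) distances on additive matrices
    from binary trees with positive lengths.
    """
    bad = D.incomparable_pairs()
    if bad:
        raise TreeError(f"incomparable (non-finite) distances for pairs: {bad[:5]}")
    n = len(D.labels)
    if n < 2:
        raise TreeError("need at least 2 taxa for a tree")
    if n == 2:
        d = D.values[0, 1]
        return Tree.from_newick(f"({_q(D.labels[0])}:{d / 2}," f"{_q(D.labels[1])}:{d / 2});")
    csv = io.StringIO()
    csv.write("," + ",".join(D.labels) + "\n")
    for i, l in enumerate(D.labels):
        csv.write(l + "," + ",".join(f"{float(v):.17g}" for v in D.values[i]) + "\n")
    csv.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=csv, delimiter=",")
    dtree = pdm.nj_tree()
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return Tree(dtree)


def _q(label: str) -> str:
    return f"'{label}'" if any(c in label for c in " ()[]:;,'") else label


def patristic_distances(tree: Tree) -> DistanceMatrix:
    """Tip-to-tip path-length distances."""
    if not tree.has_branch_lengths():
        raise TreeError("tree has missing branch lengths")
    dt = tree.dendropy_tree
    pdm = dt.phylogenetic_distance_matrix()
    taxa = sorted(dt.taxon_namespace, key=lambda t: t.label)
    taxa = [t for t in taxa if any(l.taxon is t for l in dt.leaf_node_iter())]
    labels = [t.label for t in taxa]
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def restrict_to_taxa(tree: Tree, taxa: Iterable[str]) -> Tree:
    """Prune to the given taxa; degree-2 nodes suppressed, lengths summed."""
    taxa = set(taxa)
    leaves = set(tree.leaves)
    unknown = taxa - leaves
    if unknown:
        raise TreeError(f"unknown taxa: {sorted(unknown)}")
    if len(taxa) < 2:
        raise TreeError("need at least 2 taxa to restrict to")
    clone = tree.dendropy_tree.clone(depth=1)
    clone.retain_taxa_with_labels(sorted(taxa))
    clone.suppress_unifurcations()
    return Tree(clone)


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Tree containing exactly the splits shared by every input.

    Inputs must be on identical leaf sets (restrict first if not); the
    result is unrooted, polytomic where inputs conflict, and carries no
    branch lengths.
    """
    if len(trees) < 2:
        raise TreeError("strict consensus needs at least 2 trees")
    leafsets = {frozenset(t.leaves) for t in trees}
    if len(leafsets) != 1:
        raise TreeError("leaf-set mismatch between input trees; restrict first")
    leaves = sorted(leafsets.pop())
    common = set.intersection(*(t.splits() for t in trees))
    return tree_from_splits(leaves, common)


def tree_from_splits(leaves: Sequence[str], splits: Iterable[frozenset]) -> Tree:
    """Build the (unique) unrooted tree realising a compatible split set.

    Splits must be pairwise compatible canonical sides (not containing the
    smallest leaf).  Used for consensus construction; no branch lengths.
    """
    leaves = sorted(leaves)
    anchor = leaves[0]
    splits = sorted(set(splits), key=lambda s: (len(s), sorted(s)))
    for s in splits:
        if anchor in s:
            raise TreeError("splits must be canonical (anchor-free side)")
    # nest splits: since all are compatible and anchor-free, containment is a
    # forest; build rooted-at-anchor node hierarchy.
    children: dict = {None: []}
    nodes: list[tuple[frozenset, dendropy.Node]] = []
    tns = dendropy.TaxonNamespace(leaves)
    root = dendropy.Node()
    made: list[tuple[frozenset, dendropy.Node]] = []
    for s in sorted(splits, key=len, reverse=False):
        made.append((s, dendropy.Node()))
    # attach each split node to the smallest strictly containing split (or root)
    for s, node in sorted(made, key=lambda x: -len(x[0])):
        parent = root
        best = None
        for s2, node2 in made:
            if s < s2 and (best is None or len(s2) < len(best)):
                best, parent = s2, node2
        parent.add_child(node)
    for leaf in leaves:
        parent = root
        best = None
        for s, node in made:
            if leaf in s and (best is None or len(s) < len(best)):
                best, parent = s, node
        lnode = dendropy.Node(taxon=tns.get_taxon(leaf))
        parent.add_child(lnode)
    dtree = dendropy.Tree(taxon_namespace=tns)
    dtree.seed_node = root
    dtree.is_rooted = False
    return Tree(dtree)
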