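"""Constrained ML placement of query taxa on a fixed backbone tree.

The backbone topology (and, by default, its branch lengths) is held fixed;
for every backbone edge the query is grafted onto that edge and only the
three local branch lengths — the two sub-edges created by the attachment
node and the query's pendant branch — are optimized.  Edges are identified
by the bipartition (split) they induce, which keeps placement descriptors
stable across bootstrap replicates and makes rogue-taxon deletions
well-defined set operations.

Bootstrap support is computed by resampling sites with replacement within
each partition (pattern weights are redrawn, so the expensive conditional
likelihoods are shared across replicates), re-placing the query — and any
designated rogue taxa — in every replicate, and tallying attachment edges.
Two rogue-aware summaries follow the tally: *effective support* (support
for a relationship after deleting rogues from each replicate's placement)
and *cumulative region support* (total placement frequency over a union of
clades and their connecting spine).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from phylotier.likelihood import BL_MIN, BL_MAX, TreeLikelihood
from phylotier.seqdata import DEFAULT_MISSING, PartitionedAlignment
from phylotier.substmodels import SubstitutionModel, ModelError
from phylotier.trees import Tree, TreeError

__all__ = [
    "PlacementError",
    "graft",
    "EdgePlacement",
    "PlacementResult",
    "ReplicateRecord",
    "PlacementTally",
    "PlacementModel",
    "PlacementResults",
    "place_query",
    "place_multiple",
    "bootstrap_placements",
    "effective_support",
    "region_support",
    "select_subset",
    "write_jplace",
]


class PlacementError(ValueError):
    """Raised for invalid placement requests."""


# ---------------------------------------------------------------------------
# grafting
# ---------------------------------------------------------------------------

def _find_edge_node(tree: Tree, edge: frozenset | tuple):
    """Locate the dendropy node whose subtending edge induces ``edge``.

    ``edge`` is a leaf-set split: either one side (frozenset) or both sides
    (tuple of two frozensets) over the tree's leaves.
    """
    sides = (
        {frozenset(edge[0]), frozenset(edge[1])}
        if isinstance(edge, tuple)
        else {frozenset(edge)}
    )
    all_leaves = frozenset(tree.leaves)
    dt = tree.dendropy_tree
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if below in sides or (all_leaves - below) in sides:
            return node
    raise PlacementError(f"no edge matching split {sorted(map(sorted, sides))}")


def graft(
    backbone: Tree,
    edge: frozenset | tuple,
    query: str,
    attach_fraction: float = 0.5,
    pendant_length: float = 0.1,
) -> Tree:
    """Attach ``query`` to ``edge``, subdividing it at ``attach_fraction``
    of its length (measured from the parent end).  All other splits are
    unchanged; pruning the query restores the original tree."""
    if query in backbone.leaves:
        raise PlacementError(f"query {query!r} already in backbone")
    if not (0 < attach_fraction < 1):
        raise PlacementError("attach_fraction must be in (0, 1)")
    work = backbone.copy()
    node = _find_edge_node(work, edge)
    return _graft_at_node(work, node, query, attach_fraction * (node.edge.length or 0.0),
                          (1 - attach_fraction) * (node.edge.length or 0.0),
                          pendant_length)


def _graft_at_node(work: Tree, node, query: str, t_parent: float,
                   t_child: float, pendant: float) -> Tree:
    import dendropy

    dt = work.dendropy_tree
    parent = node.parent_node
    new = dendropy.Node()
    parent.remove_child(node)
    parent.add_child(new)
    new.add_child(node)
    new.edge.length = t_parent
    node.edge.length = t_child
    taxon = dt.taxon_namespace.require_taxon(label=query)
    leaf = dendropy.Node(taxon=taxon)
    new.add_child(leaf)
    leaf.edge.length = pendant
    return Tree(dt)


def prune_taxa(tree: Tree, taxa: Iterable[str]) -> Tree:
    """Remove leaves, suppressing degree-2 nodes (lengths summed)."""
    keep = [l for l in tree.leaves if l not in set(taxa)]
    return tree.restrict_to_taxa(keep)


# ---------------------------------------------------------------------------
# per-edge placement machinery
# ---------------------------------------------------------------------------

class _PlacementEngine:
    """Per-edge likelihood evaluation for one query on a fixed tree.

    Wraps a :class:`TreeLikelihood` whose pattern compression includes the
    query row; conditional likelihoods toward both ends of every edge are
    computed once, after which each (sub-edge, sub-edge, pendant) evaluation
    is O(patterns).
    """

    def __init__(self, lk: TreeLikelihood, query: str):
        self.lk = lk
        self.query = query
        self.cache = lk._ensure_cache(with_up=True)
        self.arr = lk.arr
        self._edge_cache: dict[tuple[int, int], tuple] = {}
        # partitions sharing a substitution model evaluate as one pattern
        # block (weights stay per-partition for stratified resampling)
        groups: dict[tuple, dict] = {}
        any_data = False
        for part in lk.parts:
            q = part.tipp.get(query)
            if q is None:
                raise PlacementError(f"query {query!r} missing from alignment")
            if (q.sum(axis=1) < 4).any():
                any_data = True
            m = part.model
            key = (m.rates, m.freqs, m.gamma_shape, m.n_categories, m.rate_scale)
            g = groups.setdefault(key, {"parts": [], "model": m})
            g["parts"].append(part)
        if not any_data:
            raise PlacementError(
                f"query {query!r} has no determinate site in the retained partitions"
            )
        self.groups: list[dict] = []
        for g in groups.values():
            m = g["model"]
            w_, left, right = m._eigensystem()
            g["w"] = w_
            g["leftT"] = left.T.copy()
            g["rates"] = m.category_rates() * m.rate_scale
            g["pi"] = np.asarray(m.freqs)
            g["qt"] = np.concatenate(
                [part.tipp[query] for part in g["parts"]]
            ) @ right.T
            g["right"] = right
            g["weights0"] = np.concatenate([p.weights for p in g["parts"]])
            self.groups.append(g)

    def _edge_transforms(self, gi: int, v: int):
        """Eigenbasis-transformed rest-of-tree / subtree partials for edge
        ``v`` and precomputed scale factors, cached across evaluations."""
        hit = self._edge_cache.get((gi, v))
        if hit is not None:
            return hit
        g = self.groups[gi]
        right = g["right"]
        H = np.concatenate([self.cache[p.name]["H"][v] for p in g["parts"]])
        D = np.concatenate([self.cache[p.name]["D"][v] for p in g["parts"]])
        SS = np.concatenate(
            [self.cache[p.name]["S"][v] + self.cache[p.name]["SH"][v]
             for p in g["parts"]]
        )
        Ht = H @ right.T
        Dt = D @ right.T
        K = H.shape[1]
        Qb = np.broadcast_to(g["qt"][:, None, :], Ht.shape)
        A = np.stack([Ht, Dt, Qb])  # (3, patterns, K, 4)
        M = SS.max(axis=1)
        expSS = np.exp(SS - M[:, None])
        out = (A, M, expSS)
        self._edge_cache[(gi, v)] = out
        return out

    def _group_weights(
        self, gi: int, weights: Mapping[str, np.ndarray] | None
    ) -> np.ndarray:
        g = self.groups[gi]
        if weights is None:
            return g["weights0"]
        return np.concatenate([weights[p.name] for p in g["parts"]])

    def edge_loglik(
        self,
        v: int,
        t_parent: float,
        t_child: float,
        pendant: float,
        weights: Mapping[str, np.ndarray] | None = None,
    ) -> float:
        ts = np.array([t_parent, t_child, pendant])
        total = 0.0
        for gi, g in enumerate(self.groups):
            w_, leftT, rates, pi = g["w"], g["leftT"], g["rates"], g["pi"]
            A, M, expSS = self._edge_transforms(gi, v)
            ew = np.exp(ts[:, None, None] * np.outer(rates, w_))  # (3, K, 4)
            Y = (A * ew[:, None, :, :]) @ leftT
            lik = np.maximum((Y[0] * Y[1] * Y[2]) @ pi, 1e-300)
            s = (lik * expSS).sum(axis=1)
            ll = np.log(s) + M - np.log(rates.size)
            total += float(ll @ self._group_weights(gi, weights))
        return total

    def optimize_edge(
        self,
        v: int,
        weights: Mapping[str, np.ndarray] | None = None,
        xatol: float = 1e-5,
        sweeps: int = 2,
        init: tuple[float, float, float] | None = None,
        narrow: bool = False,
    ) -> tuple[float, float, float, float]:
        """Coordinate-wise Brent optimization of the three local lengths
        (parent sub-edge, child sub-edge, pendant).  With ``narrow`` the
        search brackets each length within a x16 window around its starting
        value (used for bootstrap re-placement seeded at the point fit)."""
        if init is None:
            L = max(self.arr.blen[v], 2 * BL_MIN)
            params = [max(L / 2, BL_MIN), max(L / 2, BL_MIN), 0.1]
        else:
            params = [max(t, BL_MIN) for t in init]

        def obj(i, t):
            trial = list(params)
            trial[i] = t
            return -self.edge_loglik(v, *trial, weights=weights)

        for _ in range(sweeps):
            for i in (2, 0, 1):  # pendant first: it carries most signal
                if narrow:
                    bounds = (
                        max(BL_MIN, params[i] / 16.0),
                        min(BL_MAX, max(params[i] * 16.0, 0.2)),
                    )
                else:
                    bounds = (BL_MIN, BL_MAX)
                res = minimize_scalar(
                    lambda t: obj(i, t), bounds=bounds,
                    method="bounded", options={"xatol": xatol},
                )
                if res.fun <= obj(i, params[i]):
                    params[i] = float(res.x)
        ll = self.edge_loglik(v, *params, weights=weights)
        return ll, params[0], params[1], params[2]

    def candidate_edges(self) -> list[int]:
        return self.arr.edges

    def edge_split(self, v: int) -> tuple[frozenset, frozenset]:
        below = self.arr.leafset_below(v)
        others = frozenset(self.arr.leaf_nodes) - below
        return below, others

    def draw_weights(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Stratified site bootstrap expressed as pattern-weight redraws."""
        out = {}
        for part in self.lk.parts:
            n = int(round(part.weights.sum()))
            out[part.name] = rng.multinomial(n, part.weights / part.weights.sum()).astype(float)
        return out


@dataclass
class EdgePlacement:
    """One candidate attachment: the edge's split and its optimized fit."""

    split: tuple[frozenset, frozenset]
    loglik: float
    t_parent: float
    t_child: float
    pendant: float
    edge_length: float

    @property
    def attach_fraction(self) -> float:
        s = self.t_parent + self.t_child
        return self.t_parent / s if s > 0 else 0.5


@dataclass
class PlacementResult:
    """Ranked per-edge placements of one query on one backbone."""

    query: str
    edges: list[EdgePlacement]  # sorted by decreasing log-likelihood
    backbone: Tree

    def __post_init__(self):
        self.edges = sorted(self.edges, key=lambda e: -e.loglik)

    @property
    def best(self) -> EdgePlacement:
        return self.edges[0]

    @property
    def margin(self) -> float:
        """Log-likelihood margin between the best edge and the runner-up."""
        if len(self.edges) < 2:
            return np.inf
        return self.edges[0].loglik - self.edges[1].loglik

    def best_tree(self) -> Tree:
        """Backbone with the query grafted at its best edge, using the
        optimized sub-edge and pendant lengths."""
        b = self.best
        tree = graft(self.backbone, b.split, self.query, 0.5, b.pendant)
        for l in tree.dendropy_tree.leaf_node_iter():
            if l.taxon.label == self.query:
                w = l.parent_node
                w.edge.length = b.t_parent
                for c in w.child_nodes():
                    if c is not l:
                        c.edge.length = b.t_child
        return tree


# ---------------------------------------------------------------------------
# tallies and rogue-aware support
# ---------------------------------------------------------------------------

@dataclass
class ReplicateRecord:
    """Where the query (and designated rogues) landed in one replicate.

    ``query_sides`` is the split of the attachment edge over all leaves
    except the query itself (rogues included at their replicate positions);
    ``rogue_sides`` maps each rogue to its own attachment split; ``newick``
    (when present) is the full augmented replicate tree and is used as the
    authoritative source for support computations.
    """

    query_sides: tuple[frozenset, frozenset]
    rogue_sides: dict[str, tuple[frozenset, frozenset]] = field(default_factory=dict)
    newick: str | None = None


@dataclass
class PlacementTally:
    """Per-replicate bootstrap placement records for one query."""

    query: str
    backbone_leaves: frozenset
    records: list[ReplicateRecord]
    rogues: tuple[str, ...] = ()
    seed: int | None = None

    @property
    def B(self) -> int:
        return len(self.records)

    def edge_counts(self) -> dict[tuple, int]:
        """Aggregated counts keyed by the canonicalised query split."""
        counts: dict[tuple, int] = {}
        for rec in self.records:
            key = tuple(sorted(map(tuple, map(sorted, rec.query_sides))))
            counts[key] = counts.get(key, 0) + 1
        return counts

    def to_table(self) -> str:
        """Tab-separated tally: descriptor, count, percentage."""
        lines = ["placement\tcount\tpercent"]
        for key, c in sorted(self.edge_counts().items(), key=lambda kv: (-kv[1], kv[0])):
            desc = " | ".join(",".join(side) for side in key)
            lines.append(f"{desc}\t{c}\t{100.0 * c / self.B:.1f}")
        return "\n".join(lines) + "\n"


def _replicate_tree(rec: ReplicateRecord) -> Tree | None:
    return Tree.from_newick(rec.newick) if rec.newick else None


def _qualifies_effective(
    rec: ReplicateRecord, query: str, focal: frozenset, rogues: frozenset
) -> bool:
    """Does the query join the focal clade (inside or as sister) once the
    rogues are deleted from this replicate's placement?"""
    tree = _replicate_tree(rec)
    focal_kept = focal - rogues
    if tree is not None:
        kept = [l for l in tree.leaves if l not in rogues]
        sub = tree.restrict_to_taxa(kept)
        return sub.is_clade(focal_kept | {query})
    # descriptor-only record: subset rule on the attachment split, then check
    # that taxa still free to move do not break the focal clade
    sides = [frozenset(s) - rogues for s in rec.query_sides]
    if not any(s and s <= focal_kept for s in sides):
        return False
    for r, rsides in rec.rogue_sides.items():
        if r in rogues:
            continue
        rs = [frozenset(s) - rogues - {r} for s in rsides]
        inside = any(s and s <= (focal_kept - {r}) for s in rs)
        if r in focal and not inside:
            return False
        if r not in focal and any(s and s < focal_kept for s in rs):
            return False
    return True


def effective_support(
    tally: PlacementTally,
    focal_clade: Iterable[str],
    rogues: Iterable[str] = (),
) -> float:
    """Bootstrap percentage of replicates in which the query attaches inside
    or as sister to ``focal_clade`` after deleting ``rogues`` from each
    replicate's placement.  With no rogues this is the plain edge support
    for the clade (query included)."""
    focal = frozenset(focal_clade)
    rogues = frozenset(rogues)
    known = tally.backbone_leaves | set(tally.rogues)
    unknown = focal - known
    if unknown:
        raise PlacementError(f"focal clade taxa not in backbone: {sorted(unknown)}")
    if tally.B == 0:
        raise PlacementError("empty tally")
    hits = sum(
        _qualifies_effective(rec, tally.query, focal, rogues) for rec in tally.records
    )
    return 100.0 * hits / tally.B


def _in_region(sides: Sequence[frozenset], region: frozenset) -> bool:
    a, b = frozenset(sides[0]), frozenset(sides[1])
    if a <= region or b <= region:
        return True
    return bool(a & region) and bool(b & region)


def region_support(tally: PlacementTally, region_taxa: Iterable[str]) -> float:
    """Cumulative bootstrap percentage of replicates whose attachment edge
    lies on or within the region (the subtrees of the region's clades and
    the spine connecting them)."""
    region = frozenset(region_taxa)
    if not region:
        raise PlacementError("empty region")
    if tally.B == 0:
        raise PlacementError("empty tally")
    hits = sum(_in_region(rec.query_sides, region) for rec in tally.records)
    return 100.0 * hits / tally.B


def select_subset(
    backbone: Tree,
    tally: PlacementTally,
    aln: PartitionedAlignment,
    region_threshold: float = 95.0,
    outgroup_clades: Mapping[str, Iterable[str]] | None = None,
    k: int = 2,
) -> list[str]:
    """Focused taxon subset for second-tier reanalysis.

    Greedily accumulates backbone clades (smallest first among equal gains)
    until their union's cumulative region support reaches
    ``region_threshold``; then adds, from each named outgroup clade, the
    ``k`` taxa with the least missing data (ties broken lexicographically).
    """
    if not (50.0 < region_threshold <= 100.0):
        raise PlacementError("region_threshold must be in (50, 100]")
    leaves = frozenset(backbone.leaves)
    # candidate clades: every split side of the backbone, plus single leaves
    candidates: set[frozenset] = {frozenset([l]) for l in leaves}
    for side in backbone.splits(include_trivial=True):
        candidates.add(side)
        candidates.add(leaves - side)
    candidates.discard(frozenset())
    chosen: set[str] = set()
    current = 0.0
    ordered = sorted(candidates, key=lambda s: (len(s), tuple(sorted(s))))
    while current < region_threshold:
        best_gain, best_cand = None, None
        for cand in ordered:
            if cand <= chosen:
                continue
            sup = region_support(tally, chosen | cand)
            gain = (sup - current) / len(cand - chosen)
            key = (gain, -len(cand - chosen), tuple(sorted(cand)))
            if best_gain is None or key > best_gain:
                best_gain, best_cand = key, cand
        if best_cand is None or best_gain[0] <= 0:
            achieved = region_support(tally, leaves)
            raise PlacementError(
                f"region threshold {region_threshold} unattainable; "
                f"maximum achievable is {achieved:.1f}"
            )
        chosen |= best_cand
        current = region_support(tally, chosen)
    subset = set(chosen)
    for name, taxa in (outgroup_clades or {}).items():
        taxa = sorted(set(taxa))
        ranked = sorted(
            taxa, key=lambda t: (aln.taxon_missing_fraction(t, DEFAULT_MISSING), t)
        )
        subset.update(ranked[:k])
    return sorted(subset)


# ---------------------------------------------------------------------------
# Model / Results layer
# ---------------------------------------------------------------------------

class PlacementModel:
    """Constrained-placement model: a fixed backbone, a partitioned
    alignment with per-partition substitution models, and one query taxon.

    ``fit`` optimizes the query's attachment on every backbone edge and
    (optionally) bootstraps the placement, returning
    :class:`PlacementResults`.
    """

    def __init__(
        self,
        aln: PartitionedAlignment,
        backbone: Tree,
        models: SubstitutionModel | Mapping[str, SubstitutionModel],
        query: str,
        rogues: Sequence[str] = (),
    ):
        if query not in aln.taxa:
            raise PlacementError(f"query {query!r} not in alignment")
        missing = set(backbone.leaves) - set(aln.taxa)
        if missing:
            raise PlacementError(f"backbone taxa absent from alignment: {sorted(missing)}")
        if not backbone.has_branch_lengths():
            raise PlacementError("backbone must carry branch lengths")
        self.aln = aln
        self.backbone = backbone
        self.models = models
        self.query = query
        self.rogues = tuple(rogues)

    def _place_on(
        self,
        tree: Tree,
        taxon: str,
        other_extras: Sequence[str] = (),
        weights: Mapping[str, np.ndarray] | None = None,
        xatol: float = 1e-5,
    ) -> PlacementResult:
        lk = TreeLikelihood(
            tree, self.aln, self.models, extra_taxa=[taxon, *other_extras]
        )
        eng = _PlacementEngine(lk, taxon)
        edges = []
        for v in eng.candidate_edges():
            ll, t1, t2, tq = eng.optimize_edge(v, weights=weights, xatol=xatol)
            edges.append(
                EdgePlacement(eng.edge_split(v), ll, t1, t2, tq, float(eng.arr.blen[v]))
            )
        return PlacementResult(taxon, edges, tree)

    def fit(
        self,
        bootstrap: int = 0,
        seed: int | None = None,
        xatol: float = 1e-6,
        bootstrap_xatol: float = 2e-2,
    ) -> "PlacementResults":
        point = self._place_on(self.backbone, self.query, xatol=xatol)
        tally = None
        if bootstrap:
            tally = self._bootstrap(bootstrap, seed, xatol=bootstrap_xatol)
        return PlacementResults(self, point, tally)

    def _bootstrap(
        self, B: int, seed: int | None, xatol: float, preselect: int = 5
    ) -> PlacementTally:
        rng = np.random.default_rng(seed)
        records: list[ReplicateRecord] = []
        if not self.rogues:
            lk = TreeLikelihood(
                self.backbone, self.aln, self.models, extra_taxa=[self.query]
            )
            eng = _PlacementEngine(lk, self.query)
            edges = eng.candidate_edges()
            # per-edge local optima on the original data: used both to seed
            # and to preselect candidate edges in each replicate
            point: dict[int, tuple[float, float, float]] = {}
            for v in edges:
                _, t1, t2, tq = eng.optimize_edge(v, xatol=min(xatol, 1e-3))
                point[v] = (t1, t2, tq)
            for _ in range(B):
                weights = eng.draw_weights(rng)
                scored = sorted(
                    edges,
                    key=lambda v: -eng.edge_loglik(v, *point[v], weights=weights),
                )
                best_ll, best_v = -np.inf, None
                for v in scored[: max(preselect, 1)]:
                    ll, *_ = eng.optimize_edge(
                        v, weights=weights, xatol=xatol, sweeps=1,
                        init=point[v], narrow=True,
                    )
                    if ll > best_ll:
                        best_ll, best_v = ll, v
                records.append(ReplicateRecord(eng.edge_split(best_v)))
            return PlacementTally(
                self.query, frozenset(self.backbone.leaves), records, (), seed
            )
        # rogue-aware bootstrap: detach rogues, re-place them jointly with
        # the query in every replicate (most-complete taxon first)
        base = prune_taxa(self.backbone, self.rogues)
        movers = [self.query, *self.rogues]
        order = sorted(
            movers,
            key=lambda t: (self.aln.taxon_missing_fraction(t), t),
        )
        base_lk = TreeLikelihood(base, self.aln, self.models, extra_taxa=movers)
        base_eng = _PlacementEngine(base_lk, order[0])
        for _ in range(B):
            weights = base_eng.draw_weights(rng)
            tree = base
            for i, taxon in enumerate(order):
                remaining = order[i:]
                lk = (
                    base_lk
                    if tree is base
                    else TreeLikelihood(tree, self.aln, self.models, extra_taxa=remaining)
                )
                eng = _PlacementEngine(lk, taxon)
                best_ll, best = -np.inf, None
                for v in eng.candidate_edges():
                    ll, t1, t2, tq = eng.optimize_edge(v, weights=weights, xatol=xatol)
                    if ll > best_ll:
                        best_ll, best = ll, (v, t1, t2, tq)
                v, t1, t2, tq = best
                frac = t1 / (t1 + t2) if t1 + t2 > 0 else 0.5
                tree = graft(tree, eng.edge_split(v), taxon, frac, tq)
            rec = ReplicateRecord(
                tree.attachment_split(self.query),
                {r: tree.attachment_split(r) for r in self.rogues},
                tree.to_newick(include_support=False),
            )
            records.append(rec)
        return PlacementTally(
            self.query, frozenset(base.leaves), records, self.rogues, seed
        )


class PlacementResults:
    """Fitted placement: ranked edges, optional bootstrap tally, summaries."""

    def __init__(
        self,
        model: PlacementModel,
        point: PlacementResult,
        tally: PlacementTally | None,
    ):
        self.model = model
        self.point = point
        self.tally = tally

    @property
    def best_edge(self) -> EdgePlacement:
        return self.point.best

    @property
    def margin(self) -> float:
        return self.point.margin

    def placements(self) -> pd.DataFrame:
        rows = []
        for e in self.point.edges:
            rows.append(
                {
                    "edge": " | ".join(
                        ",".join(sorted(side)) for side in sorted(
                            e.split, key=lambda s: tuple(sorted(s))
                        )
                    ),
                    "loglik": e.loglik,
                    "pendant": e.pendant,
                    "t_parent": e.t_parent,
                    "t_child": e.t_child,
                }
            )
        df = pd.DataFrame(rows)
        df["lwr"] = np.exp(df["loglik"] - logsumexp(df["loglik"]))
        return df

    def effective_support(self, focal_clade, rogues=()) -> float:
        if self.tally is None:
            raise PlacementError("fit with bootstrap>0 to get support values")
        return effective_support(self.tally, focal_clade, rogues)

    def region_support(self, region_taxa) -> float:
        if self.tally is None:
            raise PlacementError("fit with bootstrap>0 to get support values")
        return region_support(self.tally, region_taxa)

    def summary(self) -> str:
        df = self.placements()
        lines = [
            f"Placement of {self.model.query!r} "
            f"on {self.point.backbone.n_leaves}-leaf backbone",
            f"  candidate edges: {len(self.point.edges)}",
            f"  best edge: {df.iloc[0]['edge']}",
            f"  log-likelihood: {self.best_edge.loglik:.4f} "
            f"(margin to runner-up: {self.margin:.4f})",
            f"  pendant length: {self.best_edge.pendant:.6f}",
        ]
        if self.tally is not None:
            counts = self.tally.edge_counts()
            best_key = tuple(
                sorted(map(tuple, map(sorted, self.best_edge.split)))
            )
            freq = counts.get(best_key, 0)
            lines.append(
                f"  bootstrap: B={self.tally.B}, best-edge frequency "
                f"{100.0 * freq / self.tally.B:.1f}%"
            )
        return "\n".join(lines)

    def to_jplace(self) -> str:
        return write_jplace(self.point)


# ---------------------------------------------------------------------------
# spec-surface functional forms
# ---------------------------------------------------------------------------

def place_query(
    backbone: Tree,
    aln: PartitionedAlignment,
    models,
    query: str,
    xatol: float = 1e-6,
) -> PlacementResult:
    """Optimize the query's attachment on every backbone edge; ranked result."""
    return PlacementModel(aln, backbone, models, query).fit(xatol=xatol).point


def place_multiple(
    backbone: Tree,
    aln: PartitionedAlignment,
    models,
    queries: Sequence[str],
    xatol: float = 1e-5,
) -> dict[str, PlacementResult]:
    """Sequential insertion of several queries (most complete first) with one
    re-placement refinement pass; the refinement never lowers the total fit."""
    if not queries:
        raise PlacementError("need at least one query")
    order = sorted(queries, key=lambda t: (aln.taxon_missing_fraction(t), t))
    results: dict[str, PlacementResult] = {}
    tree = backbone
    for i, q in enumerate(order):
        pm = PlacementModel(aln, tree, models, q)
        res = pm._place_on(tree, q, other_extras=order[i + 1:], xatol=xatol)
        results[q] = res
        b = res.best
        tree = graft(tree, b.split, q, b.attach_fraction, b.pendant)
    if len(order) > 1:
        for q in order:
            reduced = prune_taxa(tree, [q])
            pm = PlacementModel(aln, reduced, models, q)
            res = pm._place_on(reduced, q, xatol=xatol)
            if res.best.loglik >= results[q].best.loglik:
                results[q] = res
                b = res.best
                tree = graft(reduced, b.split, q, b.attach_fraction, b.pendant)
            else:
                tree = graft(
                    reduced, results[q].best.split, q,
                    results[q].best.attach_fraction, results[q].best.pendant,
                )
    return {q: results[q] for q in queries}


def bootstrap_placements(
    backbone: Tree,
    aln: PartitionedAlignment,
    models,
    query: str,
    B: int = 100,
    seed: int | None = None,
    rogues: Sequence[str] = (),
) -> PlacementTally:
    """Nonparametric bootstrap of the placement (sites resampled within
    partitions; rogues re-placed jointly with the query)."""
    if B < 1:
        raise PlacementError("need at least one bootstrap replicate")
    pm = PlacementModel(aln, backbone, models, query, rogues=rogues)
    return pm._bootstrap(B, seed, xatol=2e-2)


# ---------------------------------------------------------------------------
# jplace export
# ---------------------------------------------------------------------------

def write_jplace(result: PlacementResult, top_n: int | None = None) -> str:
    """Serialize a placement as jplace (version 3) with edge numbers
    embedded in the reference-tree newick."""
    tree = result.backbone
    dt = tree.dendropy_tree
    edge_numbers: dict[tuple, int] = {}
    counter = [0]
    all_leaves = frozenset(tree.leaves)

    def render(node) -> str:
        if node.is_leaf():
            core = node.taxon.label
        else:
            core = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
        if node.parent_node is None:
            return core
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        key = tuple(sorted(map(tuple, map(sorted, (below, all_leaves - below)))))
        num = counter[0]
        edge_numbers.setdefault(key, num)
        counter[0] += 1
        ln = node.edge.length if node.edge.length is not None else 0.0
        return f"{core}:{ln:.9g}{{{edge_numbers[key]}}}"

    newick = render(dt.seed_node) + ";"
    lls = np.array([e.loglik for e in result.edges])
    lwr = np.exp(lls - logsumexp(lls))
    rows = []
    for e, w in zip(result.edges[: top_n or len(result.edges)], lwr):
        key = tuple(sorted(map(tuple, map(sorted, e.split))))
        rows.append(
            [
                edge_numbers[key],
                round(float(e.loglik), 6),
                round(float(w), 6),
                round(float(e.t_parent), 6),
                round(float(e.pendant), 6),
            ]
        )
    doc = {
        "version": 3,
        "tree": newick,
        "placements": [{"p": rows, "n": [result.query]}],
        "fields": [
            "edge_num", "likelihood", "like_weight_ratio",
            "distal_length", "pendant_length",
        ],
        "metadata": {"software": "phylotier"},
    }
    return json.dumps(doc, indent=1, sort_keys=True)
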