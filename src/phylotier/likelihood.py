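"""Felsenstein pruning likelihood with discrete-Gamma rate mixing.

The engine works on compressed site patterns and keeps, for every branch,
both the downward ("subtree below") and upward ("rest of tree") conditional
likelihood vectors.  That two-pass layout makes per-branch length
optimization and query placement cheap: evaluating the likelihood of a new
taxon grafted anywhere costs O(patterns) per candidate edge, independent of
tree size, and bootstrap replicates only redraw pattern weights.

Per-node rescaling (tracked in log space) keeps partials in floating range
for large trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from phylotier.seqdata import PartitionedAlignment, Partition
from phylotier.substmodels import PARTIALS, SubstitutionModel, ModelError
from phylotier.trees import Tree, TreeError

__all__ = [
    "PhyloArrays",
    "TreeLikelihood",
    "SitewiseLogLik",
    "site_loglik",
    "optimize_branch_lengths",
]

BL_MIN, BL_MAX = 1e-8, 10.0


@dataclass
class SitewiseLogLik:
    """Per-site log-likelihood matrix for a set of trees on one alignment."""

    tree_ids: list[str]
    matrix: np.ndarray  # (n_trees, n_sites)
    site_partitions: np.ndarray  # partition index per site
    partition_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.site_partitions = np.asarray(self.site_partitions, dtype=int)
        if self.matrix.shape[1] != self.site_partitions.size:
            raise ValueError("site partition labels do not match matrix width")
        if len(self.tree_ids) != self.matrix.shape[0]:
            raise ValueError("tree ids do not match matrix rows")

    @property
    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_table(self) -> str:
        """Sites x trees tab-separated table (header = tree ids)."""
        lines = ["site\t" + "\t".join(self.tree_ids)]
        for j in range(self.matrix.shape[1]):
            lines.append(
                str(j + 1) + "\t" + "\t".join(f"{v:.6f}" for v in self.matrix[:, j])
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "SitewiseLogLik":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        ids = lines[0].split("\t")[1:]
        rows = [[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]]
        m = np.array(rows).T
        return cls(ids, m, np.zeros(m.shape[1], dtype=int), ["all"])


class PhyloArrays:
    """Flat array view of a tree: parents, children, branch lengths,
    postorder schedule, and back-references to the dendropy nodes."""

    def __init__(self, tree: Tree):
        dt = tree.dendropy_tree
        self.dnodes = list(dt.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(self.dnodes)}
        n = len(self.dnodes)
        self.n_nodes = n
        self.parent = np.full(n, -1, dtype=int)
        self.blen = np.zeros(n)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.leaf_nodes: dict[str, int] = {}
        for i, node in enumerate(self.dnodes):
            if node.parent_node is not None:
                p = index[id(node.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                if node.edge.length is None:
                    raise TreeError("tree has missing branch lengths")
                self.blen[i] = max(float(node.edge.length), 0.0)
            if node.is_leaf():
                self.leaf_nodes[node.taxon.label] = i
        self.root = n - 1  # postorder puts the seed node last
        self.postorder = list(range(n))

    @property
    def edges(self) -> list[int]:
        """Branch ids = child-node ids (every node except the root)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def leafset_below(self, v: int) -> frozenset:
        out: set[str] = set()
        stack = [v]
        while stack:
            u = stack.pop()
            node = self.dnodes[u]
            if node.is_leaf():
                out.add(node.taxon.label)
            else:
                stack.extend(self.children[u])
        return frozenset(out)

    def write_lengths_back(self) -> None:
        for i, node in enumerate(self.dnodes):
            if i != self.root:
                node.edge.length = float(self.blen[i])


def _tip_partials_for_block(
    block: np.ndarray, taxa: Sequence[str]
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Compress columns of a character block into unique patterns.

    Returns (per-taxon (n_patterns, 4) partial arrays, pattern weights,
    site -> pattern index map).  Ambiguity codes become their IUPAC state
    sets; missing symbols contribute 1 for every state.
    """
    uniq, inverse, counts = np.unique(
        block, axis=1, return_inverse=True, return_counts=True
    )
    tipp: dict[str, np.ndarray] = {}
    lut = np.stack([PARTIALS.get(c, PARTIALS["N"]) for c in "ACGTURYSWKMBDHVNX?-"])
    code = {c: i for i, c in enumerate("ACGTURYSWKMBDHVNX?-")}
    for r, taxon in enumerate(taxa):
        idx = np.array([code.get(c, code["N"]) for c in uniq[r]], dtype=int)
        tipp[taxon] = lut[idx]
    return tipp, counts.astype(float), inverse


@dataclass
class _PartitionData:
    name: str
    sites: np.ndarray  # global site indices (sorted)
    model: SubstitutionModel
    tipp: dict[str, np.ndarray]  # taxon -> (p, 4)
    weights: np.ndarray  # (p,)
    inverse: np.ndarray  # site -> pattern

    @property
    def n_patterns(self) -> int:
        return self.weights.size


class TreeLikelihood:
    """Likelihood of one tree under per-partition substitution models.

    Parameters
    ----------
    tree : the (branch-length-bearing) topology; leaves must be alignment taxa.
    aln : partitioned alignment.
    models : a single model (applied to every partition) or a mapping
        ``partition name -> SubstitutionModel``; only mapped partitions enter
        the likelihood.
    extra_taxa : additional alignment taxa (e.g. placement queries) whose
        characters are included in pattern compression so their tip partials
        line up with the tree's pattern set.
    """

    def __init__(
        self,
        tree: Tree,
        aln: PartitionedAlignment,
        models: SubstitutionModel | Mapping[str, SubstitutionModel],
        extra_taxa: Sequence[str] = (),
    ):
        self.tree = tree
        self.arr = PhyloArrays(tree)
        leaves = set(self.arr.leaf_nodes)
        missing = leaves - set(aln.taxa)
        if missing:
            raise ModelError(f"tree taxa absent from alignment: {sorted(missing)}")
        if isinstance(models, SubstitutionModel):
            models = {p.name: models for p in aln.partitions}
        self.taxa = sorted(leaves) + [t for t in extra_taxa if t not in leaves]
        rows = [aln.taxa.index(t) for t in self.taxa]
        self.parts: list[_PartitionData] = []
        for p in aln.partitions:
            if p.name not in models:
                continue
            block = aln.matrix[np.ix_(rows, aln.sites_of(p))]
            tipp, weights, inverse = _tip_partials_for_block(block, self.taxa)
            self.parts.append(
                _PartitionData(p.name, aln.sites_of(p), models[p.name], tipp,
                               weights, inverse)
            )
        if not self.parts:
            raise ModelError("no partitions selected for likelihood")
        self._cache: dict | None = None

    # -- core passes -----------------------------------------------------
    def _pmats(self, part: _PartitionData) -> np.ndarray:
        """(n_nodes, K, 4, 4) per-branch transition matrices."""
        m = part.model
        w, left, right = m._eigensystem()
        ts = np.outer(self.arr.blen * m.rate_scale, m.category_rates())  # (n, K)
        ew = np.exp(ts[..., None] * w)  # (n, K, 4)
        P = np.einsum("iw,nkw,wj->nkij", left, ew, right)
        return np.clip(P, 0.0, None)

    def _down(self, part: _PartitionData, P: np.ndarray):
        """Postorder partials D (n_nodes, p, K, 4) and log-scales (n_nodes, p, K)."""
        arr = self.arr
        K = part.model.category_rates().size
        p = part.n_patterns
        D = np.empty((arr.n_nodes, p, K, 4))
        S = np.zeros((arr.n_nodes, p, K))
        for v in arr.postorder:
            if not arr.children[v]:
                label = arr.dnodes[v].taxon.label
                D[v] = part.tipp[label][:, None, :]
                continue
            acc = None
            s_acc = np.zeros((p, K))
            for c in arr.children[v]:
                T = np.einsum("pky,kxy->pkx", D[c], P[c])
                acc = T if acc is None else acc * T
                s_acc += S[c]
            m = np.maximum(acc.max(axis=-1, keepdims=True), 1e-300)
            D[v] = acc / m
            S[v] = s_acc + np.log(m[..., 0])
        return D, S

    def _up(self, part: _PartitionData, P: np.ndarray, D: np.ndarray, S: np.ndarray):
        """Preorder partials H (rest-of-tree, at the parent end of each
        branch, stationary frequencies *not* applied) with log-scales."""
        arr = self.arr
        H = np.empty_like(D)
        SH = np.zeros_like(S)
        G = np.empty_like(D)
        SG = np.zeros_like(S)
        G[arr.root] = 1.0
        SG[arr.root] = 0.0
        for v in reversed(arr.postorder):  # preorder
            if not arr.children[v]:
                continue
            kids = arr.children[v]
            Ts = {c: np.einsum("pky,kxy->pkx", D[c], P[c]) for c in kids}
            for c in kids:
                acc = G[v].copy()
                s_acc = SG[v].copy()
                for s in kids:
                    if s is c:
                        continue
                    acc = acc * Ts[s]
                    s_acc = s_acc + S[s]
                m = np.maximum(acc.max(axis=-1, keepdims=True), 1e-300)
                H[c] = acc / m
                SH[c] = s_acc + np.log(m[..., 0])
                Gc = np.einsum("pkx,kyx->pky", H[c], P[c])
                m2 = np.maximum(Gc.max(axis=-1, keepdims=True), 1e-300)
                G[c] = Gc / m2
                SG[c] = SH[c] + np.log(m2[..., 0])
        return H, SH

    def _ensure_cache(self, with_up: bool = False) -> dict:
        if self._cache is None or (with_up and "H" not in next(iter(self._cache.values()))):
            cache = {}
            for part in self.parts:
                P = self._pmats(part)
                D, S = self._down(part, P)
                entry = {"P": P, "D": D, "S": S}
                if with_up:
                    H, SH = self._up(part, P, D, S)
                    entry["H"], entry["SH"] = H, SH
                cache[part.name] = entry
            self._cache = cache
        return self._cache

    def invalidate(self) -> None:
        self._cache = None

    def with_models(
        self, models: SubstitutionModel | Mapping[str, SubstitutionModel]
    ) -> "TreeLikelihood":
        """Same tree and compressed patterns under different models (cheap:
        pattern compression and tree arrays are shared, not recomputed)."""
        from dataclasses import replace as _replace

        mapping = (
            {p.name: models for p in self.parts}
            if isinstance(models, SubstitutionModel)
            else models
        )
        new = object.__new__(TreeLikelihood)
        new.tree = self.tree
        new.arr = self.arr
        new.taxa = self.taxa
        new.parts = [_replace(p, model=mapping[p.name]) for p in self.parts]
        new._cache = None
        return new

    # -- likelihood queries ----------------------------------------------
    def pattern_logliks(self, part: _PartitionData) -> np.ndarray:
        cache = self._ensure_cache()[part.name]
        pi = np.asarray(part.model.freqs)
        root = self.arr.root
        lik = np.maximum(np.einsum("pkx,x->pk", cache["D"][root], pi), 1e-300)
        K = lik.shape[1]
        return logsumexp(np.log(lik) + cache["S"][root], axis=1) - np.log(K)

    def total_loglik(self) -> float:
        return float(
            sum(self.pattern_logliks(p) @ p.weights for p in self.parts)
        )

    def site_logliks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-site log-likelihoods in global site order.

        Returns (values, global site indices, partition index per site).
        """
        vals, sites, pidx = [], [], []
        for k, part in enumerate(self.parts):
            per_pattern = self.pattern_logliks(part)
            vals.append(per_pattern[part.inverse])
            sites.append(part.sites)
            pidx.append(np.full(part.sites.size, k))
        order = np.argsort(np.concatenate(sites), kind="stable")
        return (
            np.concatenate(vals)[order],
            np.concatenate(sites)[order],
            np.concatenate(pidx)[order],
        )

    # -- branch-length optimization ---------------------------------------
    def _edge_loglik(self, v: int, t: float) -> float:
        """Total log-likelihood with branch ``v`` set to ``t`` (partials for
        the rest of the tree taken from the cache)."""
        total = 0.0
        cache = self._ensure_cache(with_up=True)
        for part in self.parts:
            e = cache[part.name]
            m = part.model
            w, left, right = m._eigensystem()
            ts = t * m.rate_scale * m.category_rates()
            P = np.clip(
                np.einsum("iw,kw,wj->kij", left, np.exp(np.outer(ts, w)), right),
                0.0, None,
            )
            pi = np.asarray(m.freqs)
            lik = np.einsum("pkx,x,kxy,pky->pk", e["H"][v], pi, P, e["D"][v])
            lik = np.maximum(lik, 1e-300)
            K = lik.shape[1]
            ll = logsumexp(np.log(lik) + e["S"][v] + e["SH"][v], axis=1) - np.log(K)
            total += float(ll @ part.weights)
        return total

    def optimize_branch_lengths(
        self, tol: float = 1e-6, max_sweeps: int = 20
    ) -> float:
        """Round-robin Brent optimization of every branch until the total
        log-likelihood improves by less than ``tol``; returns the final
        log-likelihood.  The log-likelihood is guaranteed non-decreasing
        across sweeps (a decrease beyond numerical tolerance raises)."""
        arr = self.arr
        last = self.total_loglik()
        for _ in range(max_sweeps):
            for v in arr.edges:
                self.invalidate()
                self._ensure_cache(with_up=True)
                res = minimize_scalar(
                    lambda t: -self._edge_loglik(v, t),
                    bounds=(BL_MIN, BL_MAX),
                    method="bounded",
                    options={"xatol": 1e-8},
                )
                if -res.fun >= self._edge_loglik(v, arr.blen[v]):
                    arr.blen[v] = float(res.x)
            self.invalidate()
            now = self.total_loglik()
            if now < last - 1e-4:
                raise RuntimeError(
                    f"log-likelihood decreased during optimization "
                    f"({last:.6f} -> {now:.6f}); this is a bug"
                )
            if now - last < tol:
                last = now
                break
            last = now
        return last

    def write_lengths_back(self) -> None:
        self.arr.write_lengths_back()


# ---------------------------------------------------------------------------
# module-level operation forms
# ---------------------------------------------------------------------------

def site_loglik(
    tree: Tree,
    aln: PartitionedAlignment,
    models: SubstitutionModel | Mapping[str, SubstitutionModel],
    tree_id: str = "tree",
) -> SitewiseLogLik:
    """Site-wise log-likelihoods of one tree (fixed branch lengths)."""
    lk = TreeLikelihood(tree, aln, models)
    vals, _sites, pidx = lk.site_logliks()
    return SitewiseLogLik(
        [tree_id], vals[None, :], pidx, [p.name for p in lk.parts]
    )


def optimize_branch_lengths(
    tree: Tree,
    aln: PartitionedAlignment,
    models: SubstitutionModel | Mapping[str, SubstitutionModel],
    tol: float = 1e-6,
) -> tuple[Tree, float]:
    """Optimize all branch lengths of ``tree`` (returned as a new tree)."""
    work = tree.copy()
    lk = TreeLikelihood(work, aln, models)
    ll = lk.optimize_branch_lengths(tol=tol)
    lk.write_lengths_back()
    return work, ll
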