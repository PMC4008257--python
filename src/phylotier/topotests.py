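"""Topology comparison on a fixed alignment: RELL bootstrap and the AU test.

Candidate trees are compared through their site-wise log-likelihood
matrices.  The RELL ("resampling estimated log-likelihoods") bootstrap
resamples site columns — within partitions when the matrix is partitioned —
without re-optimizing anything.  The Approximately Unbiased test runs the
RELL resampling at several scales r (replicate size ceil(r * n_sites)),
records each tree's winning proportion BP(r), fits the normal-theory
relation  z(r) = Phi^{-1}(1 - BP(r)) = d*sqrt(r) + c/sqrt(r)  by weighted
least squares, and reports  p_AU = 1 - Phi(d - c),  where d plays the role
of a signed distance to the boundary of the tree's optimality region and c
its curvature.  Trees rejected at the 0.05 level are considered
significantly worse fits than the maximum-likelihood tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from phylotier.likelihood import SitewiseLogLik, TreeLikelihood, optimize_branch_lengths
from phylotier.seqdata import PartitionedAlignment
from phylotier.substmodels import SubstitutionModel
from phylotier.trees import Tree, TreeError, strict_consensus

__all__ = [
    "AUResult",
    "sitewise_matrix",
    "rell_bootstrap",
    "au_test",
    "kh_pvalues",
    "compare_restricted",
    "RestrictedComparison",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


def sitewise_matrix(
    trees: Sequence[Tree],
    aln: PartitionedAlignment,
    models: SubstitutionModel | Mapping[str, SubstitutionModel],
    tree_ids: Sequence[str] | None = None,
    optimize: bool = True,
    tol: float = 1e-4,
) -> SitewiseLogLik:
    """Site-wise log-likelihoods of several trees on one alignment.

    Branch lengths are optimized independently per tree; rows share one
    site order, and each row sums to that tree's optimized log-likelihood.
    """
    if len(trees) < 2:
        raise TreeError("need at least two trees to compare")
    leafsets = {frozenset(t.leaves) for t in trees}
    if len(leafsets) != 1:
        raise TreeError("trees must share one leaf set; restrict first")
    ids = list(tree_ids) if tree_ids is not None else [
        f"tree{i + 1}" for i in range(len(trees))
    ]
    rows = []
    pidx_ref = None
    pnames = None
    for tree in trees:
        work = tree
        if optimize:
            work, _ = optimize_branch_lengths(tree, aln, models, tol=tol)
        lk = TreeLikelihood(work, aln, models)
        vals, _sites, pidx = lk.site_logliks()
        rows.append(vals)
        pidx_ref = pidx
        pnames = [p.name for p in lk.parts]
    return SitewiseLogLik(ids, np.vstack(rows), pidx_ref, pnames)


def _stratum_indices(matrix: SitewiseLogLik) -> list[np.ndarray]:
    parts = matrix.site_partitions
    return [np.nonzero(parts == k)[0] for k in np.unique(parts)]


def rell_bootstrap(
    matrix: SitewiseLogLik, B: int, seed: int | None = None, scale: float = 1.0
) -> np.ndarray:
    """(B, n_trees) bootstrap totals by resampling site columns with
    replacement (within partitions), without re-optimization."""
    if B < 1:
        raise ValueError("need B >= 1")
    rng = np.random.default_rng(seed)
    totals = np.zeros((B, matrix.matrix.shape[0]))
    for idx in _stratum_indices(matrix):
        m = int(np.ceil(scale * idx.size))
        counts = rng.multinomial(m, np.full(idx.size, 1.0 / idx.size), size=B)
        totals += counts @ matrix.matrix[:, idx].T
    return totals


@dataclass
class AUResult:
    """Per-tree outcome of the multiscale RELL / AU procedure."""

    tree_ids: list[str]
    p_values: np.ndarray
    naive_bp: np.ndarray  # winning proportion at scale 1
    d: np.ndarray  # signed distance
    c: np.ndarray  # curvature
    bp: np.ndarray  # (n_trees, n_scales)
    scales: np.ndarray
    B_per_scale: int
    seed: int | None
    degenerate: np.ndarray = field(default=None)  # bool per tree

    def summary(self) -> str:
        df = self.table()
        lines = ["tree\tau_p\tnaive_bp\td\tc\trank"]
        for _, r in df.iterrows():
            lines.append(
                f"{r['tree']}\t{r['au_p']:.4f}\t{r['naive_bp']:.4f}"
                f"\t{r['d']:.4f}\t{r['c']:.4f}\t{int(r['rank'])}"
            )
        return "\n".join(lines) + "\n"

    def table(self) -> pd.DataFrame:
        order = np.argsort(-self.p_values)
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(order) + 1)
        return pd.DataFrame(
            {
                "tree": self.tree_ids,
                "au_p": self.p_values,
                "naive_bp": self.naive_bp,
                "d": self.d,
                "c": self.c,
                "rank": rank,
            }
        )


def _winning_proportions(totals: np.ndarray) -> np.ndarray:
    """Per-tree fraction of replicates in which it attains the maximum
    (ties split as equal fractional counts)."""
    B, n = totals.shape
    best = totals.max(axis=1, keepdims=True)
    is_max = np.isclose(totals, best, rtol=0.0, atol=1e-9)
    return (is_max / is_max.sum(axis=1, keepdims=True)).sum(axis=0) / B


def au_test(
    matrix: SitewiseLogLik,
    scales: Sequence[float] = DEFAULT_SCALES,
    B_per_scale: int = 10000,
    seed: int | None = None,
) -> AUResult:
    """Approximately Unbiased test via multiscale RELL bootstrap.

    Winning proportions of exactly 0 or 1 are continuity-corrected to
    1/(2B) and 1 - 1/(2B); a tree with fewer than three informative scales
    is reported with a degenerate p of 0 or 1.
    """
    if matrix.matrix.shape[0] < 2:
        raise ValueError("need at least two trees")
    scales = np.asarray(sorted(scales), dtype=float)
    rng = np.random.default_rng(seed)
    n_trees = matrix.matrix.shape[0]
    bp = np.empty((n_trees, scales.size))
    for si, r in enumerate(scales):
        totals = rell_bootstrap(
            matrix, B_per_scale, seed=int(rng.integers(2**31 - 1)), scale=float(r)
        )
        bp[:, si] = _winning_proportions(totals)
    idx_one = int(np.argmin(np.abs(scales - 1.0)))
    naive = bp[:, idx_one].copy()
    eps = 1.0 / (2.0 * B_per_scale)
    informative = (bp > 0.0) & (bp < 1.0)
    bp_c = np.clip(bp, eps, 1.0 - eps)
    p = np.empty(n_trees)
    d = np.zeros(n_trees)
    c = np.zeros(n_trees)
    degen = np.zeros(n_trees, dtype=bool)
    for j in range(n_trees):
        use = informative[j]
        if use.sum() < 3:
            degen[j] = True
            high = bp[j].mean() >= 0.5
            p[j] = (1.0 - eps) if high else eps
            continue
        r = scales[use]
        z = norm.ppf(1.0 - bp_c[j, use])
        X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        w = B_per_scale * norm.pdf(z) ** 2 / (bp_c[j, use] * (1.0 - bp_c[j, use]))
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        d[j], c[j] = beta
        p[j] = float(1.0 - norm.cdf(d[j] - c[j]))
    return AUResult(
        list(matrix.tree_ids), p, naive, d, c, bp, scales, B_per_scale, seed, degen
    )


def kh_pvalues(
    matrix: SitewiseLogLik, B: int = 10000, seed: int | None = None
) -> np.ndarray:
    """One-sided Kishino-Hasegawa-style p per tree against the ML tree,
    from the normal approximation to centred RELL difference totals."""
    obs = matrix.totals
    best = int(np.argmax(obs))
    totals = rell_bootstrap(matrix, B, seed=seed)
    p = np.ones(obs.size)
    for j in range(obs.size):
        if j == best:
            continue
        delta = totals[:, best] - totals[:, j]
        centred = delta - delta.mean()
        obs_delta = obs[best] - obs[j]
        sd = max(centred.std(ddof=1), 1e-12)
        p[j] = float(1.0 - norm.cdf(obs_delta / sd))
    return p


@dataclass
class RestrictedComparison:
    """Two-tree report: optimized fits, their difference, AU p-values, and
    the strict consensus topology."""

    tree_ids: tuple[str, str]
    logliks: tuple[float, float]
    difference: float  # loglik(a) - loglik(b)
    au_p: tuple[float, float]
    consensus: Tree

    def summary(self) -> str:
        a, b = self.tree_ids
        return (
            f"{a}: lnL = {self.logliks[0]:.4f} (AU p = {self.au_p[0]:.4f})\n"
            f"{b}: lnL = {self.logliks[1]:.4f} (AU p = {self.au_p[1]:.4f})\n"
            f"difference: {self.difference:.4f}\n"
            f"strict consensus: {self.consensus.to_newick()}\n"
        )


def compare_restricted(
    tree_a: Tree,
    tree_b: Tree,
    aln: PartitionedAlignment,
    models: SubstitutionModel | Mapping[str, SubstitutionModel],
    tree_ids: tuple[str, str] = ("tree_a", "tree_b"),
    B_per_scale: int = 10000,
    seed: int | None = None,
) -> RestrictedComparison:
    """Compare two trees already restricted to identical taxa: optimized
    log-likelihoods, their difference, two-tree AU p-values, and the strict
    consensus."""
    if frozenset(tree_a.leaves) != frozenset(tree_b.leaves):
        raise TreeError("trees must be restricted to identical taxa first")
    matrix = sitewise_matrix([tree_a, tree_b], aln, models, tree_ids=list(tree_ids))
    if set(tree_a.splits()) == set(tree_b.splits()):
        totals = matrix.totals
        return RestrictedComparison(
            tree_ids, (float(totals[0]), float(totals[1])),
            float(totals[0] - totals[1]), (1.0, 1.0),
            strict_consensus([tree_a, tree_b]),
        )
    res = au_test(matrix, B_per_scale=B_per_scale, seed=seed)
    totals = matrix.totals
    return RestrictedComparison(
        tree_ids,
        (float(totals[0]), float(totals[1])),
        float(totals[0] - totals[1]),
        (float(res.p_values[0]), float(res.p_values[1])),
        strict_consensus([tree_a, tree_b]),
    )
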