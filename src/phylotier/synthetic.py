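"""Seeded synthetic placement studies.

Generates data with the statistical structure the analysis assumes: a
backbone tree, a multi-marker supermatrix with block-structured missing
data (whole taxon x marker blocks, the way real supermatrices are missing
entire markers for a taxon), mixed mitochondrial/nuclear partitions with
heterogeneous rates — including fast third codon positions that plant
substitution saturation — a query taxon with a known attachment edge, and
optional contaminant ("outlier") sequences.

Everything is driven by an integer seed through numpy's Generator, so
identical configurations reproduce byte-identical studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from phylotier.placement import graft, prune_taxa
from phylotier.seqdata import Partition, PartitionedAlignment, missing_fraction
from phylotier.substmodels import NUC, SubstitutionModel
from phylotier.trees import Tree

__all__ = [
    "PartitionSpec",
    "SyntheticStudyConfig",
    "TruthRecord",
    "random_tree",
    "simulate_alignment",
    "make_placement_study",
    "apply_missingness",
    "inject_outlier",
    "default_study_config",
]


@dataclass(frozen=True)
class PartitionSpec:
    """One simulated marker: length, origin, model, and rate structure.

    ``rate_multiplier`` scales the whole marker; for coding markers
    ``position_rates`` additionally scales first/second/third codon
    positions (third positions on mitochondrial genes are the classical
    saturation risk).
    """

    name: str
    length: int
    origin: str = "nuclear"
    coding: bool = True
    model: SubstitutionModel = field(default_factory=SubstitutionModel.jc)
    rate_multiplier: float = 1.0
    position_rates: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def site_rates(self) -> np.ndarray:
        rates = np.full(self.length, self.rate_multiplier)
        if self.coding:
            pos = np.arange(self.length) % 3
            rates *= np.asarray(self.position_rates)[pos]
        return rates


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study-level design: backbone size, markers, query, missingness."""

    seed: int
    n_leaves: int = 12
    partitions: tuple[PartitionSpec, ...] = ()
    branch_length_range: tuple[float, float] = (0.008, 0.045)
    query_name: str = "query"
    pendant_length: float = 0.05
    true_edge: tuple | None = None  # split over backbone leaves, or None=random
    missingness: float = 0.0
    outlier_taxon: str | None = None
    outlier_partition: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError("missingness target must be in [0, 1)")
        for p in self.partitions:
            if p.rate_multiplier <= 0 or min(p.position_rates) <= 0:
                raise ValueError("rate multipliers must be positive")


@dataclass
class TruthRecord:
    """Planted ground truth emitted alongside a synthetic study."""

    query: str
    true_edge: tuple[frozenset, frozenset]
    pendant_length: float
    saturated_units: tuple[str, ...] = ()
    outlier: tuple[str, str] | None = None  # (taxon, partition)

    def to_text(self) -> str:
        lines = [
            f"query\t{self.query}",
            "true_edge\t" + " | ".join(
                ",".join(sorted(s)) for s in sorted(self.true_edge, key=lambda x: tuple(sorted(x)))
            ),
            f"pendant_length\t{self.pendant_length}",
            "saturated_units\t" + ",".join(self.saturated_units),
        ]
        if self.outlier:
            lines.append(f"outlier\t{self.outlier[0]}\t{self.outlier[1]}")
        return "\n".join(lines) + "\n"


def default_study_config(seed: int, **overrides) -> SyntheticStudyConfig:
    """The package's reference fixture: a 12-leaf backbone and six markers
    (two mitochondrial protein-coding genes, one mitochondrial rRNA, three
    nuclear protein-coding genes, ~5 kb total).  Mitochondrial markers
    evolve twice as fast overall and their third codon positions 15x faster,
    planting clear substitution saturation in exactly those two units."""
    mito_model = SubstitutionModel.hky(
        kappa=6.0, freqs=(0.32, 0.27, 0.11, 0.30), gamma_shape=0.4
    )
    nuc_model = SubstitutionModel.hky(
        kappa=3.0, freqs=(0.27, 0.23, 0.23, 0.27), gamma_shape=0.8
    )
    parts = (
        PartitionSpec("cytb", 900, "mitochondrial", True, mito_model, 1.5, (1.0, 0.5, 15.0)),
        PartitionSpec("nd2", 900, "mitochondrial", True, mito_model, 1.5, (1.0, 0.5, 15.0)),
        PartitionSpec("rrn16", 800, "mitochondrial", False, mito_model, 1.2),
        PartitionSpec("rag1", 900, "nuclear", True, nuc_model, 1.0, (1.0, 0.5, 1.5)),
        PartitionSpec("pomc", 800, "nuclear", True, nuc_model, 1.0, (1.0, 0.5, 1.5)),
        PartitionSpec("tyr", 700, "nuclear", True, nuc_model, 1.0, (1.0, 0.5, 1.5)),
    )
    cfg = SyntheticStudyConfig(seed=seed, n_leaves=12, partitions=parts)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# tree and sequence simulation
# ---------------------------------------------------------------------------

def random_tree(
    n_leaves: int,
    rng: np.random.Generator,
    branch_length_range: tuple[float, float] = (0.008, 0.045),
    prefix: str = "t",
) -> Tree:
    """Random binary unrooted topology by successive random joins, with
    i.i.d. uniform branch lengths."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    lo, hi = branch_length_range
    names = [f"{prefix}{i + 1:02d}" for i in range(n_leaves)]

    def bl() -> str:
        return f"{rng.uniform(lo, hi):.6f}"

    nodes = [f"{n}:{bl()}" for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{bl()}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return Tree.from_newick("(" + ",".join(nodes) + ");")


def simulate_alignment(
    tree: Tree,
    model: SubstitutionModel,
    length: int,
    seed: int | np.random.Generator,
    site_rate_multipliers: np.ndarray | None = None,
    partition_name: str = "all",
) -> PartitionedAlignment:
    """Evolve sequences along ``tree`` under ``model``.

    Root states are drawn from the stationary frequencies; each site draws a
    discrete-Gamma rate category once (shared across branches) and states
    evolve edge by edge with the corresponding transition matrices.
    ``site_rate_multipliers`` scales individual sites on top of the Gamma
    rates (used to plant fast codon positions).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if length < 1:
        raise ValueError("length must be >= 1")
    mult = (
        np.ones(length)
        if site_rate_multipliers is None
        else np.asarray(site_rate_multipliers, dtype=float)
    )
    if mult.shape != (length,):
        raise ValueError("site_rate_multipliers must match length")
    cat_rates = model.category_rates()
    site_cat = rng.integers(0, cat_rates.size, size=length)
    site_rate = cat_rates[site_cat] * mult * model.rate_scale
    pi = np.asarray(model.freqs)
    w, left, right = model._eigensystem()

    from phylotier.likelihood import PhyloArrays

    arr = PhyloArrays(tree)
    states = np.empty((arr.n_nodes, length), dtype=np.int8)
    root = arr.root
    states[root] = rng.choice(4, size=length, p=pi)
    unique_rates, inverse = np.unique(site_rate, return_inverse=True)
    for v in reversed(arr.postorder):  # preorder
        if v == root:
            continue
        parent_states = states[arr.parent[v]]
        t = arr.blen[v]
        ew = np.exp(np.outer(unique_rates * t, w))  # (R, 4)
        P = np.clip(np.einsum("iw,rw,wj->rij", left, ew, right), 0.0, None)
        P = P / P.sum(axis=2, keepdims=True)
        probs = P[inverse, parent_states]  # (length, 4)
        u = rng.random(length)
        states[v] = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
    taxa = sorted(arr.leaf_nodes)
    matrix = np.array(
        [[NUC[s] for s in states[arr.leaf_nodes[t]]] for t in taxa], dtype="<U1"
    )
    part = Partition(partition_name, tuple(range(length)))
    return PartitionedAlignment(taxa, matrix, [part])


def make_placement_study(
    config: SyntheticStudyConfig,
) -> tuple[Tree, PartitionedAlignment, TruthRecord]:
    """Backbone tree, supermatrix including the query, and ground truth.

    The full tree (query grafted at its true edge) drives the simulation;
    the emitted backbone is the query-pruned tree, so recovering the true
    edge is a well-posed placement problem.
    """
    rng = np.random.default_rng(config.seed)
    backbone = random_tree(config.n_leaves, rng, config.branch_length_range)
    splits = sorted(
        backbone.splits(include_trivial=True),
        key=lambda s: (len(s), tuple(sorted(s))),
    )
    if config.true_edge is not None:
        edge = config.true_edge
    else:
        edge = splits[int(rng.integers(0, len(splits)))]
    full = graft(backbone, edge, config.query_name, 0.5, config.pendant_length)
    parts = config.partitions or default_study_config(config.seed).partitions
    gene_alns = []
    offset = 0
    blocks = []
    partition_objs = []
    for spec in parts:
        sub = simulate_alignment(
            full, spec.model, spec.length, rng,
            site_rate_multipliers=spec.site_rates(),
            partition_name=spec.name,
        )
        blocks.append(sub.matrix)
        partition_objs.append(
            Partition(
                spec.name,
                tuple(range(offset, offset + spec.length)),
                origin=spec.origin,
                coding=spec.coding,
                frame=0 if spec.coding else None,
            )
        )
        offset += spec.length
        gene_alns.append(sub)
    taxa = gene_alns[0].taxa
    aln = PartitionedAlignment(taxa, np.hstack(blocks), partition_objs)
    if config.missingness > 0:
        aln = apply_missingness(
            aln, config.missingness, rng, protect=[config.query_name]
        )
    saturated = tuple(
        f"{spec.name}_pos3" for spec in parts
        if spec.coding and spec.position_rates[2] * spec.rate_multiplier >= 10.0
    )
    outlier = None
    if config.outlier_taxon is not None:
        aln = inject_outlier(
            aln, config.outlier_taxon, config.outlier_partition or parts[0].name, rng
        )
        outlier = (config.outlier_taxon, config.outlier_partition or parts[0].name)
    sideA = frozenset(edge) if not isinstance(edge, tuple) else frozenset(edge[0])
    truth = TruthRecord(
        config.query_name,
        (sideA, frozenset(backbone.leaves) - sideA),
        config.pendant_length,
        saturated,
        outlier,
    )
    return backbone, aln, truth


def apply_missingness(
    aln: PartitionedAlignment,
    target_fraction: float,
    seed: int | np.random.Generator,
    protect: Sequence[str] = (),
    tolerance: float = 0.02,
) -> PartitionedAlignment:
    """Mask whole taxon x marker blocks until the global missing fraction is
    within ``tolerance`` of the target; every taxon keeps at least one
    unmasked marker (and ``protect`` taxa are never masked)."""
    if not (0.0 <= target_fraction <= 0.95):
        raise ValueError("target_fraction must be in [0, 0.95]")
    out = aln.copy()
    if target_fraction == 0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    candidates = [
        (t, p.name) for t in aln.taxa if t not in set(protect) for p in aln.partitions
    ]
    order = rng.permutation(len(candidates))
    unmasked: dict[str, set[str]] = {
        t: {p.name for p in aln.partitions} for t in aln.taxa
    }
    total_cells = out.matrix.size
    n_missing = int(np.isin(out.matrix, list("?-N")).sum())
    for idx in order:
        if n_missing / total_cells >= target_fraction - tolerance:
            break
        taxon, pname = candidates[idx]
        if len(unmasked[taxon]) <= 1:
            continue
        sites = out.sites_of(pname)
        block = out.matrix[out.taxa.index(taxon), sites]
        gain = int((~np.isin(block, list("?-N"))).sum())
        if (n_missing + gain) / total_cells > target_fraction + tolerance:
            continue
        out.matrix[out.taxa.index(taxon), sites] = "?"
        unmasked[taxon].discard(pname)
        n_missing += gain
    achieved = n_missing / total_cells
    if achieved < target_fraction - tolerance:
        raise ValueError(
            f"missingness target {target_fraction:.2f} unreachable under the "
            f"last-marker guard; achieved {achieved:.3f}"
        )
    return out


def inject_outlier(
    aln: PartitionedAlignment,
    taxon: str,
    partition: str,
    seed: int | np.random.Generator,
) -> PartitionedAlignment:
    """Replace one taxon's block in one partition with i.i.d. uniform bases
    (a contaminant / non-homolog stand-in); everything else untouched."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = aln.copy()
    sites = out.sites_of(partition)
    row = out.taxa.index(taxon)
    out.matrix[row, sites] = np.array(list(NUC))[rng.integers(0, 4, size=sites.size)]
    return out
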