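"""End-to-end two-tiered placement workflow.

Tier 1 ("large scale"): clean the supermatrix, run per-gene QC trees,
screen gene x codon-position units for saturation, place the query on the
full backbone under the topological constraint, and bootstrap the
placement with rogue-aware tallies.  The tally circumscribes a region of
the tree (cumulative bootstrap support), from which a focused taxon subset
is selected — all clades needed to cover the region plus the most complete
representatives of designated outgroup clades.

Tier 2 ("small scale"): re-place and re-bootstrap on the subset, build
rival hypothesis trees by regrafting the query onto the best-fitting tree
(so rivals are not penalised for unrelated topological differences), and
adjudicate them with AU tests on recomputed site-wise log-likelihoods.

The pipeline is a pure function of (inputs, config, seed): rerunning with
the same configuration reproduces byte-identical artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from phylotier import __version__
from phylotier.likelihood import TreeLikelihood, optimize_branch_lengths
from phylotier.placement import (
    PlacementError,
    PlacementModel,
    graft,
    prune_taxa,
    region_support,
    select_subset,
    write_jplace,
)
from phylotier.saturation import (
    estimate_hky_model,
    saturation_pairs,
    screen_partitions,
)
from phylotier.seqdata import (
    PartitionedAlignment,
    clean_alignment,
    missing_fraction,
    read_alignment,
    write_alignment,
)
from phylotier.substmodels import SubstitutionModel, ml_pairwise_distance
from phylotier.topotests import au_test, sitewise_matrix
from phylotier.trees import Tree, neighbor_joining, restrict_to_taxa, strict_consensus
from phylotier.saturation import InsufficientDataError
from phylotier.trees import DistanceMatrix

__all__ = ["RunConfig", "GeneQC", "single_gene_qc", "estimate_unit_models", "run_two_tier"]


@dataclass
class RunConfig:
    """Configuration of a two-tier run (paths + thresholds + seeds)."""

    alignment: str
    backbone: str
    query: str
    output_dir: str
    partition_table: str | None = None
    rogues: list[str] = field(default_factory=list)
    focal_clade: list[str] = field(default_factory=list)
    outgroup_clades: dict[str, list[str]] = field(default_factory=dict)
    hypotheses: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 1
    bootstrap: int = 100
    qc_bootstrap: int = 50
    au_replicates: int = 2000
    region_threshold: float = 95.0
    k_outgroup: int = 2
    plateau_threshold: float = 0.5
    slope_threshold: float = 0.3
    outlier_k: float = 5.0
    min_sites: int = 50
    optimize_backbone: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        for p in (self.alignment, self.backbone):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.bootstrap < 1:
            raise ValueError("bootstrap must be >= 1")


@dataclass
class GeneQC:
    """Per-gene sanity check of a newly added (query) sequence."""

    gene: str
    n_taxa: int
    neighbors: tuple[str, ...]
    frequency: float  # bootstrap % of the modal neighbour set
    flagged: bool = False
    note: str = ""


def _query_neighbors(tree: Tree, query: str) -> frozenset:
    a, b = tree.attachment_split(query)
    return a if len(a) <= len(b) else b


def single_gene_qc(
    aln: PartitionedAlignment,
    query: str,
    B: int = 50,
    seed: int | None = None,
    min_sites: int = 50,
    conflict_threshold: float = 70.0,
) -> list[GeneQC]:
    """Distance-tree QC of the query in every gene it has data for.

    For each gene, an NJ tree on model-corrected distances gives the
    query's nearest-neighbour group; a site bootstrap gives that group's
    frequency.  A gene is flagged when its neighbour group is supported at
    or above ``conflict_threshold`` percent yet disjoint from the majority
    neighbour group across genes — the signature of a sequencing error or
    contamination in one marker.
    """
    rng = np.random.default_rng(seed)
    results: list[GeneQC] = []
    per_gene_neighbors: dict[str, frozenset] = {}
    for part in aln.partitions:
        block = aln.block(part)
        qrow = block[aln.taxa.index(query)]
        if not np.isin(qrow, list("ACGT")).any():
            continue
        det = np.isin(block, list("ACGT"))
        usable = [
            i for i in range(aln.n_taxa)
            if det[i].sum() >= min(min_sites, max(10, part.n_sites // 10))
        ]
        if aln.taxa.index(query) not in usable:
            usable.append(aln.taxa.index(query))
        if len(usable) < 4:
            results.append(
                GeneQC(part.name, len(usable), (), 0.0, note="skipped: <4 taxa")
            )
            continue
        taxa = [aln.taxa[i] for i in usable]
        sub = block[usable]
        model = estimate_hky_model(sub)
        tree = _nj_from_block(sub, taxa, model)
        neighbors = _query_neighbors(tree, query)
        hits = 0
        for _ in range(B):
            cols = rng.integers(0, sub.shape[1], size=sub.shape[1])
            btree = _nj_from_block(sub[:, cols], taxa, model)
            if _query_neighbors(btree, query) == neighbors:
                hits += 1
        freq = 100.0 * hits / B
        per_gene_neighbors[part.name] = neighbors
        results.append(GeneQC(part.name, len(taxa), tuple(sorted(neighbors)), freq))
    # cross-gene conflict: flag confident neighbour groups disjoint from the
    # modal group over genes
    confident = [r for r in results if r.frequency >= conflict_threshold and r.neighbors]
    if len(confident) >= 2:
        groups: dict[frozenset, int] = {}
        for r in confident:
            key = frozenset(r.neighbors)
            merged = next((g for g in groups if g & key), None)
            if merged is None:
                groups[key] = 1
            else:
                groups[merged] += 1
        majority = max(groups, key=lambda g: (groups[g], tuple(sorted(g))))
        for r in confident:
            if not (frozenset(r.neighbors) & majority):
                r.flagged = True
                r.note = "neighbour group conflicts with other genes"
    return results


def _nj_from_block(block, taxa, model) -> Tree:
    from phylotier.substmodels import p_distance

    n = len(taxa)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(block[i], block[j])
            if p is None:
                d = 5.0  # incomparable pair: pessimistic cap
            else:
                d = ml_pairwise_distance(block[i], block[j], model)
            vals[i, j] = vals[j, i] = d
    return neighbor_joining(DistanceMatrix(list(taxa), vals))


def estimate_unit_models(
    aln: PartitionedAlignment,
    gamma_shape: float = 0.5,
    max_pairs: int = 120,
) -> dict[str, SubstitutionModel]:
    """Per-partition HKY+Gamma models with relative rate multipliers.

    Kappa and base frequencies are moment/empirical estimates per unit; the
    per-unit rate multiplier is the unit's mean pairwise ML distance
    relative to the site-weighted mean over units, so that unlinked models
    can share one set of backbone branch lengths.
    """
    from dataclasses import replace as drep

    raw: dict[str, SubstitutionModel] = {}
    mean_dist: dict[str, float] = {}
    for part in aln.partitions:
        block = aln.block(part)
        model = estimate_hky_model(block, gamma_shape=gamma_shape)
        n = block.shape[0]
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        if len(pairs) > max_pairs:
            rng = np.random.default_rng(0)
            pairs = [pairs[i] for i in rng.choice(len(pairs), max_pairs, replace=False)]
        dists = []
        for i, j in pairs:
            from phylotier.substmodels import p_distance

            if p_distance(block[i], block[j]) is None:
                continue
            dists.append(min(ml_pairwise_distance(block[i], block[j], model), 10.0))
        raw[part.name] = model
        mean_dist[part.name] = float(np.mean(dists)) if dists else 1.0
    weights = {p.name: p.n_sites for p in aln.partitions}
    total_w = sum(weights.values())
    global_mean = sum(mean_dist[n] * w for n, w in weights.items()) / total_w
    out = {}
    for name, model in raw.items():
        scale = mean_dist[name] / global_mean if global_mean > 0 else 1.0
        out[name] = drep(model, rate_scale=float(np.clip(scale, 0.05, 50.0)))
    return out


# ---------------------------------------------------------------------------
# the two-tier driver
# ---------------------------------------------------------------------------

def run_two_tier(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    Every artifact (filtered alignment, QC and screen reports, jplace
    placements, tally tables, subset list, AU report, consensus tree, run
    log) is written under ``config.output_dir``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "phylotier_version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    rng = np.random.default_rng(config.seed)
    seeds = {
        name: int(rng.integers(2**31 - 1))
        for name in ("qc", "tier1", "tier2", "au")
    }
    log["derived_seeds"] = seeds

    def stage(name):
        log["stages"].append(name)

    try:
        stage("read")
        aln = read_alignment(config.alignment, partition_table=config.partition_table)
        backbone = Tree.from_newick(Path(config.backbone).read_text())
        query = config.query

        stage("clean")
        aln, clean_report = clean_alignment(aln)
        log["clean"] = {
            "removed_taxa": clean_report.removed_taxa,
            "removed_columns": clean_report.n_removed_columns,
        }
        write_alignment(aln, out / "cleaned_alignment.fasta", "fasta")

        stage("qc")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            qc = single_gene_qc(
                aln, query, B=config.qc_bootstrap, seed=seeds["qc"],
                min_sites=config.min_sites,
            )
        _write_qc(qc, out / "qc_report.tsv")
        log["qc_flags"] = sorted(r.gene for r in qc if r.flagged)

        stage("screen")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filtered, screen_report = screen_partitions(
                aln,
                plateau_threshold=config.plateau_threshold,
                slope_threshold=config.slope_threshold,
                outlier_k=config.outlier_k,
                min_sites=config.min_sites,
            )
        (out / "screen_report.tsv").write_text(screen_report.to_table())
        pair_dir = out / "saturation_pairs"
        pair_dir.mkdir(exist_ok=True)
        for unit in screen_report.retained_units + screen_report.excluded_units:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pr = saturation_pairs(aln, _unit_partition(aln, filtered, unit),
                                          min_sites=config.min_sites)
                (pair_dir / f"{unit}.tsv").write_text(pr.to_table())
            except (InsufficientDataError, KeyError):
                continue
        log["screen"] = {
            "retained": screen_report.retained_units,
            "excluded": screen_report.excluded_units,
            "taxon_marker_exclusions": [
                list(x) for x in screen_report.taxon_marker_exclusions
            ],
            "missing_fraction": round(missing_fraction(filtered), 4),
        }

        stage("models")
        models = estimate_unit_models(filtered)
        log["models"] = {
            n: {"kappa": round(m.kappa, 3), "rate_scale": round(m.rate_scale, 3)}
            for n, m in sorted(models.items())
        }

        work_backbone = backbone
        if config.optimize_backbone:
            stage("backbone-lengths")
            work_backbone, _ = optimize_branch_lengths(
                backbone, filtered, models, tol=1e-3
            )

        stage("tier1-placement")
        pm1 = PlacementModel(filtered, work_backbone, models, query,
                             rogues=config.rogues)
        res1 = pm1.fit(bootstrap=config.bootstrap, seed=seeds["tier1"], xatol=1e-5)
        (out / "tier1.jplace").write_text(res1.to_jplace())
        (out / "tier1_tally.tsv").write_text(res1.tally.to_table())

        stage("tier1-summaries")
        summaries = {}
        if config.focal_clade:
            summaries["plain_support"] = res1.effective_support(config.focal_clade)
            summaries["effective_support"] = res1.effective_support(
                config.focal_clade, rogues=config.rogues
            )
        subset = select_subset(
            work_backbone, res1.tally, filtered,
            region_threshold=config.region_threshold,
            outgroup_clades=config.outgroup_clades,
            k=config.k_outgroup,
        )
        summaries["region_threshold"] = config.region_threshold
        summaries["subset_size"] = len(subset)
        summaries["subset_region_support"] = region_support(res1.tally, subset)
        (out / "subset.txt").write_text("\n".join(subset) + "\n")
        log["tier1"] = {k: (round(v, 4) if isinstance(v, float) else v)
                        for k, v in summaries.items()}

        stage("tier2-placement")
        sub_backbone = restrict_to_taxa(work_backbone, subset)
        keep_rows = [t for t in filtered.taxa if t in set(subset) | {query}]
        sub_matrix = filtered.matrix[[filtered.taxa.index(t) for t in keep_rows]]
        sub_aln = PartitionedAlignment(keep_rows, sub_matrix, filtered.partitions)
        log["tier2_missing_fraction"] = round(missing_fraction(sub_aln), 4)
        pm2 = PlacementModel(sub_aln, sub_backbone, models, query)
        res2 = pm2.fit(bootstrap=config.bootstrap, seed=seeds["tier2"], xatol=1e-5)
        (out / "tier2.jplace").write_text(res2.to_jplace())
        (out / "tier2_tally.tsv").write_text(res2.tally.to_table())

        stage("hypothesis-trees")
        best2 = res2.point.best_tree()
        hyp_trees = [best2]
        hyp_ids = ["fitted"]
        pruned = prune_taxa(best2, [query])
        for name, clade in sorted(config.hypotheses.items()):
            clade_set = frozenset(clade) & frozenset(pruned.leaves)
            if not clade_set or clade_set == frozenset(pruned.leaves):
                raise PlacementError(
                    f"hypothesis {name!r} is degenerate on the tier-2 subset "
                    f"(covers none or all of its taxa)"
                )
            if not pruned.is_clade(clade_set):
                raise PlacementError(
                    f"hypothesis {name!r}: {sorted(clade_set)} is not a clade "
                    f"of the tier-2 tree"
                )
            tree_h = graft(pruned, clade_set, query, 0.5, res2.best_edge.pendant)
            hyp_trees.append(tree_h)
            hyp_ids.append(name)

        stage("au-test")
        if len(hyp_trees) >= 2:
            matrix = sitewise_matrix(hyp_trees, sub_aln, models, tree_ids=hyp_ids)
            au = au_test(matrix, B_per_scale=config.au_replicates, seed=seeds["au"])
            (out / "hypothesis_autest.tsv").write_text(au.summary())
            log["au"] = {
                tid: round(float(p), 4) for tid, p in zip(au.tree_ids, au.p_values)
            }

        stage("consensus")
        common = sorted(set(pruned.leaves) & set(work_backbone.leaves))
        cons = strict_consensus(
            [restrict_to_taxa(pruned, common), restrict_to_taxa(work_backbone, common)]
        )
        (out / "consensus.nwk").write_text(cons.to_newick() + "\n")
    except Exception as exc:
        failed_stage = log["stages"][-1] if log["stages"] else "init"
        log["error"] = {"stage": failed_stage, "message": str(exc)}
        (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {failed_stage!r}: {exc}") from exc

    log["thresholds"] = {
        "plateau": config.plateau_threshold,
        "slope": config.slope_threshold,
        "outlier_k": config.outlier_k,
        "min_sites": config.min_sites,
        "region": config.region_threshold,
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    return out


def _unit_partition(aln, filtered, unit_name):
    for p in filtered.partitions:
        if p.name == unit_name:
            return p
    # excluded units are absent from the filtered alignment; rebuild from the
    # cleaned alignment's codon split
    from phylotier.seqdata import split_codon_positions

    for p in aln.partitions:
        if p.name == unit_name:
            return p
        if p.coding:
            for sub in split_codon_positions(aln, p):
                if sub.name == unit_name:
                    return sub
    raise KeyError(unit_name)


def _write_qc(qc: list[GeneQC], path: Path) -> None:
    lines = ["gene\tn_taxa\tneighbors\tfrequency\tflagged\tnote"]
    for r in qc:
        lines.append(
            f"{r.gene}\t{r.n_taxa}\t{','.join(r.neighbors) or '-'}"
            f"\t{r.frequency:.1f}\t{int(r.flagged)}\t{r.note or '-'}"
        )
    path.write_text("\n".join(lines) + "\n")
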