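"""Substitution-saturation screening of supermatrix partitions.

For each gene x codon-position unit, tip-to-tip (patristic) distances are
compared between two distance trees built from the same data: one from
uncorrected p-distances and one from model-corrected (HKY85+Gamma)
maximum-likelihood distances.  Unsaturated data fall on a straight line;
saturation shows as a plateau — corrected distances keep growing while
observed distances stop.  The plateau is made operational as a two-piece
slope ratio: an ordinary least-squares slope on the pairs above the median
corrected distance divided by the slope on the pairs at or below it.
Units with a small ratio (or a globally flat regression) are excluded.

Outlier sequences — contaminants or non-homologs with extremely high
corrected distances to everything — are flagged per unit by a robust
median + k*MAD rule on each taxon's median tip-to-tip distance, and that
taxon's marker is masked rather than the whole unit dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from phylotier.seqdata import (
    Partition,
    PartitionedAlignment,
    split_codon_positions,
)
from phylotier.substmodels import (
    NUC,
    SubstitutionModel,
    empirical_frequencies,
    ml_pairwise_distance,
    p_distance,
)
from phylotier.trees import DistanceMatrix, neighbor_joining, patristic_distances

__all__ = [
    "InsufficientDataError",
    "SaturationPairs",
    "SaturationAssessment",
    "ScreenReport",
    "estimate_hky_model",
    "saturation_pairs",
    "assess_saturation",
    "detect_outliers",
    "screen_partitions",
]


class InsufficientDataError(ValueError):
    """Too few usable taxa/pairs for a saturation assessment."""


@dataclass
class SaturationPairs:
    """Paired patristic distances for one partition.

    ``x``: tip-to-tip distances on the NJ tree from model-corrected
    distances; ``y``: tip-to-tip distances on the NJ tree from p-distances.
    """

    partition: str
    taxa: list[str]
    pair_labels: list[tuple[str, str]]
    x: np.ndarray
    y: np.ndarray
    corrected: DistanceMatrix | None = None

    @property
    def n_pairs(self) -> int:
        return self.x.size

    def to_table(self) -> str:
        lines = ["taxon_i\ttaxon_j\tcorrected\tobserved"]
        for (a, b), xv, yv in zip(self.pair_labels, self.x, self.y):
            lines.append(f"{a}\t{b}\t{xv:.6f}\t{yv:.6f}")
        return "\n".join(lines) + "\n"


@dataclass
class SaturationAssessment:
    """Regression statistics and the include/exclude decision for one unit."""

    partition: str
    n_pairs: int
    slope: float
    intercept: float
    r_squared: float
    plateau_ratio: float
    decision: str  # 'include' | 'exclude'
    degenerate: bool = False
    outliers: dict[str, float] = field(default_factory=dict)
    plateau_threshold: float = 0.5
    slope_threshold: float = 0.3


@dataclass
class ScreenReport:
    """Outcome of screening every unit of a supermatrix."""

    assessments: list[SaturationAssessment]
    retained_units: list[str]
    excluded_units: list[str]
    taxon_marker_exclusions: list[tuple[str, str]]  # (taxon, unit)
    skipped_units: list[str] = field(default_factory=list)

    def to_table(self) -> str:
        lines = [
            "partition\tn_pairs\tslope\tr_squared\tplateau_ratio\tdecision\toutliers"
        ]
        for a in self.assessments:
            outl = ",".join(sorted(a.outliers)) or "-"
            lines.append(
                f"{a.partition}\t{a.n_pairs}\t{a.slope:.4f}\t{a.r_squared:.4f}"
                f"\t{a.plateau_ratio:.4f}\t{a.decision}\t{outl}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# per-partition model and distance machinery
# ---------------------------------------------------------------------------

def estimate_hky_model(
    block: np.ndarray,
    gamma_shape: float = 0.5,
    max_pairs: int = 200,
) -> SubstitutionModel:
    """Quick HKY85+Gamma model for distance work.

    Base frequencies are empirical; the transition/transversion ratio kappa
    comes from pooled transition/transversion proportions across sequence
    pairs (a moment estimate in the Kimura-formula family); the Gamma shape
    defaults to 0.5 rather than being optimized — distance-tree shapes are
    insensitive to it, and saturated data make a likelihood fit unstable.
    """
    freqs = empirical_frequencies(block)
    n = block.shape[0]
    ts = tv = comp = 0.0
    purines = {"A", "G"}
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) > max_pairs:
        pairs = pairs[:max_pairs]
    det = np.isin(block, list(NUC))
    for i, j in pairs:
        mask = det[i] & det[j]
        a, b = block[i, mask], block[j, mask]
        diff = a != b
        if not mask.any():
            continue
        comp += mask.sum()
        is_ts = diff & (
            (np.isin(a, list(purines)) & np.isin(b, list(purines)))
            | (~np.isin(a, list(purines)) & ~np.isin(b, list(purines)))
        )
        ts += is_ts.sum()
        tv += (diff & ~is_ts).sum()
    if comp == 0 or tv == 0:
        kappa = 4.0
    else:
        # transversions hit 8 of 12 off-diagonal channels; rescale to a rate ratio
        kappa = float(np.clip(2.0 * ts / tv, 0.5, 50.0))
    return SubstitutionModel.hky(kappa, tuple(freqs), gamma_shape)


def _usable_taxa(block: np.ndarray, taxa: Sequence[str], min_sites: int) -> list[int]:
    det = np.isin(block, list(NUC))
    return [i for i in range(len(taxa)) if det[i].sum() >= min_sites]


def _distance_matrices(
    block: np.ndarray, taxa: list[str], model: SubstitutionModel
) -> tuple[DistanceMatrix, DistanceMatrix]:
    n = len(taxa)
    P = np.zeros((n, n))
    X = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(block[i], block[j])
            if p is None:
                P[i, j] = P[j, i] = np.nan
                X[i, j] = X[j, i] = np.nan
                continue
            P[i, j] = P[j, i] = p
            X[i, j] = X[j, i] = ml_pairwise_distance(block[i], block[j], model)
    return DistanceMatrix(taxa, P), DistanceMatrix(taxa, X)


def _drop_nan_taxa(dp: DistanceMatrix, dx: DistanceMatrix):
    """Greedily drop the taxa with most non-comparable pairs until finite."""
    while True:
        bad_counts = (~np.isfinite(dp.values)).sum(axis=1)
        if bad_counts.sum() == 0:
            return dp, dx
        worst = dp.labels[int(bad_counts.argmax())]
        dp, dx = dp.drop([worst]), dx.drop([worst])


def saturation_pairs(
    aln: PartitionedAlignment,
    partition: Partition | str,
    min_sites: int = 50,
    model: SubstitutionModel | None = None,
) -> SaturationPairs:
    """Paired patristic distances (corrected vs observed) for one unit."""
    if isinstance(partition, str):
        partition = aln.partition(partition)
    block = aln.block(partition)
    usable = _usable_taxa(block, aln.taxa, min_sites)
    if len(usable) < 4:
        raise InsufficientDataError(
            f"partition {partition.name!r}: only {len(usable)} taxa with "
            f">= {min_sites} comparable sites"
        )
    taxa = [aln.taxa[i] for i in usable]
    sub = block[usable]
    if model is None:
        model = estimate_hky_model(sub)
    dp, dx = _distance_matrices(sub, taxa, model)
    dp, dx = _drop_nan_taxa(dp, dx)
    if len(dp.labels) < 4:
        raise InsufficientDataError(
            f"partition {partition.name!r}: fewer than 4 mutually comparable taxa"
        )
    tree_p = neighbor_joining(dp)
    tree_x = neighbor_joining(dx)
    pat_p = patristic_distances(tree_p)
    pat_x = patristic_distances(tree_x)
    labels = pat_x.labels
    pairs, xs, ys = [], [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairs.append((labels[i], labels[j]))
            xs.append(pat_x.values[i, j])
            ys.append(pat_p.get(labels[i], labels[j]))
    return SaturationPairs(
        partition.name, list(labels), pairs, np.array(xs), np.array(ys), pat_x
    )


def assess_saturation(
    pairs: SaturationPairs,
    plateau_threshold: float = 0.5,
    slope_threshold: float = 0.3,
) -> SaturationAssessment:
    """Two-piece slope-ratio plateau rule.

    Exclude iff the upper-half/lower-half OLS slope ratio falls below
    ``plateau_threshold`` or the global slope falls below
    ``slope_threshold``; perfectly linear data give ratio ~1 and are kept.
    """
    x, y = pairs.x, pairs.y
    if x.size < 6:
        raise InsufficientDataError(
            f"partition {pairs.partition!r}: need >= 6 pairs, got {x.size}"
        )
    if np.ptp(x) < 1e-12:
        return SaturationAssessment(
            pairs.partition, x.size, 0.0, float(np.mean(y)), 0.0, 1.0,
            "include", degenerate=True,
            plateau_threshold=plateau_threshold, slope_threshold=slope_threshold,
        )
    fit = stats.linregress(x, y)
    med = np.median(x)
    lo, hi = x <= med, x > med
    slope_lo = _ols_slope(x[lo], y[lo])
    slope_hi = _ols_slope(x[hi], y[hi])
    if slope_lo is None or slope_hi is None:
        ratio = 1.0
    elif slope_lo <= 1e-9:
        ratio = 1.0 if abs(slope_hi) <= 1e-9 else np.inf
    else:
        ratio = slope_hi / slope_lo
    decision = (
        "exclude"
        if (ratio < plateau_threshold or fit.slope < slope_threshold)
        else "include"
    )
    return SaturationAssessment(
        pairs.partition, x.size, float(fit.slope), float(fit.intercept),
        float(fit.rvalue**2), float(ratio), decision,
        plateau_threshold=plateau_threshold, slope_threshold=slope_threshold,
    )


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float | None:
    if x.size < 2 or np.ptp(x) < 1e-12:
        return None
    return float(stats.linregress(x, y).slope)


def detect_outliers(
    pairs_or_matrix: SaturationPairs | DistanceMatrix,
    k: float = 5.0,
    mad_floor: float = 0.25,
) -> dict[str, float]:
    """Flag taxa whose median corrected tip-to-tip distance exceeds the
    overall median by more than ``k`` median absolute deviations.

    The MAD is floored at ``mad_floor`` times the median score: in small,
    homogeneous taxon panels the raw MAD collapses toward zero and would
    turn ordinary among-lineage rate variation (scores within ~2x of the
    median) into spurious flags.  Genuine contaminants/non-homologs sit
    orders of magnitude above the median once model-corrected, so the
    floored rule stays sensitive to them.
    """
    if isinstance(pairs_or_matrix, SaturationPairs):
        dm = pairs_or_matrix.corrected
        if dm is None:
            raise ValueError("pairs carry no corrected distance matrix")
    else:
        dm = pairs_or_matrix
    n = len(dm.labels)
    if n < 5:
        raise InsufficientDataError("need >= 5 taxa for outlier detection")
    vals = dm.values + np.diag(np.full(n, np.nan))
    scores = np.nanmedian(vals, axis=1)
    med = np.median(scores)
    mad = max(np.median(np.abs(scores - med)), mad_floor * abs(med))
    cutoff = med + k * mad
    return {
        dm.labels[i]: float(scores[i]) for i in range(n) if scores[i] > cutoff
    }


def screen_partitions(
    aln: PartitionedAlignment,
    plateau_threshold: float = 0.5,
    slope_threshold: float = 0.3,
    outlier_k: float = 5.0,
    min_sites: int = 50,
) -> tuple[PartitionedAlignment, ScreenReport]:
    """Screen every gene x codon-position unit; return the filtered
    supermatrix (retained units as partitions, outlier cells masked) plus a
    full report.

    Coding partitions are split into codon positions first.  Within a unit,
    outlier taxa are removed before the plateau assessment so a single
    contaminant cannot sink an otherwise clean unit; their cells are
    replaced by ``'?'`` in the filtered matrix (exclusion is local — the
    taxon keeps its other markers).
    """
    units: list[Partition] = []
    for p in aln.partitions:
        if p.coding:
            units.extend(split_codon_positions(aln, p))
        else:
            units.append(p)
    assessments: list[SaturationAssessment] = []
    retained: list[Partition] = []
    excluded: list[str] = []
    skipped: list[str] = []
    exclusions: list[tuple[str, str]] = []
    filtered = aln.copy()
    def _unit_pairs(unit, exclude):
        kept = [t for t in aln.taxa if t not in exclude]
        rows = [aln.taxa.index(t) for t in kept]
        sub = PartitionedAlignment(
            kept,
            aln.matrix[np.ix_(rows, aln.sites_of(unit))],
            [replace(unit, sites=tuple(range(unit.n_sites)))],
        )
        return saturation_pairs(sub, unit.name, min_sites=min_sites)

    for unit in units:
        try:
            pairs = saturation_pairs(aln, unit, min_sites=min_sites)
            # iterative peeling: one extreme sequence can distort the whole
            # corrected-distance tree, so remove the worst, rebuild, re-test
            outliers: dict[str, float] = {}
            pairs_clean = pairs
            while True:
                try:
                    flags = detect_outliers(pairs_clean, k=outlier_k)
                except InsufficientDataError:
                    break
                if not flags:
                    break
                worst = max(flags, key=lambda t: flags[t])
                outliers[worst] = flags[worst]
                try:
                    pairs_clean = _unit_pairs(unit, set(outliers))
                except InsufficientDataError:
                    break
            assessment = assess_saturation(
                pairs_clean, plateau_threshold, slope_threshold
            )
            assessment.outliers = outliers
        except InsufficientDataError as exc:
            warnings.warn(str(exc), stacklevel=2)
            skipped.append(unit.name)
            continue
        assessments.append(assessment)
        if assessment.decision == "include":
            retained.append(unit)
            for taxon in assessment.outliers:
                exclusions.append((taxon, unit.name))
                filtered.matrix[
                    filtered.taxa.index(taxon), filtered.sites_of(unit)
                ] = "?"
        else:
            excluded.append(unit.name)
    out = PartitionedAlignment(filtered.taxa, filtered.matrix, retained or None)
    report = ScreenReport(
        assessments,
        [p.name for p in retained],
        excluded,
        exclusions,
        skipped,
    )
    return out, report
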