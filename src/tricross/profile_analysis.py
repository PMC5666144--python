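"""Expression and growth-profile comparisons between strain backgrounds.

The layer reproduces a classic microarray/phenotype-microarray workflow:
one-way ANOVA per row, linear fold-change filters at fixed thresholds
(2-fold and 5-fold at P < 0.01), agglomerative pattern clustering
(1 - Pearson distance, average linkage), relative-growth percentages
with standard deviations, and one-sided hypergeometric category
enrichment of gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .genome_io import GenomeIOError, ProfileMatrix

__all__ = [
    "AnovaResult",
    "DEResult",
    "DEFilterResult",
    "ClusterAssignment",
    "GrowthRatio",
    "one_way_anova",
    "de_filter",
    "hierarchical_cluster",
    "relative_growth",
    "enrich_categories",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False  # zero within-group variance with unequal means


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the sums-of-squares definitions.

    F = MS_between / MS_within on (k - 1, N - k) degrees of freedom;
    the p-value is the upper tail of the F distribution.  Groups with
    identical values throughout give F = 0, p = 1; zero within-group
    variance with unequal means reports p = 0 with a degeneracy flag.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise GenomeIOError("ANOVA needs at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise GenomeIOError("every group needs at least 2 values")
        if not np.isfinite(g).all():
            raise GenomeIOError("non-finite value in ANOVA input")
    k = len(arrays)
    N = sum(g.size for g in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b, df_w = k - 1, N - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, df_b, df_w)
        return AnovaResult(np.inf, 0.0, df_b, df_w, degenerate=True)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, df_b, df_w)


@dataclass(frozen=True)
class DEResult:
    """Per-row differential-regulation evidence between two groups."""

    row_id: str
    fold_change: float  # mean(group_a) / mean(group_b), linear scale
    p_value: float

    def passes(self, fc_threshold: float, p_threshold: float) -> bool:
        return (
            self.fold_change >= fc_threshold or self.fold_change <= 1.0 / fc_threshold
        ) and self.p_value < p_threshold


@dataclass
class DEFilterResult:
    up: set[str]  # FC >= threshold in group_a relative to group_b
    down: set[str]
    results: list[DEResult]
    n_excluded_zero_mean: int


def de_filter(
    matrix: ProfileMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
) -> DEFilterResult:
    """ANOVA + linear fold-change filter between two sample groups.

    Fold change is the ratio of linear-scale group means (group_a over
    group_b).  ``up`` collects rows with FC >= ``fc_threshold`` and
    p < ``p_threshold``; ``down`` the mirror set with FC <= 1/threshold.
    Rows whose group_b mean is zero cannot form a ratio and are excluded
    with a tally.  The up/down sets are disjoint by construction.
    """
    for label in (group_a, group_b):
        if label in matrix.small_groups:
            raise GenomeIOError(f"group {label!r} has < 2 samples; cannot test")
    va = matrix.group_values(group_a)
    vb = matrix.group_values(group_b)
    up: set[str] = set()
    down: set[str] = set()
    results: list[DEResult] = []
    n_excluded = 0
    for i, row_id in enumerate(matrix.values.index):
        mb = vb[i].mean()
        if mb == 0.0:
            n_excluded += 1
            continue
        fc = va[i].mean() / mb
        anova = one_way_anova([va[i], vb[i]])
        res = DEResult(str(row_id), float(fc), anova.p_value)
        results.append(res)
        if res.p_value < p_threshold:
            if fc >= fc_threshold:
                up.add(res.row_id)
            elif fc <= 1.0 / fc_threshold:
                down.add(res.row_id)
    return DEFilterResult(up, down, results, n_excluded)


@dataclass
class ClusterAssignment:
    """Flat cluster labels (1..k) plus the agglomeration tree."""

    labels: dict[str, int]
    linkage_matrix: np.ndarray | None
    k: int

    def members(self, label: int) -> set[str]:
        return {r for r, l in self.labels.items() if l == label}


def hierarchical_cluster(
    matrix: ProfileMatrix,
    k: int,
    distance: str = "one_minus_pearson",
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering of row patterns, cut to exactly k clusters.

    Default distance is 1 - Pearson correlation between rows — pattern
    shape, not magnitude — with average linkage, the configuration of
    classic expression-pattern tools.  Constant (zero-variance) rows
    have no defined correlation; they are held out and assigned to the
    nearest cluster centroid (Euclidean) afterwards, so filtered
    matrices with flat rows cluster without error.  Deterministic for a
    given input: ties follow scipy's stable agglomeration order.
    """
    X = matrix.values.to_numpy(dtype=float)
    ids = [str(r) for r in matrix.values.index]
    if k < 1 or k > len(ids):
        raise GenomeIOError(f"k={k} invalid for {len(ids)} rows")
    metric = {"one_minus_pearson": "correlation", "euclidean": "euclidean"}.get(distance)
    if metric is None:
        raise GenomeIOError(f"unknown distance {distance!r}")
    variable = np.std(X, axis=1) > 0 if metric == "correlation" else np.ones(len(ids), bool)
    labels: dict[str, int] = {}
    Z = None
    idx_var = np.flatnonzero(variable)
    if idx_var.size == 0:
        # all rows constant: a single flat cluster (k must be 1 to be exact)
        for r in ids:
            labels[r] = 1
        return ClusterAssignment(labels, None, 1)
    k_eff = min(k, idx_var.size)
    if idx_var.size == 1:
        flat = np.array([1])
    else:
        Z = linkage(X[idx_var], method=linkage_method, metric=metric)
        flat = fcluster(Z, t=k_eff, criterion="maxclust")
    for i, row in enumerate(idx_var):
        labels[ids[row]] = int(flat[i])
    # constant rows -> nearest centroid
    centroids = {
        lab: X[idx_var][flat == lab].mean(axis=0) for lab in np.unique(flat)
    }
    for row in np.flatnonzero(~variable):
        dists = {lab: np.linalg.norm(X[row] - c) for lab, c in centroids.items()}
        labels[ids[row]] = min(sorted(dists), key=dists.get)
    # relabel contiguously 1..k in order of first appearance
    remap: dict[int, int] = {}
    for r in ids:
        lab = labels[r]
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = {r: remap[labels[r]] for r in ids}
    return ClusterAssignment(labels, Z, len(remap))


@dataclass(frozen=True)
class GrowthRatio:
    """Relative growth of strain a vs strain b as a percentage with SD."""

    percent: float
    sd: float
    n_pairs: int
    n_excluded_nonpositive: int
    method: str  # paired | bootstrap


def relative_growth(
    a: Sequence[float],
    b: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> GrowthRatio:
    """Mean +/- SD of the growth ratio a/b, in percent.

    With equal replicate counts, replicate i of a is paired with
    replicate i of b and the ratio distribution is the per-pair ratios
    (SD with ddof=1).  With unequal counts, the ratio of means is
    reported with the SD of a seeded ``n_boot``-resample bootstrap.
    Non-positive readings are excluded and tallied.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    n_excl = int((a_arr <= 0).sum() + (b_arr <= 0).sum())
    a_arr = a_arr[a_arr > 0]
    b_arr = b_arr[b_arr > 0]
    if a_arr.size < 2 or b_arr.size < 2:
        raise GenomeIOError("need at least 2 positive replicates per strain")
    if a_arr.size == b_arr.size:
        ratios = a_arr / b_arr * 100.0
        sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
        return GrowthRatio(float(ratios.mean()), sd, int(ratios.size), n_excl, "paired")
    rng = np.random.default_rng(seed)
    point = a_arr.mean() / b_arr.mean() * 100.0
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = rng.choice(a_arr, size=a_arr.size, replace=True)
        rb = rng.choice(b_arr, size=b_arr.size, replace=True)
        boots[i] = ra.mean() / rb.mean() * 100.0
    return GrowthRatio(float(point), float(boots.std(ddof=1)),
                       int(min(a_arr.size, b_arr.size)), n_excl, "bootstrap")


def enrich_categories(
    gene_set: Iterable[str],
    universe: Iterable[str],
    category_map: Mapping[str, Iterable[str]],
    correction: str = "none",
) -> dict[str, float]:
    """One-sided hypergeometric enrichment p-value per functional category.

    For a category of size K in a universe of size M and a gene set of
    size n with k overlapping members, p = P(overlap >= k) under random
    draws without replacement.  Raw p-values by default (matching how
    functional-category enrichments are classically reported); set
    ``correction='bonferroni'`` to multiply by the category count.
    """
    uni = set(universe)
    gset = set(gene_set)
    if not gset <= uni:
        raise GenomeIOError("gene_set must be a subset of the universe")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    M, n = len(uni), len(gset)
    out: dict[str, float] = {}
    for cat, members in category_map.items():
        cat_set = set(members) & uni
        K = len(cat_set)
        k = len(cat_set & gset)
        if n == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, M, K, n))
        if correction == "bonferroni":
            p = min(1.0, p * len(category_map))
        out[cat] = p
    return out
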