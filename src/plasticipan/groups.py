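"""Genomogroup delineation and differential gene-content statistics.

Genomes are ordinated by PCA on their orthogroup copy counts (for
column-centred data with Euclidean distances this coincides with PCoA),
the number of gene-content clusters is chosen with the gap statistic
(uniform reference sampled in the principal-axis-aligned bounding box),
groups are cut from a Ward.D2/Euclidean dendrogram, and per-orthogroup
differences between the two groups are tested with a two-sided Wilcoxon
rank-sum (exact, tie-aware, for small samples) under Benjamini-Hochberg
FDR control.  COG-category enrichment compares each genome's core versus
accessory functional profile with a paired signed-rank test under
Bonferroni correction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from statsmodels.stats.multitest import multipletests

from plasticipan.ani import cluster_ward

log = logging.getLogger(__name__)


@dataclass
class Ordination:
    genome_ids: list[str]
    coordinates: np.ndarray  # genomes x axes
    variance_explained: np.ndarray  # fraction per axis, non-increasing


@dataclass
class GroupAssignment:
    labels: dict[str, str]
    k: int
    method: str = "ward.D2/euclidean"


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # group_id, mean_I, mean_II, W, p, q, direction
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["q"] < self.alpha]


@dataclass
class GapResult:
    optimal_k: int
    k: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    log_w: np.ndarray


def ordinate(matrix: pd.DataFrame, n_axes: int | None = None) -> Ordination:
    """PCA of genomes by orthogroup copy counts (column-centred, unscaled)."""
    if matrix.shape[1] < 3:
        raise ValueError("need at least three genomes to ordinate")
    X = matrix.values.T.astype(float)  # genomes x orthogroups
    X = X - X.mean(axis=0, keepdims=True)
    n = X.shape[0]
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    coords = u * s
    if n_axes is None:
        n_axes = min(n - 1, coords.shape[1])
    return Ordination(
        genome_ids=list(matrix.columns),
        coordinates=coords[:, :n_axes],
        variance_explained=frac[:n_axes],
    )


def _ward_labels(X: np.ndarray, k: int) -> np.ndarray:
    if k == 1:
        return np.ones(X.shape[0], dtype=int)
    Z = cluster_ward(X)
    return sch.fcluster(Z, t=k, criterion="maxclust")


def _pooled_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared distances to centroids."""
    w = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def gap_statistic(matrix: pd.DataFrame, k_max: int = 6, B: int = 50,
                  seed: int = 0) -> GapResult:
    """Tibshirani gap statistic with Ward.D2 clustering.

    Reference sets are sampled uniformly in the bounding box of the data
    after rotation to its principal axes.  The optimal k is the smallest k
    with gap(k) >= gap(k+1) - se(k+1); degenerate data (zero dispersion)
    gives k = 1.
    """
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    if B < 10:
        raise ValueError("need at least 10 reference sets")
    X = matrix.values.T.astype(float)
    n = X.shape[0]
    k_max = min(k_max, n - 1)
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        return GapResult(optimal_k=1, k=np.arange(1, k_max + 1),
                         gap=np.zeros(k_max), se=np.zeros(k_max), log_w=np.zeros(k_max))
    # rotate to principal axes; Euclidean geometry is preserved
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)

    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)
    log_w = np.array([math.log(max(_pooled_dispersion(Xp, _ward_labels(Xp, k)), 1e-300))
                      for k in ks])
    ref_log_w = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=Xp.shape)
        for ki, k in enumerate(ks):
            ref_log_w[b, ki] = math.log(max(_pooled_dispersion(ref, _ward_labels(ref, k)), 1e-300))
    gap = ref_log_w.mean(axis=0) - log_w
    se = ref_log_w.std(axis=0, ddof=0) * math.sqrt(1.0 + 1.0 / B)

    optimal = int(ks[-1])
    for ki in range(k_max - 1):
        if gap[ki] >= gap[ki + 1] - se[ki + 1]:
            optimal = int(ks[ki])
            break
    return GapResult(optimal_k=optimal, k=ks, gap=gap, se=se, log_w=log_w)


def assign_groups(matrix: pd.DataFrame, k: int) -> GroupAssignment:
    """Cut the Ward.D2 dendrogram at k groups; labels by size (I = largest).

    Roman-numeral labels are assigned in order of decreasing group size,
    ties broken by first genome in column order, so the assignment is
    invariant to genome input order.
    """
    genomes = list(matrix.columns)
    n = len(genomes)
    if k > n:
        raise ValueError(f"cannot form {k} groups from {n} genomes")
    if k < 1:
        raise ValueError("k must be at least 1")
    order = np.argsort(genomes)  # canonical row order: input-order invariant
    X = matrix.values.T.astype(float)[order]
    raw = _ward_labels(X, k)
    sorted_genomes = [genomes[i] for i in order]
    sizes = {lab: int((raw == lab).sum()) for lab in np.unique(raw)}
    first = {lab: min(i for i in range(n) if raw[i] == lab) for lab in sizes}
    ranked = sorted(sizes, key=lambda lab: (-sizes[lab], first[lab]))
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    name = {lab: (roman[i] if i < len(roman) else f"G{i + 1}") for i, lab in enumerate(ranked)}
    labels = {g: name[lab] for g, lab in zip(sorted_genomes, raw)}
    return GroupAssignment(labels=labels, k=k)


def _exact_ranksum_p(values: np.ndarray, group1_idx: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all group-1 labelings.

    Tie-aware: mid-ranks are used, and the null distribution is the rank
    sum over every size-preserving relabelling.  Two-sided p is the
    probability of a rank sum at least as far from its mean as observed.
    """
    n = values.size
    n1 = group1_idx.size
    ranks = stats.rankdata(values)
    w_obs = float(ranks[group1_idx].sum())
    mu = n1 * (n + 1) / 2.0
    combs = np.fromiter(
        (i for c in combinations(range(n), n1) for i in c), dtype=np.intp
    ).reshape(-1, n1)
    w_null = ranks[combs].sum(axis=1)
    p = float(np.mean(np.abs(w_null - mu) >= abs(w_obs - mu) - 1e-9))
    return w_obs, p


def ranksum_test(x: np.ndarray, y: np.ndarray, exact_limit: int = 20) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum with ties.

    Exact enumeration when the combined sample size is at most
    ``exact_limit``; tie- and continuity-corrected normal approximation
    otherwise.  Returns (rank-sum statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size + y.size
    values = np.concatenate([x, y])
    if np.all(values == values[0]):
        return float(stats.rankdata(values)[: x.size].sum()), 1.0
    if n <= exact_limit:
        return _exact_ranksum_p(values, np.arange(x.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    w = float(stats.rankdata(values)[: x.size].sum())
    return w, float(res.pvalue)


def differential(matrix: pd.DataFrame, labels: Mapping[str, str],
                 alpha: float = 0.05, binarize: bool = False) -> DifferentialResult:
    """Per-orthogroup two-group Wilcoxon rank-sum with BH correction.

    Copy counts are compared by default (a presence/absence mode is
    available via ``binarize``); the enriched-in direction is the group
    with the larger mean count.
    """
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    gA, gB = groups
    a_cols = [g for g in matrix.columns if labels[g] == gA]
    b_cols = [g for g in matrix.columns if labels[g] == gB]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least two genomes")
    data = (matrix >= 1).astype(int) if binarize else matrix

    rows = []
    for gid in data.index:
        x = data.loc[gid, a_cols].to_numpy(dtype=float)
        y = data.loc[gid, b_cols].to_numpy(dtype=float)
        w, p = ranksum_test(x, y)
        mean_a, mean_b = float(x.mean()), float(y.mean())
        rows.append((gid, mean_a, mean_b, w, p,
                     gA if mean_a > mean_b else (gB if mean_b > mean_a else "none")))
    table = pd.DataFrame(rows, columns=["group_id", f"mean_{gA}", f"mean_{gB}",
                                        "W", "p", "direction"])
    table["q"] = multipletests(table["p"].values, method="fdr_bh")[1]
    table = table[["group_id", f"mean_{gA}", f"mean_{gB}", "W", "p", "q", "direction"]]
    return DifferentialResult(table=table, alpha=alpha)


@dataclass
class CogEnrichment:
    table: pd.DataFrame  # category, core_frac_mean, accessory_frac_mean, p, p_bonferroni, enriched_in


def _category_fractions(matrix: pd.DataFrame, group_ids: Sequence[str],
                        annotations: Mapping[str, str], categories: Sequence[str]) -> pd.DataFrame:
    """Per genome, the fraction of annotated gene copies in each category."""
    annotated = [g for g in group_ids if annotations.get(g)]
    out = pd.DataFrame(0.0, index=list(matrix.columns), columns=list(categories))
    if not annotated:
        return out
    sub = matrix.loc[annotated]
    totals = sub.sum(axis=0).astype(float)
    for cat in categories:
        members = [g for g in annotated if cat in annotations[g]]
        if members:
            out[cat] = (sub.loc[members].sum(axis=0) / totals.replace(0, np.nan)).fillna(0.0)
    return out


def cog_enrichment(matrix: pd.DataFrame, annotations: Mapping[str, str],
                   core: Sequence[str], accessory: Sequence[str],
                   alpha: float = 0.05, paired: bool = True) -> CogEnrichment:
    """Core- vs accessory-genome COG category comparison.

    For every genome the fraction of its (COG-annotated) core gene copies
    in each category is compared with the accessory fraction; per category
    a two-sided Wilcoxon signed-rank across genomes (paired by genome;
    ``paired=False`` pools the two compartments with a rank-sum instead),
    Bonferroni-adjusted over the categories tested.  Orthogroups mapping
    to several category letters count once per letter.
    """
    categories = sorted({c for letters in annotations.values() for c in letters})
    if not categories:
        raise ValueError("no COG categories in the annotation table")
    core_frac = _category_fractions(matrix, core, annotations, categories)
    acc_frac = _category_fractions(matrix, accessory, annotations, categories)

    rows = []
    tested = []
    for cat in categories:
        cf, af = core_frac[cat].values, acc_frac[cat].values
        if not (np.any(cf) or np.any(af)):
            log.warning("COG category %s has no annotated groups; skipped", cat)
            continue
        if paired:
            diff = af - cf
            if np.all(diff == 0):
                p = 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    method = "exact" if len(diff) <= 25 else "approx"
                    p = float(stats.wilcoxon(af, cf, zero_method="wilcox",
                                             alternative="two-sided", method=method).pvalue)
        else:
            _, p = ranksum_test(af, cf)
        rows.append((cat, float(cf.mean()), float(af.mean()), p,
                     "accessory" if af.mean() > cf.mean() else
                     ("core" if cf.mean() > af.mean() else "none")))
        tested.append(cat)
    n_tested = len(tested)
    table = pd.DataFrame(rows, columns=["category", "core_frac_mean",
                                        "accessory_frac_mean", "p", "enriched_in"])
    table["p_bonferroni"] = np.minimum(1.0, table["p"] * n_tested)
    table = table[["category", "core_frac_mean", "accessory_frac_mean",
                   "p", "p_bonferroni", "enriched_in"]]
    return CogEnrichment(table=table)
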