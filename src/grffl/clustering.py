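"""Expression clustering: Z-scores, ANOVA filter, k-means, condition tests.

The clustering substrate is the per-gene Z-score of log2 expression across
conditions, z = (log2 x - mean)/sd, which removes magnitude so clusters are
shaped by response pattern rather than absolute expression. Differential
genes are pre-selected by a one-way ANOVA across condition groups, the
number of clusters is chosen by the elbow of the within-cluster
sum-of-squares curve, and condition contrasts within clusters are tested
with the Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from grffl.datatypes import ExpressionMatrix, TestResult, ValidationError

__all__ = [
    "ZScoreMatrix",
    "ClusteringResult",
    "zscore_rows",
    "anova_filter",
    "kmeans_cluster",
    "elbow_select_k",
    "mann_whitney_u",
    "cluster_condition_report",
    "average_replicates",
]


@dataclass
class ZScoreMatrix:
    """Row-standardized log2 expression; constant rows are flagged, not scored."""

    gene_ids: list[str]
    condition_ids: list[str]
    z: np.ndarray
    constant_genes: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ClusteringResult:
    k: int
    labels: dict[str, int]
    centroids: np.ndarray
    wss: float
    wss_by_k: dict[int, float] = field(default_factory=dict)


def zscore_rows(m: ExpressionMatrix, pseudocount: float = 0.0) -> ZScoreMatrix:
    """Standardize each gene's log2 expression across conditions.

    Uses the sample (n-1) standard deviation. Rows that are constant after
    the log transform carry no pattern information and are flagged and
    excluded. Zero values require a positive ``pseudocount``.
    """
    if m.n_conditions < 2:
        raise ValidationError("need >= 2 conditions to standardize")
    x = m.values + pseudocount
    if np.any(x <= 0):
        raise ValidationError(
            "non-positive values cannot be log2-transformed; set a pseudocount"
        )
    logx = np.log2(x)
    sd = logx.std(axis=1, ddof=1)
    constant = sd == 0.0
    mean = logx.mean(axis=1)
    gene_ids = [g for g, c in zip(m.gene_ids, constant) if not c]
    z = (logx[~constant] - mean[~constant, None]) / sd[~constant, None]
    return ZScoreMatrix(
        gene_ids=gene_ids,
        condition_ids=list(m.condition_ids),
        z=z,
        constant_genes=[g for g, c in zip(m.gene_ids, constant) if c],
    )


def average_replicates(m: ExpressionMatrix,
                       groups: Mapping[str, str]) -> ExpressionMatrix:
    """Average replicate columns on the log2 scale into one column per group.

    ``groups`` maps each condition column to its group label (e.g.
    ``{"U_1": "U", "U_2": "U", ...}``). The geometric mean on the linear
    scale corresponds to the arithmetic mean of log2 values.
    """
    missing = set(m.condition_ids) - set(groups)
    if missing:
        raise ValidationError(f"columns without a group: {sorted(missing)}")
    order = list(dict.fromkeys(groups[c] for c in m.condition_ids))
    cols = []
    for g in order:
        idx = [j for j, c in enumerate(m.condition_ids) if groups[c] == g]
        sub = m.values[:, idx]
        if np.any(sub <= 0):
            raise ValidationError("non-positive values; cannot log-average")
        cols.append(np.exp2(np.log2(sub).mean(axis=1)))
    return ExpressionMatrix(list(m.gene_ids), order, np.column_stack(cols))


def anova_filter(m: ExpressionMatrix, groups: Mapping[str, Sequence[str]],
                 alpha: float, pseudocount: float = 0.0) -> list[str]:
    """Retain genes differential across condition groups by one-way ANOVA.

    ``groups`` maps group label -> replicate column ids (each group needs
    >= 2 replicates). The F test runs on log2 values; genes with p <= alpha
    are returned in input order.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    col_idx: dict[str, list[int]] = {}
    for g, cols in groups.items():
        if len(cols) < 2:
            raise ValidationError(f"group {g!r} has < 2 replicate columns")
        try:
            col_idx[g] = [m.condition_ids.index(c) for c in cols]
        except ValueError as exc:
            raise ValidationError(f"group {g!r}: unknown column ({exc})") from None
    x = m.values + pseudocount
    if np.any(x <= 0):
        raise ValidationError("non-positive values; set a pseudocount")
    logx = np.log2(x)
    samples = [logx[:, idx] for idx in col_idx.values()]
    f_stat, p = stats.f_oneway(*samples, axis=1)
    keep = p <= alpha
    return [g for g, k in zip(m.gene_ids, keep) if k]


def kmeans_cluster(z: ZScoreMatrix, k: int, n_init: int = 10,
                   seed: int = 0,
                   init_centroids: np.ndarray | None = None) -> ClusteringResult:
    """Lloyd k-means with Euclidean distance, best of ``n_init`` random starts.

    Deterministic under ``seed``. ``init_centroids`` adds one extra
    deterministic initialization (used by the elbow scan to warm-start k
    from the k-1 solution, which guarantees a non-increasing wss curve).
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > z.n_genes:
        raise ValidationError(f"k = {k} exceeds {z.n_genes} genes")
    km = KMeans(n_clusters=k, init="random", n_init=n_init,
                random_state=seed & 0x7FFFFFFF).fit(z.z)
    best_wss, best_labels, best_centers = km.inertia_, km.labels_, km.cluster_centers_
    if init_centroids is not None:
        km2 = KMeans(n_clusters=k, init=np.asarray(init_centroids), n_init=1).fit(z.z)
        if km2.inertia_ < best_wss:
            best_wss, best_labels, best_centers = (
                km2.inertia_, km2.labels_, km2.cluster_centers_)
    return ClusteringResult(
        k=k,
        labels={g: int(l) for g, l in zip(z.gene_ids, best_labels)},
        centroids=best_centers,
        wss=float(best_wss),
    )


@dataclass
class ElbowResult:
    k: int
    wss_by_k: dict[int, float]
    distinct: bool  # False when the curve is flat ("no distinct elbow")
    results: dict[int, ClusteringResult] = field(default_factory=dict)


def elbow_select_k(z: ZScoreMatrix, k_range: tuple[int, int], seed: int = 0,
                   n_init: int = 10, flat_fraction: float = 0.05) -> ElbowResult:
    """Scan k over ``k_range`` and pick the elbow of the wss curve.

    The elbow k* maximizes the discrete second difference
    wss(k-1) - 2 wss(k) + wss(k+1) over interior k. Each k is warm-started
    from the previous solution's centroids plus the farthest point, so the
    returned curve is non-increasing. When the largest second difference is
    below ``flat_fraction`` of wss at the smallest k the curve is flagged as
    having no distinct elbow.
    """
    k_min, k_max = k_range
    if k_min < 2 or k_max > z.n_genes:
        raise ValidationError("k_range must lie within [2, n_genes]")
    ks = list(range(k_min, k_max + 1))
    if len(ks) < 3:
        raise ValidationError("k_range must span >= 3 values (no interior point)")
    wss_by_k: dict[int, float] = {}
    results: dict[int, ClusteringResult] = {}
    prev: ClusteringResult | None = None
    for k in ks:
        warm = None
        if prev is not None:
            # add the point farthest from its assigned centroid as a new seed
            assign = np.array([prev.labels[g] for g in z.gene_ids])
            dists = np.linalg.norm(z.z - prev.centroids[assign], axis=1)
            far = z.z[int(np.argmax(dists))]
            warm = np.vstack([prev.centroids, far])
        res = kmeans_cluster(z, k, n_init=n_init, seed=seed + k, init_centroids=warm)
        if prev is not None and res.wss > prev.wss:
            res.wss = prev.wss  # warm start guarantees this never triggers
        wss_by_k[k] = res.wss
        results[k] = res
        prev = res
    second_diff = {
        k: wss_by_k[k - 1] - 2.0 * wss_by_k[k] + wss_by_k[k + 1]
        for k in ks[1:-1]
    }
    k_star = max(second_diff, key=lambda k: (second_diff[k], -k))
    distinct = second_diff[k_star] >= flat_fraction * wss_by_k[ks[0]]
    for res in results.values():
        res.wss_by_k = wss_by_k
    return ElbowResult(k=k_star, wss_by_k=wss_by_k, distinct=distinct,
                       results=results)


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   groups: tuple[str, str] = ("x", "y")) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact p by enumeration when n + m <= 20 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)),
                      method=f"mann-whitney-{method}", groups=groups)


def cluster_condition_report(m: ExpressionMatrix, labels: Mapping[str, int],
                             contrasts: Sequence[tuple[str, str]],
                             min_cluster_size: int = 3) -> pd.DataFrame:
    """Mann-Whitney condition contrasts within each cluster.

    For every cluster and every (condition A, condition B) contrast, tests
    the per-gene expression values of A against B across the cluster's
    genes. Clusters smaller than ``min_cluster_size`` are reported but
    flagged underpowered. Stars follow the 0.05/0.01/0.001 convention.
    """
    missing = set(m.gene_ids) - set(labels)
    if missing:
        raise ValidationError(f"labels missing for genes: {sorted(missing)[:5]}...")
    for a, b in contrasts:
        for c in (a, b):
            if c not in m.condition_ids:
                raise ValidationError(f"unknown condition {c!r}")
    rows = []
    clusters = sorted(set(labels[g] for g in m.gene_ids))
    for cl in clusters:
        genes = [g for g in m.gene_ids if labels[g] == cl]
        idx = [m.gene_ids.index(g) for g in genes]
        for a, b in contrasts:
            xa = m.values[idx, m.condition_ids.index(a)]
            xb = m.values[idx, m.condition_ids.index(b)]
            if a == b or (np.array_equal(xa, xb)):
                tr = TestResult(statistic=float(len(xa) ** 2 / 2.0), p_value=1.0,
                                method="mann-whitney-degenerate", groups=(a, b))
            else:
                tr = mann_whitney_u(xa, xb, groups=(a, b))
            rows.append({
                "cluster": cl, "n_genes": len(genes),
                "condition_a": a, "condition_b": b,
                "U": tr.statistic, "p_value": tr.p_value,
                "stars": tr.stars, "method": tr.method,
                "underpowered": len(genes) < min_cluster_size,
            })
    return pd.DataFrame(rows)
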