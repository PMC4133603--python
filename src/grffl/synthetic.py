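"""Synthetic inputs with the statistical structure the pipeline assumes.

Each generator emulates one class of study input so every downstream stage
can be exercised and benchmarked without external data:

- expression matrices with planted co-regulation clusters (Normal noise on
  the log2 scale, i.e. multiplicative on the linear scale);
- fold-change time courses from the I1-FFL model with lognormal
  fixed-CV replicate noise (RT-qPCR-style multiplicative error);
- planted-partition random graphs (within-community edge probability p_in,
  between-community p_out);
- genomic interval sets with background intervals uniform on a small
  synthetic genome plus intervals planted near target genes;
- random gene-category annotation tables with optional planted
  overrepresented categories.

All generators are fully deterministic under their seed and also return the
ground truth needed for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from grffl.datatypes import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    ValidationError,
)
from grffl.ffl import FFLParameters, TimeCourse, simulate_i1ffl

__all__ = [
    "ClusterTemplate",
    "PlantedGraphSpec",
    "IntervalPlantSpec",
    "gen_expression",
    "gen_ffl_timecourse",
    "gen_planted_network",
    "gen_interval_plant",
    "gen_annotations",
    "default_genome",
    "gen_gene_models",
]

#: Default synthetic genome: 2 chromosomes x 10 Mb — small enough for
#: exhaustive overlap oracles.
DEFAULT_GENOME: list[tuple[str, int]] = [("chr1", 10_000_000), ("chr2", 10_000_000)]


@dataclass
class ClusterTemplate:
    """One planted co-regulation cluster.

    condition_means are log2-scale offsets (one per condition); each gene
    gets a Normal(0, gene_sd) baseline shift and Normal(0, noise_sd)
    residuals, all on the log2 scale.
    """

    template_id: str
    condition_means: Sequence[float]
    n_genes: int
    gene_sd: float = 0.5
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.gene_sd < 0 or self.noise_sd < 0:
            raise ValidationError("standard deviations must be >= 0")


@dataclass
class PlantedGraphSpec:
    """Planted-partition graph: communities of given sizes, Bernoulli edges."""

    sizes: Sequence[int]
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValidationError("require 0 <= p_out <= p_in <= 1")
        if any(s < 1 for s in self.sizes):
            raise ValidationError("community sizes must be >= 1")


@dataclass
class IntervalPlantSpec:
    """Interval set with planted proximity enrichment near target genes."""

    target_genes: set[str]
    n_background: int
    n_planted: int
    window_bp: int = 15000
    genome: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_GENOME))
    interval_length: int = 200

    def __post_init__(self) -> None:
        if self.n_background < 0 or self.n_planted < 0:
            raise ValidationError("counts must be >= 0")
        if self.window_bp < 0:
            raise ValidationError("window_bp must be >= 0")


def gen_expression(templates: Sequence[ClusterTemplate], seed: int = 0
                   ) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Planted-cluster expression matrix plus true gene -> template labels.

    For gene g of template T at condition c:
    log2 x = baseline + T.mean_c + b_g + eps with b_g ~ N(0, gene_sd) and
    eps ~ N(0, noise_sd); the matrix is returned on the linear scale (2^x).
    """
    if not templates:
        raise ValidationError("empty template list")
    n_cond = len(templates[0].condition_means)
    if any(len(t.condition_means) != n_cond for t in templates):
        raise ValidationError("templates must share one condition set")
    rng = np.random.default_rng(seed)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth: dict[str, str] = {}
    for t in templates:
        means = np.asarray(t.condition_means, dtype=float)
        for i in range(t.n_genes):
            gid = f"{t.template_id}_g{i:04d}"
            b = rng.normal(0.0, t.gene_sd)
            eps = rng.normal(0.0, t.noise_sd, size=n_cond)
            rows.append(np.exp2(means + b + eps))
            gene_ids.append(gid)
            truth[gid] = t.template_id
    conditions = [f"c{j}" for j in range(n_cond)]
    return ExpressionMatrix(gene_ids, conditions, np.vstack(rows)), truth


def gen_ffl_timecourse(params: FFLParameters, times: Sequence[float],
                       noise_cv: float = 0.05, n_rep: int = 3, seed: int = 0,
                       gene_id: str = "synthetic") -> tuple[TimeCourse, np.ndarray]:
    """Noisy replicate fold-change time course from the I1-FFL model.

    Each replicate is the model target z(t) multiplied by lognormal noise
    with coefficient of variation ``noise_cv``. Returns the per-timepoint
    mean (with SEM) as a TimeCourse plus the full replicate matrix.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    if n_rep < 1:
        raise ValidationError("n_rep must be >= 1")
    z = simulate_i1ffl(params, t).z
    if noise_cv == 0.0:
        reps = np.tile(z, (n_rep, 1))
    else:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))  # lognormal with unit mean, CV=noise_cv
        mu = -0.5 * sigma**2
        reps = z[None, :] * rng.lognormal(mu, sigma, size=(n_rep, t.size))
    mean = reps.mean(axis=0)
    sem = reps.std(axis=0, ddof=1) / np.sqrt(n_rep) if n_rep > 1 else np.zeros_like(mean)
    return TimeCourse(gene_id, t, mean, sem), reps


def gen_planted_network(spec: PlantedGraphSpec) -> tuple[nx.Graph, dict[str, int]]:
    """Planted-partition random graph plus true community membership."""
    rng = np.random.default_rng(spec.seed)
    nodes: list[str] = []
    truth: dict[str, int] = {}
    for ci, size in enumerate(spec.sizes):
        for i in range(size):
            node = f"m{ci}_n{i:03d}"
            nodes.append(node)
            truth[node] = ci
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            p = spec.p_in if truth[u] == truth[v] else spec.p_out
            if p > 0 and rng.random() < p:
                g.add_edge(u, v)
    return g, truth


def gen_gene_models(n_genes: int, genome: Sequence[tuple[str, int]] | None = None,
                    gene_length: int = 2000, seed: int = 0) -> list[GeneModel]:
    """Non-overlapping synthetic gene bodies evenly spread over the genome."""
    genome = list(genome or DEFAULT_GENOME)
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(n_genes / len(genome)))
    gi = 0
    for chrom, length in genome:
        slots = np.linspace(1, length - gene_length, per_chrom, dtype=int)
        for s in slots:
            if gi >= n_genes:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{gi:04d}", chrom, int(s),
                                   int(s) + gene_length - 1, strand))
            gi += 1
    return genes


def gen_interval_plant(spec: IntervalPlantSpec, genes: Sequence[GeneModel],
                       seed: int = 0) -> list[GenomicInterval]:
    """Background intervals uniform on the genome + intervals planted near targets."""
    by_id = {g.gene_id: g for g in genes}
    missing = spec.target_genes - set(by_id)
    if missing:
        raise ValidationError(f"target genes absent from gene table: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    L = spec.interval_length
    intervals: list[GenomicInterval] = []
    chrom_names = [c for c, _ in spec.genome]
    chrom_len = dict(spec.genome)
    for _ in range(spec.n_background):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        start = int(rng.integers(1, chrom_len[chrom] - L + 1))
        intervals.append(GenomicInterval(chrom, start, start + L - 1, "background"))
    targets = sorted(spec.target_genes)
    for _ in range(spec.n_planted):
        g = by_id[targets[rng.integers(len(targets))]]
        lo = max(1, g.start - spec.window_bp)
        hi = g.end + spec.window_bp - L + 1
        start = int(rng.integers(lo, max(hi, lo + 1)))
        intervals.append(GenomicInterval(g.chrom, start, start + L - 1, "planted"))
    return intervals


def gen_annotations(genes: Sequence[str], n_categories: int,
                    planted: Mapping[str, set[str]] | None = None,
                    seed: int = 0, size_range: tuple[int, int] = (10, 50)
                    ) -> dict[str, set[str]]:
    """Random gene-category annotation table plus planted categories.

    Random categories draw uniform gene subsets with sizes uniform in
    ``size_range``; planted categories are included verbatim. Categories
    that end up empty are dropped.
    """
    genes = list(genes)
    planted = dict(planted or {})
    for cat, members in planted.items():
        stray = members - set(genes)
        if stray:
            raise ValidationError(f"planted category {cat!r} has unknown genes")
    rng = np.random.default_rng(seed)
    table: dict[str, set[str]] = {}
    for i in range(n_categories):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(genes))
        members = set(rng.choice(genes, size=size, replace=False))
        if members:
            table[f"random_cat{i:03d}"] = members
    for cat, members in planted.items():
        if members:
            table[cat] = set(members)
    return table
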