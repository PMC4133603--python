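"""Core domain types shared across the pipeline stages.

Genomic coordinates are 1-based closed throughout (mm9 annotation style);
BED input/output converts at the boundary (:mod:`grffl.io`). Expression
values are stored on the linear (RPKM-like) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """Input violates a documented invariant (duplicate ids, bad coordinates...)."""


class ParseError(ValueError):
    """A file cell or line could not be parsed; message names the location."""


@dataclass
class ExpressionMatrix:
    """Genes × conditions table of non-negative linear-scale expression values.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers.
    condition_ids : list of str
        Column identifiers, e.g. ``U, D, L, LD`` or replicate-suffixed
        variants like ``U_1, U_2``.
    values : ndarray, shape (n_genes, n_conditions)
        Non-negative expression values (RPKM-like, linear scale).
    """

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")
        if np.any(self.values < 0):
            raise ValidationError("negative expression values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass(frozen=True)
class GeneModel:
    """A gene body on the genome, 1-based closed coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"{self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval (e.g. a ChIP peak), 1-based closed coordinates."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"interval start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(f"interval end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class PipelineConfig:
    """Run-wide settings with the study defaults.

    flank_bp
        Symmetric flank added to each gene body when associating binding
        sites (default 15 kb on each side).
    k_range
        Inclusive range of cluster numbers scanned by the elbow method.
    seed
        Single seed governing every stochastic operation in a run.
    enrichment_alpha
        FDR threshold used when reporting enriched categories.
    fit_window_hours
        Optional truncation of time courses before FFL fitting (the early
        window where equal-degradation fits are most informative).
    """

    flank_bp: int = 15000
    k_range: tuple[int, int] = (8, 14)
    seed: int = 0
    enrichment_alpha: float = 1e-3
    fit_window_hours: float | None = None

    def __post_init__(self) -> None:
        if self.flank_bp < 0:
            raise ValidationError("flank_bp must be >= 0")
        self.k_range = (int(self.k_range[0]), int(self.k_range[1]))
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValidationError("k_range must satisfy 2 <= k_min <= k_max")


@dataclass
class TestResult:
    """Outcome of a two-group statistical test."""

    statistic: float
    p_value: float
    method: str
    groups: tuple[str, str] = ("", "")
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def stars(self) -> str:
        """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""
        if np.isnan(self.p_value):
            return "na"
        for marks, cut in (("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
            if self.p_value < cut:
                return marks
        return "ns"


@dataclass
class ContingencyTable:
    """2×2 contingency counts laid out as rows (a, b) / (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValidationError("negative contingency counts")
        if all(x == 0 for x in counts):
            raise ValidationError("all-zero contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def as_gene_set(genes: Sequence[str] | set[str]) -> set[str]:
    return set(genes)
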