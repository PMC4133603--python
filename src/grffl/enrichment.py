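"""Binding-site association, gene-set enrichment and motif scanning.

A binding site is "gene-associated" when its interval overlaps the gene
body extended by a symmetric flanking window (default 15 kb each side) by
at least one nucleotide; coordinates are 1-based closed. Enrichment uses
the one-sided upper-tail hypergeometric test with Benjamini-Hochberg FDR
control, and gene-set similarity is the overlap coefficient
|A ∩ B| / min(|A|, |B|).
"""

from __future__ import annotations

import itertools
import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from grffl.datatypes import (
    ContingencyTable,
    GeneModel,
    GenomicInterval,
    ValidationError,
)
from grffl.network import chi_square_yates

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAssociationSet",
    "EnrichmentResult",
    "MotifModel",
    "associate_intervals",
    "association_frequency_report",
    "hypergeometric_enrichment",
    "bh_fdr",
    "geneset_similarity_network",
    "tf_cooccurrence",
    "gre_scan",
    "expression_tiers",
]

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class GeneAssociationSet:
    """Genes associated with at least one binding site of one TF dataset."""

    tf_label: str
    associated_genes: set[str]
    window_bp: int


@dataclass
class EnrichmentResult:
    category: str
    population: int
    population_hits: int
    sample: int
    sample_hits: int
    p_value: float
    q_value: float = float("nan")


@dataclass
class MotifModel:
    """IUPAC consensus motif (default: canonical 15-mer GRE pseudo-palindrome)."""

    consensus: str = "AGAACANNNTGTTCT"
    min_report_matches: int = 7

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if not self.consensus:
            raise ValidationError("empty consensus")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValidationError(f"non-IUPAC letters in consensus: {sorted(bad)}")

    @property
    def n_defined(self) -> int:
        return sum(1 for c in self.consensus if c != "N")


def associate_intervals(peaks: Sequence[GenomicInterval],
                        genes: Sequence[GeneModel],
                        window_bp: int = 15000,
                        tf_label: str = "") -> GeneAssociationSet:
    """Associate genes with peaks overlapping gene ± window by >= 1 nt.

    Gene g is associated iff some peak on g's chromosome satisfies
    ``peak.start <= g.end + window_bp`` and ``peak.end >= max(1, g.start - window_bp)``.
    Implemented as a per-chromosome sweep over peaks sorted by start with a
    running prefix-maximum of peak ends; equivalent to the all-pairs brute
    force.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be >= 0")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    gene_chroms = {g.chrom for g in genes}
    for chrom in sorted(set(by_chrom) - gene_chroms):
        logger.warning("peaks on chromosome %s have no genes; counted unassociated",
                       chrom)
    index: dict[str, tuple[list[int], np.ndarray]] = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: p.start)
        starts = [p.start for p in plist]
        prefix_max_end = np.maximum.accumulate([p.end for p in plist])
        index[chrom] = (starts, prefix_max_end)
    hits: set[str] = set()
    for g in genes:
        if g.chrom not in index:
            continue
        starts, prefix_max_end = index[g.chrom]
        lo = max(1, g.start - window_bp)
        hi = g.end + window_bp
        i = bisect_right(starts, hi)  # peaks with start <= hi
        if i > 0 and prefix_max_end[i - 1] >= lo:
            hits.add(g.gene_id)
    return GeneAssociationSet(tf_label=tf_label, associated_genes=hits,
                              window_bp=window_bp)


def expression_tiers(m, rpkm_low: float = 1.0, rpkm_high: float = 10.0,
                     condition: str | None = None) -> dict[str, set[str]]:
    """Background gene tiers by expression level.

    non_expressors: RPKM < rpkm_low; low_expressors: rpkm_low < RPKM < rpkm_high;
    expressors: RPKM > rpkm_low — evaluated on the given condition column or
    the per-gene mean when none is given.
    """
    vals = (m.values[:, m.condition_ids.index(condition)]
            if condition is not None else m.values.mean(axis=1))
    tiers = {"non_expressors": set(), "low_expressors": set(), "expressors": set()}
    for g, v in zip(m.gene_ids, vals):
        if v < rpkm_low:
            tiers["non_expressors"].add(g)
        else:
            tiers["expressors"].add(g)
            if v < rpkm_high:
                tiers["low_expressors"].add(g)
    return tiers


def association_frequency_report(assocs: Sequence[GeneAssociationSet],
                                 gene_groups: Mapping[str, set[str]],
                                 backgrounds: Mapping[str, set[str]]) -> pd.DataFrame:
    """Per-TF association frequency of each gene group vs each background.

    A gene counts once per TF if it has >= 1 associated site. Each group is
    compared to each background tier by Yates χ² on the 2×2 table of
    (associated / not) × (group / background). Degenerate tables (identical
    proportions or an empty marginal) are reported with χ² 0 and p 1.
    """
    for name, genes in gene_groups.items():
        if not genes:
            raise ValidationError(f"empty gene group {name!r}")
    rows = []
    for assoc in assocs:
        for gname, genes in gene_groups.items():
            k = len(genes & assoc.associated_genes)
            freq = k / len(genes)
            for bname, bg in backgrounds.items():
                if not bg:
                    rows.append({"tf": assoc.tf_label, "group": gname,
                                 "background": bname, "flag": "empty background",
                                 "group_n": len(genes), "group_hits": k,
                                 "group_freq": freq, "bg_n": 0, "bg_hits": 0,
                                 "bg_freq": float("nan"),
                                 "chi2": float("nan"), "p_value": float("nan")})
                    continue
                bk = len(bg & assoc.associated_genes)
                bfreq = bk / len(bg)
                try:
                    table = ContingencyTable(k, len(genes) - k, bk, len(bg) - bk)
                    tr = chi_square_yates(table)
                    chi2, p = tr.statistic, tr.p_value
                except ValidationError:
                    chi2, p = 0.0, 1.0
                rows.append({"tf": assoc.tf_label, "group": gname,
                             "background": bname, "flag": "",
                             "group_n": len(genes), "group_hits": k,
                             "group_freq": freq,
                             "bg_n": len(bg), "bg_hits": bk, "bg_freq": bfreq,
                             "chi2": chi2, "p_value": p})
    return pd.DataFrame(rows)


def hypergeometric_enrichment(sample: set[str],
                              annotations: Mapping[str, set[str]],
                              population: set[str]) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric overrepresentation test per category.

    p = P(X >= k) with X ~ Hypergeometric(N, K, n) where N = |population|,
    K = |category ∩ population|, n = |sample|, k = |category ∩ sample|.
    Categories with K = 0 are dropped; BH q-values span the tested
    categories. Results are sorted by p.
    """
    stray = sample - population
    if stray:
        raise ValidationError(f"sample genes outside population: {sorted(stray)[:10]}")
    N, n = len(population), len(sample)
    results = []
    for cat in sorted(annotations):
        members = annotations[cat] & population
        K = len(members)
        if K == 0:
            continue
        k = len(members & sample)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(cat, N, K, n, k, p_value=min(p, 1.0)))
    if results:
        q = bh_fdr([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = qv
    results.sort(key=lambda r: (r.p_value, r.category))
    return results


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def geneset_similarity_network(categories: Mapping[str, set[str]],
                               min_similarity: float = 0.5,
                               metric: str = "overlap") -> nx.Graph:
    """Similarity network over gene categories.

    Nodes are categories; an edge joins A and B when their similarity — the
    overlap coefficient |A∩B|/min(|A|,|B|) by default, or Jaccard — reaches
    ``min_similarity``. Empty categories are dropped with a warning.
    """
    if not categories:
        raise ValidationError("no categories")
    if metric not in ("overlap", "jaccard"):
        raise ValidationError("metric must be 'overlap' or 'jaccard'")
    kept = {}
    for cat, genes in categories.items():
        if genes:
            kept[cat] = genes
        else:
            logger.warning("empty category %s dropped", cat)
    g = nx.Graph()
    g.add_nodes_from(kept)
    for a, b in itertools.combinations(sorted(kept), 2):
        inter = len(kept[a] & kept[b])
        if inter == 0:
            continue
        if metric == "overlap":
            sim = inter / min(len(kept[a]), len(kept[b]))
        else:
            sim = inter / len(kept[a] | kept[b])
        if sim >= min_similarity:
            g.add_edge(a, b, similarity=sim)
    return g


def tf_cooccurrence(assocs: Sequence[GeneAssociationSet],
                    genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-gene TF association profile and co-occurrence flag.

    A gene is a co-occurrence locus when every queried TF has >= 1 site
    associated with it (within each set's own window).
    """
    if len(assocs) < 2:
        raise ValidationError("need >= 2 TF association sets")
    labels = [a.tf_label for a in assocs]
    rows = []
    for g in genes:
        present = [a.tf_label for a in assocs if g.gene_id in a.associated_genes]
        rows.append({"gene_id": g.gene_id, "tfs": present,
                     "n_tfs": len(present),
                     "cooccurrence": len(present) == len(labels)})
    return pd.DataFrame(rows)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gre_scan(sequence: str, motif: MotifModel | None = None,
             both_strands: bool = True) -> list[tuple[int, str, int]]:
    """Slide an IUPAC consensus across a sequence and score window matches.

    For every window, ``match_count`` is the number of non-N consensus
    positions whose IUPAC class contains the sequence base. Windows with
    ``match_count >= motif.min_report_matches`` are reported as
    (0-based offset on the forward sequence, strand, match_count). The
    reverse strand is scanned against the reverse complement when requested.
    """
    motif = motif or MotifModel()
    seq = sequence.upper()
    bad = set(seq) - {"A", "C", "G", "T", "N"}
    if bad:
        raise ValidationError(f"non-nucleotide characters: {sorted(bad)}")
    m = len(motif.consensus)
    hits: list[tuple[int, str, int]] = []

    def scan(s: str, strand: str) -> None:
        for off in range(len(s) - m + 1):
            window = s[off: off + m]
            count = sum(
                1 for c, b in zip(motif.consensus, window)
                if c != "N" and b in IUPAC[c]
            )
            if count >= motif.min_report_matches:
                fwd_off = off if strand == "+" else len(s) - m - off
                hits.append((fwd_off, strand, count))

    scan(seq, "+")
    if both_strands:
        scan(reverse_complement(seq), "-")
    hits.sort()
    return hits
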