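"""Methylation-expression linkage at the gene level.

Genes are summarized from their member CpG sites (half-open containment in
the gene body, or exons only), then related to expression divergence
between the evolved and ambient lines and to expression plasticity under
reciprocal transplant: (i) OLS + Spearman of expression divergence on the
gene's maximum |delta methylation|; (ii) KS comparison of gene methylation
between plastic and nonplastic genes; (iii) Spearman of expression level
versus methylation level.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress, spearmanr

from .omics_integration import ks_compare, KsResult
from .types import ExpressionRecord, GeneAnnotation, GeneRecord, MethylationSite, MethylationTestResult


@dataclass
class RegressionResult:
    r_squared: float
    p_linear: float
    slope: float
    spearman_rho: float
    p_spearman: float
    n: int


# ---------------------------------------------------------------------------
# Plasticity classification
# ---------------------------------------------------------------------------

def classify_plastic_genes(records: list[ExpressionRecord], contrast: str,
                           alpha: float = 0.05) -> tuple[dict[str, bool], int]:
    """Label genes plastic (adj_p < alpha, strict) for one transplant contrast.

    Genes with missing adjusted p-values are excluded from both classes;
    the exclusion count is returned alongside the labels.
    """
    labels: dict[str, bool] = {}
    n_excluded = 0
    for r in records:
        if r.contrast != contrast:
            continue
        if r.adj_p is None:
            n_excluded += 1
            continue
        labels[r.gene_id] = r.adj_p < alpha
    return labels, n_excluded


# ---------------------------------------------------------------------------
# Gene-level methylation summaries
# ---------------------------------------------------------------------------

def _sites_in_gene(gene: GeneAnnotation, sites: list[MethylationSite],
                   scope: str) -> list[MethylationSite]:
    if scope == "gene":
        return [s for s in sites
                if s.chrom == gene.chrom and gene.start <= s.pos < gene.end]
    if scope == "exon":
        exons = gene.exons if gene.exons is not None else [(gene.start, gene.end)]
        return [s for s in sites
                if s.chrom == gene.chrom
                and any(st <= s.pos < en for st, en in exons)]
    raise ValueError(f"unknown scope {scope!r}")


def summarize_gene_methylation(genes: list[GeneAnnotation],
                               meth_sites: list[MethylationSite],
                               test_results: dict[str, MethylationTestResult],
                               line_samples: dict[str, list[str]],
                               scope: str = "gene") -> list[GeneRecord]:
    """Per-gene methylation summary for the linkage analyses.

    ``test_results`` maps site_id -> differential result for the focal
    treatment contrast; ``line_samples`` maps a line label to its sample
    ids (mean methylation per line averages per-site proportions over the
    line's replicates, then over sites). A site overlapping several genes
    contributes to each. Genes with zero member sites yield n = 0 records.
    """
    records = []
    for gene in genes:
        member = _sites_in_gene(gene, meth_sites, scope)
        rec = GeneRecord(gene_id=gene.gene_id, n_meth_sites=len(member))
        if member:
            for line, sample_ids in line_samples.items():
                per_site = [np.mean([s.proportion(sid) for sid in sample_ids if sid in s.counts])
                            for s in member]
                rec.mean_methylation[line] = float(np.mean(per_site))
            deltas = [test_results[s.site_id].delta for s in member
                      if s.site_id in test_results]
            if deltas:
                rec.max_abs_delta_meth = float(max(abs(d) for d in deltas))
            rec.has_sig_meth = any(
                test_results[s.site_id].significant for s in member
                if s.site_id in test_results)
        records.append(rec)
    return records


def regression_cohort(records: list[GeneRecord], min_sites: int = 5) -> list[GeneRecord]:
    """Genes eligible for the divergence regression: >= min_sites member CpGs
    and at least one significantly diverged one."""
    return [r for r in records if r.n_meth_sites >= min_sites and r.has_sig_meth]


# ---------------------------------------------------------------------------
# Regressions and comparisons
# ---------------------------------------------------------------------------

def regress_methylation_expression(x, y, subset: set[str] | None = None,
                                   gene_ids: list[str] | None = None) -> RegressionResult:
    """OLS + Spearman of expression divergence (y) on max |delta meth| (x).

    With ``subset`` given (e.g. a functionally enriched gene list), only
    genes in it enter; ``gene_ids`` aligns with x/y in that case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if subset is not None:
        if gene_ids is None:
            raise ValueError("subset requires gene_ids aligned with x and y")
        mask = np.array([g in subset for g in gene_ids])
        x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError(f"need n >= 3 points, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    ols = linregress(x, y)
    rho, p_s = spearmanr(x, y)
    return RegressionResult(
        r_squared=float(ols.rvalue ** 2), p_linear=float(ols.pvalue),
        slope=float(ols.slope), spearman_rho=float(rho),
        p_spearman=float(p_s), n=len(x))


def compare_methylation_by_plasticity(records: list[GeneRecord],
                                      plastic_labels: dict[str, bool],
                                      line: str) -> KsResult:
    """KS test of gene mean methylation, plastic (label True) vs nonplastic.

    ``line`` selects which line's methylation enters (the transplanted
    line). Genes without a plasticity label or methylation value are
    skipped. In the KS result the True class is plastic.
    """
    values, labels = [], []
    for r in records:
        if r.gene_id not in plastic_labels or line not in r.mean_methylation:
            continue
        values.append(r.mean_methylation[line])
        labels.append(plastic_labels[r.gene_id])
    return ks_compare(values, labels, n_tests=1)


def correlate_expression_level_methylation(mean_expression, mean_methylation) -> RegressionResult:
    """Spearman association of gene expression magnitude with methylation level."""
    x = np.asarray(mean_expression, dtype=float)
    y = np.asarray(mean_methylation, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    rho, p_s = spearmanr(x, y)
    ols = linregress(x, y)
    return RegressionResult(
        r_squared=float(ols.rvalue ** 2), p_linear=float(ols.pvalue),
        slope=float(ols.slope), spearman_rho=float(rho),
        p_spearman=float(p_s), n=len(x))


__all__ = [
    "RegressionResult", "classify_plastic_genes", "summarize_gene_methylation",
    "regression_cohort", "regress_methylation_expression",
    "compare_methylation_by_plasticity", "correlate_expression_level_methylation",
]
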