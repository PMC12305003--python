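"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open throughout the package.
File dialects that use 1-based coordinates (Bismark coverage, sync) are
converted on read and restored on write by :mod:`epievolve.io_formats`.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class MethylationSite:
    """One CpG locus with per-sample (methylated, total) read counts.

    ``counts`` maps sample_id -> (meth_count, total_count). A site may be
    built up incrementally, one sample per input file.
    """

    site_id: str
    chrom: str
    pos: int  # 0-based
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def proportion(self, sample_id: str) -> float:
        m, t = self.counts[sample_id]
        return m / t

    def validate(self) -> None:
        if self.pos < 0:
            raise ValueError(f"{self.site_id}: negative position {self.pos}")
        for sid, (m, t) in self.counts.items():
            if m < 0 or t <= 0 or m > t:
                raise ValueError(
                    f"{self.site_id}/{sid}: invalid counts meth={m} total={t}"
                )


@dataclass
class SnpSite:
    """One biallelic locus with per-pool (alt, total) read counts.

    ``pool_haploid_size`` is the number of chromosomes in each pool
    (2 x individuals). ``ref_allele``/``alt_allele`` record which bases the
    counts refer to so a site can be written back to sync dialect; ``alt``
    is always the overall minor (lower total read count) allele.
    """

    snp_id: str
    chrom: str
    pos: int  # 0-based
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    pool_haploid_size: int = 2
    ref_allele: str = "N"
    alt_allele: str = "N"

    def alt_frequency(self, pool_id: str) -> float:
        a, t = self.counts[pool_id]
        return a / t


@dataclass
class GeneAnnotation:
    """Gene interval, optionally with exon sub-intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] | None = None

    def validate(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        for s, e in self.exons or []:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"{self.gene_id}: exon [{s},{e}) outside gene "
                    f"[{self.start},{self.end})"
                )


@dataclass
class ExpressionRecord:
    """Gene-level differential-expression summary for one contrast."""

    gene_id: str
    contrast: str
    log2fc: float
    adj_p: float | None
    mean_expression: float


@dataclass
class MethylationTestResult:
    """Per-site differential-methylation call for one treatment contrast.

    ``delta`` is the model estimate of treatment minus control methylation
    proportion; ``q_value`` is BH-adjusted and NaN until FDR correction has
    been applied across sites.
    """

    site_id: str
    delta: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


@dataclass
class PermutationResult:
    """Output of the label-randomization test on window values.

    ``observed_diff`` is mean(values | label False) - mean(values | label
    True); the one-sided p-value uses the add-one convention
    (n_ge + 1) / (n_perm + 1), so 0 < p <= 1 always.
    """

    observed_diff: float
    n_perm: int
    n_ge: int
    p_value: float
    seed: int
    n_false: int = 0
    n_true: int = 0


@dataclass
class GenomicWindow:
    """Non-overlapping genomic tile with member loci and derived statistics.

    ``mean_fst`` maps (treatment, replicate) -> mean member-site F_ST;
    ``sig_meth`` and ``mean_abs_delta_meth`` map treatment -> value;
    ``pi`` maps pool_id -> per-bp nucleotide diversity.
    """

    window_id: str
    chrom: str
    start: int
    end: int
    snp_ids: set[str] = field(default_factory=set)
    meth_ids: set[str] = field(default_factory=set)
    mean_fst: dict[tuple[str, int], float] = field(default_factory=dict)
    sig_meth: dict[str, bool] = field(default_factory=dict)
    mean_abs_delta_meth: dict[str, float] = field(default_factory=dict)
    pi: dict[str, float] = field(default_factory=dict)
    partial: bool = False  # trailing window shorter than the grid length


@dataclass
class GeneRecord:
    """Gene-level methylation/expression summary used by the linkage analyses."""

    gene_id: str
    n_meth_sites: int
    mean_methylation: dict[str, float] = field(default_factory=dict)  # per line
    max_abs_delta_meth: float = float("nan")
    has_sig_meth: bool = False
    expression_divergence: float = float("nan")
    plastic: dict[str, bool] = field(default_factory=dict)  # per transplant contrast
    mean_expression: float = float("nan")
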