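"""Pool-seq population-genetic estimators: per-site F_ST and windowed pi.

F_ST uses the identity-in-state (ANOVA-family) estimator for pooled data:
read counts are a two-stage sample (individuals into the pool, reads from
the pool), so the within-pool probability that two distinct reads match
mixes same-chromosome pairs (identity 1) with different-chromosome pairs.
Correcting for the pool's haploid size yields an unbiased within-pool IIS
Q1; reads from different pools always come from different chromosomes, so
the cross-pool product estimates Q2 directly. F_ST = (Q1 - Q2) / (1 - Q2).
As read depth grows this converges to the Weir-Cockerham two-population
estimator on the pools' allele counts (haploid form, equal pool sizes).

pi is Tajima's per-bp nucleotide diversity from read counts: the per-site
heterozygosity 2 a (r - a) / (r (r - 1)) is unbiased under read sampling
(a alt reads of r total), summed over a window and divided by its length.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import SnpSite

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Per-site F_ST
# ---------------------------------------------------------------------------

def fst_site_pairwise(counts_a: tuple[int, int], counts_b: tuple[int, int],
                      haploid_size_a: int, haploid_size_b: int,
                      mode: str = "anova") -> float:
    """Pairwise per-site F_ST between two pools from (alt, total) read counts.

    ``mode="anova"`` (default) is the two-stage IIS estimator described in
    the module docstring; negative values are retained (unbiased null
    behavior). ``mode="nei"`` is the naive frequency-based (Ht - Hs) / Ht
    cross-check that ignores sampling noise. Returns NaN (with a warning)
    when either pool has zero coverage or the estimator is undefined.
    """
    a1, r1 = counts_a
    a2, r2 = counts_b
    if r1 <= 0 or r2 <= 0:
        logger.warning("fst undefined: zero total read count in a pool")
        return float("nan")
    if mode == "nei":
        p1, p2 = a1 / r1, a2 / r2
        pbar = (p1 + p2) / 2
        ht = pbar * (1 - pbar)
        if ht == 0:
            return float("nan")
        hs = (p1 * (1 - p1) + p2 * (1 - p2)) / 2
        return (ht - hs) / ht
    if mode != "anova":
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = haploid_size_a, haploid_size_b
    if n1 < 2 or n2 < 2:
        raise ValueError("pool haploid sizes must be >= 2")
    if r1 < 2 or r2 < 2:
        logger.warning("fst undefined: need >=2 reads per pool for within-pool IIS")
        return float("nan")
    q1 = _within_pool_iis(a1, r1, n1)
    q2 = _within_pool_iis(a2, r2, n2)
    Q1 = 0.5 * (q1 + q2)
    Q2 = (a1 * a2 + (r1 - a1) * (r2 - a2)) / (r1 * r2)
    den = 1.0 - Q2
    if den <= 0:
        return float("nan")
    return (Q1 - Q2) / den


def _within_pool_iis(a: int, r: int, n: int) -> float:
    """Unbiased IIS probability for two distinct chromosomes of the pool.

    Two distinct reads match with probability 1/n + (1 - 1/n) Q1, so the
    read-pair matching rate is inverted for Q1.
    """
    match = (a * (a - 1) + (r - a) * (r - a - 1)) / (r * (r - 1))
    return (n * match - 1.0) / (n - 1.0)


def fst_weir_cockerham(count_a: int, n_a: int, count_b: int, n_b: int) -> float:
    """Weir-Cockerham two-population theta on haploid allele counts.

    The infinite-depth limit of the pool estimator; used as an independent
    reference in the test suite and exposed for direct allele-count data.
    """
    p1, p2 = count_a / n_a, count_b / n_b
    nbar = (n_a + n_b) / 2.0
    r = 2
    nc = (r * nbar - (n_a ** 2 + n_b ** 2) / (r * nbar)) / (r - 1)
    pbar = (n_a * p1 + n_b * p2) / (r * nbar)
    s2 = (n_a * (p1 - pbar) ** 2 + n_b * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2)
    tot = a + b
    return a / tot if tot != 0 else float("nan")


def fst_all_sites(snp_sites: list[SnpSite], pool_a: str, pool_b: str,
                  mode: str = "anova") -> dict[str, float]:
    """Per-site F_ST for one pool pairing; missing pools/coverage give NaN."""
    out = {}
    for s in snp_sites:
        ca = s.counts.get(pool_a)
        cb = s.counts.get(pool_b)
        if ca is None or cb is None:
            logger.warning("%s: pool missing for pairing (%s, %s)", s.snp_id, pool_a, pool_b)
            out[s.snp_id] = float("nan")
            continue
        out[s.snp_id] = fst_site_pairwise(ca, cb, s.pool_haploid_size,
                                          s.pool_haploid_size, mode=mode)
    return out


def window_mean_fst(site_fst: dict[str, float],
                    window_snp_ids: dict[str, set[str]]) -> dict[str, float]:
    """Arithmetic mean of member-site F_ST per window, NaN sites excluded.

    Windows whose member sites are all missing get NaN.
    """
    out = {}
    for wid, snp_ids in window_snp_ids.items():
        vals = [site_fst[sid] for sid in snp_ids
                if sid in site_fst and np.isfinite(site_fst[sid])]
        out[wid] = float(np.mean(vals)) if vals else float("nan")
    return out


# ---------------------------------------------------------------------------
# Windowed pi
# ---------------------------------------------------------------------------

@dataclass
class PiWindow:
    chrom: str
    start: int
    end: int
    pi: float
    n_sites: int
    partial: bool = False


def site_heterozygosity(alt: int, total: int, pool_haploid_size: int | None = None) -> float:
    """Read-sampling-unbiased per-site heterozygosity 2a(r-a)/(r(r-1)).

    With ``pool_haploid_size`` given, the additional finite-pool correction
    n/(n-1) is applied (off by default in the window estimator).
    """
    if total < 2:
        raise ValueError("need >=2 reads")
    h = 2.0 * alt * (total - alt) / (total * (total - 1))
    if pool_haploid_size is not None:
        h *= pool_haploid_size / (pool_haploid_size - 1)
    return h


def pi_windows(snp_sites: list[SnpSite], contigs: dict[str, int], pool_id: str,
               window_len: int = 100, pool_size_correction: bool = False) -> list[PiWindow]:
    """Tajima's pi per pool in non-overlapping windows (default 100 bp).

    Sites with fewer than 2 reads are excluded; empty windows have pi = 0.
    The trailing partial window of each contig is kept but flagged. pi is
    normalized by the actual window length.
    """
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    sums: dict[tuple[str, int], tuple[float, int]] = {}
    for s in snp_sites:
        if pool_id not in s.counts:
            continue
        a, r = s.counts[pool_id]
        if r < 2:
            continue
        h = site_heterozygosity(a, r, s.pool_haploid_size if pool_size_correction else None)
        key = (s.chrom, s.pos // window_len)
        tot, n = sums.get(key, (0.0, 0))
        sums[key] = (tot + h, n + 1)
    out = []
    for chrom, length in contigs.items():
        n_win = (length + window_len - 1) // window_len
        for k in range(n_win):
            start = k * window_len
            end = min((k + 1) * window_len, length)
            tot, n = sums.get((chrom, k), (0.0, 0))
            out.append(PiWindow(chrom, start, end, tot / (end - start), n,
                                partial=(end - start) != window_len))
    return out


__all__ = [
    "fst_site_pairwise", "fst_weir_cockerham", "fst_all_sites",
    "window_mean_fst", "site_heterozygosity", "pi_windows", "PiWindow",
]
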