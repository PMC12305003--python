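"""Window construction, SNP/CpG intersection, and randomization tests.

This is the core analysis: tile the genome into fixed windows (1.5 kb by
default), keep windows carrying enough SNPs and methylation loci, flag each
window by whether it contains at least one significant methylation change,
and ask — by label permutation — whether mean window F_ST differs between
flagged and unflagged windows. Companion analyses stratify the test by
nucleotide diversity, run it in reverse (methylation change across
allele-divergent windows), compare pi distributions by KS test, and count
overlaps of significant loci between treatments.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp

from .types import GenomicWindow, PermutationResult

DEFAULT_PI_BINS = (0.0, 0.005, 0.01, 0.015, 0.02, 0.03, float("inf"))


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

@dataclass
class WindowReport:
    n_windows_tiled: int
    n_retained: int
    n_dropped_snps: int
    n_dropped_meth: int


def build_and_filter_windows(contigs: dict[str, int], snp_sites, meth_sites,
                             window_len: int = 1500, min_snps: int = 5,
                             min_meth: int = 5) -> tuple[list[GenomicWindow], WindowReport]:
    """Tile contigs into [k*L, (k+1)*L) windows and keep well-populated ones.

    Sites are assigned by half-open containment (start <= pos < end); the
    trailing partial window is kept (flagged). A window must hold at least
    ``min_snps`` SNPs and ``min_meth`` methylation sites to be retained;
    a window failing both minima counts in the SNP-dropped tally.
    """
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    snp_in: dict[tuple[str, int], set[str]] = {}
    for s in snp_sites:
        snp_in.setdefault((s.chrom, s.pos // window_len), set()).add(s.snp_id)
    meth_in: dict[tuple[str, int], set[str]] = {}
    for s in meth_sites:
        meth_in.setdefault((s.chrom, s.pos // window_len), set()).add(s.site_id)
    windows: list[GenomicWindow] = []
    n_tiled = n_drop_snp = n_drop_meth = 0
    for chrom, length in contigs.items():
        n_win = (length + window_len - 1) // window_len
        for k in range(n_win):
            n_tiled += 1
            start, end = k * window_len, min((k + 1) * window_len, length)
            snps = snp_in.get((chrom, k), set())
            meths = meth_in.get((chrom, k), set())
            if len(snps) < min_snps:
                n_drop_snp += 1
                continue
            if len(meths) < min_meth:
                n_drop_meth += 1
                continue
            windows.append(GenomicWindow(
                window_id=f"{chrom}:{start}-{end}", chrom=chrom, start=start, end=end,
                snp_ids=snps, meth_ids=meths, partial=(end - start) != window_len))
    return windows, WindowReport(n_tiled, len(windows), n_drop_snp, n_drop_meth)


def flag_window_methylation_significance(windows: list[GenomicWindow],
                                         sig_sites: dict[str, set[str]]) -> None:
    """Set each window's per-treatment flag: >=1 significant member site."""
    for w in windows:
        for treatment, sites in sig_sites.items():
            w.sig_meth[treatment] = bool(w.meth_ids & sites)


# ---------------------------------------------------------------------------
# Randomization test
# ---------------------------------------------------------------------------

def randomization_test(values, labels, n_perm: int = 10000,
                       seed: int = 0) -> PermutationResult:
    """One-sided label-randomization test on window values.

    Observed statistic: mean(values | label False) - mean(values | label
    True). Labels are reshuffled uniformly, preserving class sizes; the
    p-value is (n_ge + 1) / (n_perm + 1) where n_ge counts permuted
    statistics >= the observed one (ties count, conservative).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be matching 1-d arrays")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_true = int(labels.sum())
    n_false = int(len(labels) - n_true)
    if n_true == 0 or n_false == 0:
        raise ValueError("both label classes must be non-empty")
    total = values.sum()
    sum_true = values[labels].sum()
    observed = (total - sum_true) / n_false - sum_true / n_true
    rng = np.random.default_rng(seed)
    n = len(values)
    # the mean difference is a strictly decreasing function of the permuted
    # true-class sum, so "permuted stat >= observed" is "permuted sum <=
    # observed sum"; the tolerance absorbs float addition-order noise and is
    # relative, keeping the count invariant to affine value transforms
    tol = 1e-12 * max(1.0, abs(sum_true))
    n_ge = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=n_true, replace=False)
        if values[idx].sum() <= sum_true + tol:
            n_ge += 1
    p = (n_ge + 1) / (n_perm + 1)
    return PermutationResult(float(observed), n_perm, n_ge, float(p), seed,
                             n_false=n_false, n_true=n_true)


def fst_vs_methylation_test(windows: list[GenomicWindow], treatment: str,
                            n_perm: int = 10000, seed: int = 0,
                            replicate_mode: str = "pooled") -> PermutationResult:
    """Randomization test of mean window F_ST by methylation significance.

    ``pooled`` (default) enters one point per (window, replicate), as the
    per-replicate display does; ``mean`` averages replicates per window
    first. Windows lacking any finite F_ST are excluded.
    """
    values, labels = [], []
    for w in windows:
        reps = [v for (t, _r), v in w.mean_fst.items()
                if t == treatment and np.isfinite(v)]
        if not reps:
            continue
        if replicate_mode == "pooled":
            values.extend(reps)
            labels.extend([w.sig_meth[treatment]] * len(reps))
        elif replicate_mode == "mean":
            values.append(float(np.mean(reps)))
            labels.append(w.sig_meth[treatment])
        else:
            raise ValueError(f"unknown replicate_mode {replicate_mode!r}")
    return randomization_test(values, labels, n_perm=n_perm, seed=seed)


def reverse_methylation_by_allele_divergence(windows: list[GenomicWindow],
                                             divergent_window_ids: set[str],
                                             treatment: str,
                                             n_perm: int = 10000,
                                             seed: int = 0) -> PermutationResult:
    """Mean |delta methylation| across windows with vs without allele divergence.

    Divergence labels are supplied externally (truth in synthetic runs);
    statistic orientation matches :func:`randomization_test`: windows
    *without* divergence minus windows *with*.
    """
    if not divergent_window_ids:
        raise ValueError("empty allele-divergence set")
    values, labels = [], []
    for w in windows:
        v = w.mean_abs_delta_meth.get(treatment)
        if v is None or not np.isfinite(v):
            continue
        values.append(v)
        labels.append(w.window_id in divergent_window_ids)
    return randomization_test(values, labels, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# pi stratification and KS comparison
# ---------------------------------------------------------------------------

def assign_pi_bin(pi: float, bins=DEFAULT_PI_BINS) -> int:
    """Left-closed, right-open bin index for a window's pi."""
    edges = np.asarray(bins, dtype=float)
    idx = int(np.searchsorted(edges, pi, side="right") - 1)
    if idx < 0 or idx >= len(edges) - 1:
        raise ValueError(f"pi {pi} outside bin range")
    return idx


def pi_stratified_fst(windows: list[GenomicWindow], treatment: str, pool_id: str,
                      bins=DEFAULT_PI_BINS, n_perm: int = 10000, seed: int = 0,
                      min_class: int = 3, replicate_mode: str = "pooled") -> dict:
    """Run the F_ST randomization test within pi bins.

    Returns bin index -> PermutationResult, or a skip-reason string where
    either label class holds fewer than ``min_class`` windows.
    """
    by_bin: dict[int, list[GenomicWindow]] = {}
    for w in windows:
        pi = w.pi.get(pool_id)
        if pi is None or not np.isfinite(pi):
            continue
        by_bin.setdefault(assign_pi_bin(pi, bins), []).append(w)
    results: dict[int, object] = {}
    rng = np.random.default_rng(seed)
    for b in range(len(bins) - 1):
        ws = by_bin.get(b, [])
        n_sig = sum(1 for w in ws if w.sig_meth.get(treatment))
        n_non = len(ws) - n_sig
        if n_sig < min_class or n_non < min_class:
            results[b] = (f"skipped: {n_sig} significant / {n_non} non-significant "
                          f"windows (need >= {min_class} each)")
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        results[b] = fst_vs_methylation_test(ws, treatment, n_perm=n_perm,
                                             seed=sub_seed, replicate_mode=replicate_mode)
    return results


@dataclass
class KsResult:
    statistic: float
    p_value: float
    p_bonferroni: float
    mean_true: float
    se_true: float
    mean_false: float
    se_false: float
    n_true: int
    n_false: int


def ks_compare(values, labels, n_tests: int = 3) -> KsResult:
    """Two-sample two-sided KS test of values split by a boolean label.

    Bonferroni multiplies the raw p by ``n_tests`` (number of treatments
    compared), clipped to 1. Also reports per-class mean +/- SE.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    a = values[labels]
    b = values[~labels]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be non-empty")
    res = ks_2samp(a, b, alternative="two-sided", method="auto")

    def se(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    return KsResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        p_bonferroni=float(min(1.0, res.pvalue * n_tests)),
        mean_true=float(a.mean()), se_true=se(a),
        mean_false=float(b.mean()), se_false=se(b),
        n_true=len(a), n_false=len(b))


def ks_compare_pi(windows: list[GenomicWindow], treatment: str, pool_id: str,
                  n_tests: int = 3, include_partial: bool = False) -> KsResult:
    """KS comparison of window pi between methylation-significant classes.

    Trailing partial windows are excluded from the per-bp comparison by
    default since their normalization differs.
    """
    values, labels = [], []
    for w in windows:
        if w.partial and not include_partial:
            continue
        pi = w.pi.get(pool_id)
        if pi is None or not np.isfinite(pi):
            continue
        values.append(pi)
        labels.append(bool(w.sig_meth.get(treatment)))
    return ks_compare(values, labels, n_tests=n_tests)


# ---------------------------------------------------------------------------
# Overlaps
# ---------------------------------------------------------------------------

def overlap_counts(sig_sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Pairwise and full intersection sizes of significant-site sets."""
    out: dict[tuple[str, ...], int] = {}
    names = sorted(sig_sets)
    for a, b in itertools.combinations(names, 2):
        out[(a, b)] = len(sig_sets[a] & sig_sets[b])
    if len(names) >= 3:
        inter = set.intersection(*(sig_sets[n] for n in names))
        out[tuple(names)] = len(inter)
    return out


__all__ = [
    "DEFAULT_PI_BINS", "WindowReport", "build_and_filter_windows",
    "flag_window_methylation_significance", "randomization_test",
    "fst_vs_methylation_test", "reverse_methylation_by_allele_divergence",
    "assign_pi_bin", "pi_stratified_fst", "KsResult", "ks_compare",
    "ks_compare_pi", "overlap_counts",
]
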