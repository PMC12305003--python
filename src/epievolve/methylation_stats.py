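"""Coverage filtering, methylation summaries, and differential methylation.

The differential test models a site's methylated read counts as
beta-binomial in the total counts, with a group-specific mean ``mu_g`` and a
site-level dispersion ``phi`` shared between groups (correlation
parameterization: ``alpha + beta = (1 - phi) / phi``). The null hypothesis
``mu_treatment = mu_control`` is tested with a likelihood-ratio statistic.

Two inference paths are provided. The default for genome-wide calling
pools one dispersion across all sites (:func:`estimate_common_dispersion`,
a Cox-Reid adjusted profile likelihood) and tests each site with the
dispersion held fixed, against chi-square(1) — the moderation strategy
that gives small-replicate designs (4 vs 4 pools) usable power. The
standalone per-site path estimates the dispersion from the site's own
replicates; because three ML parameters then come from eight
observations, chi-square(1) is anti-conservative and the statistic is
referred to F(1, N - G) instead (N samples, G group means — the
residual-df convention of quasi-likelihood F-tests). Both paths hold
near-nominal type-I error across realistic coverage regimes (checked by
simulation in the test suite).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, expit, gammaln, logit
from scipy.stats import chi2, f_oneway
from scipy.stats import f as f_dist
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .types import MethylationSite, MethylationTestResult

PHI_FLOOR = 1e-8  # dispersion floor: avoids the boundary of the parameter space
PHI_CEIL = 1 - 1e-6   # upper guard: phi -> 1 degenerates the likelihood
_MU_EPS = 1e-6


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    line: str        # treatment label: AM, OA, OW, OWA
    generation: str  # F0 or F25
    replicate: int


class DesignTable:
    """Maps sample_id -> (line, generation, replicate)."""

    def __init__(self, samples: dict[str, SampleInfo]):
        self.samples = dict(samples)

    def sample_ids(self, line: str | None = None, generation: str | None = None) -> list[str]:
        return [sid for sid, info in self.samples.items()
                if (line is None or info.line == line)
                and (generation is None or info.generation == generation)]

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples.items())


# ---------------------------------------------------------------------------
# Coverage filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input: int
    n_removed_low: int
    n_removed_high: int
    n_retained: int
    quantile_threshold: float


def filter_by_coverage(sites: list[MethylationSite], min_cov: int = 15,
                       max_quantile: float = 0.975,
                       quantile_scope: str = "all") -> tuple[list[MethylationSite], FilterReport]:
    """Keep sites covered >= min_cov in every sample and below the upper quantile.

    The upper threshold is the ``max_quantile`` quantile of site x sample
    totals (``quantile_scope="all"``, default) or of per-site mean totals
    (``"site_mean"``); a site is removed if any sample's total exceeds the
    threshold (strict >), which guards against multi-mapping artifacts.
    Both removal counts are reported; a site failing both filters counts as
    a low-coverage removal.
    """
    if not sites:
        return [], FilterReport(0, 0, 0, 0, float("nan"))
    all_totals = np.array([t for s in sites for (_, t) in s.counts.values()], dtype=float)
    if quantile_scope == "all":
        thresh = float(np.quantile(all_totals, max_quantile))
    elif quantile_scope == "site_mean":
        means = np.array([np.mean([t for (_, t) in s.counts.values()]) for s in sites])
        thresh = float(np.quantile(means, max_quantile))
    else:
        raise ValueError(f"unknown quantile_scope {quantile_scope!r}")
    kept: list[MethylationSite] = []
    n_low = n_high = 0
    for s in sites:
        totals = [t for (_, t) in s.counts.values()]
        if min(totals) < min_cov:
            n_low += 1
        elif max(totals) > thresh:
            n_high += 1
        else:
            kept.append(s)
    return kept, FilterReport(len(sites), n_low, n_high, len(kept), thresh)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def global_mean_methylation(sites, sample_id: str, method: str = "per_site") -> float:
    """Mean methylation for one sample over the (filtered) site set.

    ``per_site`` (default) averages per-site proportions; ``pooled`` sums
    counts before dividing.
    """
    if not sites:
        raise ValueError("no sites: cannot compute mean methylation")
    if method == "per_site":
        return float(np.mean([s.proportion(sample_id) for s in sites]))
    if method == "pooled":
        m = sum(s.counts[sample_id][0] for s in sites)
        t = sum(s.counts[sample_id][1] for s in sites)
        return m / t
    raise ValueError(f"unknown method {method!r}")


def compare_mean_methylation(means: dict[str, float], groups: dict[str, str],
                             tukey: bool = True):
    """One-way ANOVA across groups plus a Tukey HSD pairwise table.

    ``means`` maps sample_id -> mean methylation, ``groups`` maps sample_id
    -> group label. Returns (anova_p, tukey_frame) where tukey_frame has
    columns group1, group2, meandiff, p_adj (``None`` with ``tukey=False``,
    which skips the comparatively slow pairwise table).
    """
    import pandas as pd

    by_group: dict[str, list[float]] = {}
    for sid, val in means.items():
        by_group.setdefault(groups[sid], []).append(val)
    if len(by_group) < 2:
        raise ValueError("need >=2 groups")
    for g, vals in by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has a single sample")
    arrays = list(by_group.values())
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        anova_p = 1.0  # all observations identical: F = 0/0, no evidence
    else:
        anova_p = float(f_oneway(*arrays).pvalue)
    if not tukey:
        return anova_p, None
    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(v) for g, v in by_group.items()])
    tk = pairwise_tukeyhsd(values, labels)
    frame = pd.DataFrame(tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]])
    frame = frame.rename(columns={"p-adj": "p_adj"})[["group1", "group2", "meandiff", "p_adj"]]
    frame["meandiff"] = frame["meandiff"].astype(float)
    frame["p_adj"] = frame["p_adj"].astype(float)
    return anova_p, frame


def conversion_efficiency(lambda_counts) -> float:
    """Bisulfite conversion efficiency from an unmethylated spike-in.

    ``lambda_counts`` is an iterable of (meth_count, total_count) per
    cytosine call set on the unmethylated control genome. Every apparent
    methylated call is a conversion failure, so efficiency is
    1 - (sum meth / sum total), pooled over all calls.
    """
    meth = tot = 0
    for m, t in lambda_counts:
        meth += m
        tot += t
    if tot == 0:
        raise ValueError("no lambda calls: cannot estimate conversion efficiency")
    return 1.0 - meth / tot


# ---------------------------------------------------------------------------
# Beta-binomial likelihood machinery
# ---------------------------------------------------------------------------

def _bb_loglik_vec(m: np.ndarray, n: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Elementwise beta-binomial log-pmf with per-element mean."""
    s = (1.0 - phi) / phi
    a = mu * s
    b = (1.0 - mu) * s
    return (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
            + betaln(m + a, n - m + b) - betaln(a, b))


def estimate_common_dispersion(sites: list[MethylationSite], design: DesignTable,
                               generation: str | None = None) -> float:
    """Pooled ML estimate of one dispersion shared by all sites.

    Replicate groups are (line, generation) cells of the design; each
    site x group block contributes its likelihood at the block's
    count-weighted mean methylation (the ML mean to very good
    approximation), and a single phi maximizes the total. Sharing the
    dispersion across sites is what gives the per-site tests their power at
    a handful of replicates — the same moderation idea the established
    count-model toolkits use.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for sid, info in design:
        if generation is not None and info.generation != generation:
            continue
        groups.setdefault((info.line, info.generation), []).append(sid)
    m_parts, n_parts, mu_parts, block_idx = [], [], [], []
    block = 0
    for sample_ids in groups.values():
        if len(sample_ids) < 2:
            continue
        for s in sites:
            pairs = [s.counts[sid] for sid in sample_ids if sid in s.counts]
            if len(pairs) < 2:
                continue
            m = np.array([p[0] for p in pairs], dtype=float)
            n = np.array([p[1] for p in pairs], dtype=float)
            mu = min(max(m.sum() / n.sum(), _MU_EPS), 1 - _MU_EPS)
            m_parts.append(m)
            n_parts.append(n)
            mu_parts.append(np.full(len(m), mu))
            block_idx.append(np.full(len(m), block))
            block += 1
    if not m_parts:
        raise ValueError("no replicated groups: cannot estimate a common dispersion")
    m_all = np.concatenate(m_parts)
    n_all = np.concatenate(n_parts)
    mu_all = np.concatenate(mu_parts)
    blk = np.concatenate(block_idx).astype(int)
    muq = mu_all * (1.0 - mu_all)

    def neg_adj_profile(t):
        # Cox-Reid adjusted profile likelihood: profiling one mean per block
        # biases the dispersion low, so subtract half the log Fisher
        # information of each profiled mean (quasi-binomial form
        # Var = n mu (1-mu) (1 + (n-1) phi)).
        phi = min(max(expit(t), PHI_FLOOR), PHI_CEIL)
        ll = float(np.sum(_bb_loglik_vec(m_all, n_all, mu_all, phi)))
        info_terms = n_all / (muq * (1.0 + (n_all - 1.0) * phi))
        info_per_block = np.bincount(blk, weights=info_terms)
        ll -= 0.5 * float(np.sum(np.log(info_per_block)))
        return -ll

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(neg_adj_profile, bounds=(-18.0, 3.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(min(max(expit(res.x), PHI_FLOOR), PHI_CEIL))


def _fit_mu_fixed_phi(m: np.ndarray, n: np.ndarray, phi: float) -> tuple[float, float]:
    """ML mean under a known dispersion; returns (mu_hat, loglik)."""
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(
        lambda t: -_bb_loglik(m, n, min(max(expit(t), _MU_EPS), 1 - _MU_EPS), phi),
        bounds=(-16.0, 16.0), method="bounded", options={"xatol": 1e-9})
    mu = float(min(max(expit(res.x), _MU_EPS), 1 - _MU_EPS))
    return mu, -float(res.fun)


def _bb_loglik(m: np.ndarray, n: np.ndarray, mu: float, phi: float) -> float:
    s = (1.0 - phi) / phi
    a = mu * s
    b = (1.0 - mu) * s
    return float(np.sum(gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
                        + betaln(m + a, n - m + b) - betaln(a, b)))


def _moment_phi(m: np.ndarray, n: np.ndarray) -> float:
    """Moment starting value for the dispersion from replicate proportions."""
    p = m / n
    mu = float(np.mean(p))
    if mu <= 0 or mu >= 1 or len(p) < 2:
        return 1e-3
    v = float(np.var(p, ddof=1))
    binom_v = mu * (1 - mu) * float(np.mean(1.0 / n))
    phi = (v - binom_v) / (mu * (1 - mu)) if mu * (1 - mu) > 0 else 1e-3
    return float(min(max(phi, 1e-4), 0.9))


def _fit_bb(groups: list[tuple[np.ndarray, np.ndarray]]) -> tuple[list[float], float, float]:
    """ML fit of group means and one shared dispersion.

    Returns (mu_hats, phi_hat, loglik). Group means are optimized on the
    logit scale, dispersion on the logit scale with a floor at PHI_FLOOR.
    """
    mu0 = []
    for m, n in groups:
        mu = m.sum() / n.sum()
        mu0.append(float(min(max(mu, _MU_EPS), 1 - _MU_EPS)))
    m_all = np.concatenate([g[0] for g in groups])
    n_all = np.concatenate([g[1] for g in groups])
    phi_starts = [_moment_phi(m_all, n_all), 1e-3]

    def nll(theta):
        phi = min(max(expit(theta[-1]), PHI_FLOOR), PHI_CEIL)
        total = 0.0
        for (m, n), t in zip(groups, theta[:-1]):
            mu = min(max(expit(t), _MU_EPS), 1 - _MU_EPS)
            total -= _bb_loglik(m, n, mu, phi)
        return total

    best = None
    for phi0 in phi_starts:
        x0 = [logit(mu) for mu in mu0] + [float(logit(min(max(phi0, 1e-6), 0.99)))]
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    mus = [float(min(max(expit(t), _MU_EPS), 1 - _MU_EPS)) for t in best.x[:-1]]
    phi = float(min(max(expit(best.x[-1]), PHI_FLOOR), PHI_CEIL))
    return mus, phi, -float(best.fun)


def bb_lrt(m_a: np.ndarray, n_a: np.ndarray, m_b: np.ndarray, n_b: np.ndarray,
           phi: float | None = None):
    """Beta-binomial likelihood-ratio test of equal group means.

    Returns (delta, lrt_statistic, p_value) with delta = mu_a - mu_b and
    LRT the usual 2 * (l1 - l0), clipped at zero. With ``phi=None`` the
    site's dispersion is ML-estimated from its own replicates and the
    statistic is referred to F(1, N - 2), the small-sample reference that
    keeps the standalone test calibrated. With a known/shared ``phi``
    (see :func:`estimate_common_dispersion`) only the two means are
    estimated and the chi-square(1) reference applies.
    """
    m_a = np.asarray(m_a, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    m_b = np.asarray(m_b, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if len(m_a) == 0 or len(m_b) == 0:
        raise ValueError("each group needs at least one replicate")
    if np.all(n_a + n_b == 0) or n_a.sum() + n_b.sum() == 0:
        raise ValueError("all totals zero")
    if phi is not None:
        phi = float(min(max(phi, PHI_FLOOR), PHI_CEIL))
        m_all = np.concatenate([m_a, m_b])
        n_all = np.concatenate([n_a, n_b])
        _mu0, l0 = _fit_mu_fixed_phi(m_all, n_all, phi)
        mu_a, la = _fit_mu_fixed_phi(m_a, n_a, phi)
        mu_b, lb = _fit_mu_fixed_phi(m_b, n_b, phi)
        lrt = max(0.0, 2.0 * (la + lb - l0))
        return mu_a - mu_b, lrt, float(chi2.sf(lrt, 1))
    (mu0,), phi0, l0 = _fit_bb([(np.concatenate([m_a, m_b]), np.concatenate([n_a, n_b]))])
    (mu_a, mu_b), phi1, l1 = _fit_bb([(m_a, n_a), (m_b, n_b)])
    if l1 < l0:  # alternative must nest the null; refit from the null optimum
        def nll(theta):
            phi = min(max(expit(theta[2]), PHI_FLOOR), PHI_CEIL)
            return -(_bb_loglik(m_a, n_a, min(max(expit(theta[0]), _MU_EPS), 1 - _MU_EPS), phi)
                     + _bb_loglik(m_b, n_b, min(max(expit(theta[1]), _MU_EPS), 1 - _MU_EPS), phi))
        res = minimize(nll, [logit(mu0), logit(mu0), logit(max(phi0, 1e-6))],
                       method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 600})
        if -res.fun > l1:
            l1 = -float(res.fun)
            mu_a = float(min(max(expit(res.x[0]), _MU_EPS), 1 - _MU_EPS))
            mu_b = float(min(max(expit(res.x[1]), _MU_EPS), 1 - _MU_EPS))
    lrt = max(0.0, 2.0 * (l1 - l0))
    df2 = len(m_a) + len(m_b) - 2
    if df2 <= 0:
        raise ValueError("need more than two samples in total")
    p = float(f_dist.sf(lrt, 1, df2))
    return mu_a - mu_b, lrt, p


def test_differential_methylation(site: MethylationSite, design: DesignTable,
                                  treatment: str, control: str = "AM",
                                  generation: str = "F25",
                                  phi: float | None = None) -> MethylationTestResult:
    """Per-site differential-methylation test: treatment vs control at F25.

    Founder (F0) samples are carried in the design for display but do not
    enter the contrast. Pass a shared ``phi`` (from
    :func:`estimate_common_dispersion`) for the moderated test the pipeline
    uses; with ``phi=None`` the dispersion is per-site. Returns a result
    with the q-value unset; apply :func:`adjust_fdr_bh` across sites
    afterwards.
    """
    ids_t = design.sample_ids(line=treatment, generation=generation)
    ids_c = design.sample_ids(line=control, generation=generation)
    if not ids_t or not ids_c:
        raise ValueError(f"empty group for contrast {treatment} vs {control} at {generation}")
    m_t = np.array([site.counts[s][0] for s in ids_t], dtype=float)
    n_t = np.array([site.counts[s][1] for s in ids_t], dtype=float)
    m_c = np.array([site.counts[s][0] for s in ids_c], dtype=float)
    n_c = np.array([site.counts[s][1] for s in ids_c], dtype=float)
    delta, _lrt, p = bb_lrt(m_t, n_t, m_c, n_c, phi=phi)
    return MethylationTestResult(site.site_id, float(delta), float(p))


# ---------------------------------------------------------------------------
# Multiple testing and calls
# ---------------------------------------------------------------------------

def adjust_fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant_sites(results: list[MethylationTestResult],
                           q_thresh: float = 0.05,
                           delta_thresh: float = 0.10) -> set[str]:
    """Significant iff q < q_thresh AND |delta| > delta_thresh (both strict).

    Mutates each result's ``significant`` flag and returns the significant
    site ids.
    """
    sig = set()
    for r in results:
        r.significant = bool(r.q_value < q_thresh and abs(r.delta) > delta_thresh)
        if r.significant:
            sig.add(r.site_id)
    return sig


def apply_fdr(results: list[MethylationTestResult]) -> None:
    """Fill q-values across a set of per-site results (BH)."""
    if not results:
        return
    q = adjust_fdr_bh([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)


__all__ = [
    "SampleInfo", "DesignTable", "FilterReport",
    "filter_by_coverage", "global_mean_methylation", "compare_mean_methylation",
    "conversion_efficiency", "bb_lrt", "estimate_common_dispersion",
    "test_differential_methylation",
    "adjust_fdr_bh", "apply_fdr", "call_significant_sites", "PHI_FLOOR",
]
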