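"""Synthetic experiments with known truth, emulating the study design.

The generator builds a small genome, tiles it into windows, and assigns
each window a response class: *genetic* (alleles under selection in the
stress treatments), *epigenetic* (CpG methylation shifted in affected
treatments), or *neutral*. The coupling parameter ``kappa`` is the
probability that a response window is exclusively one class, so at
``kappa = 1`` genetic and epigenetic responses occupy disjoint genomic
regions — the inverse relationship is injected structurally and any
negative association measured downstream is emergent.

What is emulated: 4 treatments x 4 replicates evolved 25 generations from
shared founders plus founder (F0) samples; pools of 30 individuals for
methylation and 50 for DNA; per-CpG coverage with mean 124x / median 77x
(gamma-Poisson, coverage correlated across samples within a site);
two-stage pool-seq sampling (chromosomes into the pool, then reads);
beta-binomial replicate overdispersion; elevated diversity (higher founder
minor-allele frequencies) in epigenetic-response windows; expression
divergence positively coupled to methylation change; low methylation in
plastically expressed genes; an unmethylated lambda spike-in.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

from .io_formats import (write_annotation, write_expression,
                         write_methylation_counts, write_pool_counts)
from .methylation_stats import DesignTable, SampleInfo
from .types import ExpressionRecord, GeneAnnotation, MethylationSite, SnpSite

TREATMENTS = ("OA", "OW", "OWA")
CONTROL = "AM"


@dataclass
class SimulationConfig:
    """Study-structure parameters; defaults follow the emulated design."""

    seed: int = 0
    n_contigs: int = 12
    contig_len: int = 15_000
    window_len: int = 1500
    n_replicates: int = 4
    n_founder_samples: int = 4
    meth_pool_individuals: int = 30
    dna_pool_individuals: int = 50
    generations: int = 25
    effective_population_size: int = 3000
    frac_genetic: float = 0.30
    frac_epigenetic: float = 0.30
    kappa: float = 1.0              # P(response window is exclusively one class)
    selection_coefficient: float = 0.10
    meth_delta_range: tuple[float, float] = (0.12, 0.30)
    meth_shift_site_frac: float = 0.35
    snp_per_window_mean: float = 70.0
    meth_per_window_mean: float = 10.0
    meth_cov_mean: float = 124.0
    meth_cov_median: float = 77.0
    snp_cov_mean: float = 60.0
    snp_cov_shape: float = 8.0
    phi: float = 0.05               # beta-binomial dispersion among replicate pools
    f25_methylation_scale: float = 0.90  # global F0 -> F25 methylation decline
    # treatment-specific probabilities that an epigenetic window responds
    epi_response_probs: dict = field(default_factory=lambda: {
        "OWA": 0.9, "OW": 0.3, "OA": 0.25})
    epi_founder_maf: tuple[float, float] = (0.30, 0.50)
    founder_maf: tuple[float, float] = (0.05, 0.50)
    expression_beta: float = 5.0    # divergence per unit max |delta meth|
    expression_sigma: float = 0.10
    expression_meth_slope: float = 6.0  # log-expression decline per unit methylation
    plastic_fraction: float = 0.30
    plastic_meth_mean: float = 0.026
    nonplastic_meth_mean: float = 0.115
    intergenic_meth_mean: float = 0.35
    de_divergence_threshold: float = 0.30
    expression_na_prob: float = 0.02
    conversion_efficiency: float = 0.984
    lambda_n_sites: int = 1000
    lambda_coverage: int = 50

    def validate(self) -> None:
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must lie in [0, 1]")
        if self.frac_genetic + self.frac_epigenetic > 1.0:
            raise ValueError("response fractions exceed 1: more response windows than windows")
        if not (0.0 <= self.conversion_efficiency <= 1.0):
            raise ValueError("conversion efficiency must lie in [0, 1]")
        if min(self.meth_cov_mean, self.snp_cov_mean) <= 0:
            raise ValueError("coverage means must be positive")
        if self.window_len <= 0 or self.contig_len <= 0 or self.n_contigs <= 0:
            raise ValueError("genome dimensions must be positive")


@dataclass
class TruthTable:
    """Ground truth emitted alongside every simulated dataset."""

    run_id: str
    window_class: dict[str, str] = field(default_factory=dict)
    window_epi_treatments: dict[str, list[str]] = field(default_factory=dict)
    genetic_windows: set[str] = field(default_factory=set)
    shifted_sites: dict[str, set[str]] = field(default_factory=dict)  # treatment -> sites
    site_true_mu: dict[str, dict[str, float]] = field(default_factory=dict)
    snp_true_freq: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_true_divergence: dict[str, float] = field(default_factory=dict)
    gene_plastic: dict[str, bool] = field(default_factory=dict)
    gene_window: dict[str, str] = field(default_factory=dict)


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    contigs: dict[str, int]
    design: DesignTable
    meth_sites: list[MethylationSite]
    snp_sites: list[SnpSite]
    pool_ids: list[str]
    genes: list[GeneAnnotation]
    expression: list[ExpressionRecord]
    lambda_counts: list[tuple[int, int]]
    truth: TruthTable

    def write(self, outdir) -> dict:
        """Write all files (Bismark coverage per sample, sync, BED, TSV,
        truth JSON) and return a manifest of what was written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}
        for sample_id in sorted(dict(self.design).keys()):
            p = outdir / f"meth_{sample_id}.cov"
            write_methylation_counts(
                [s for s in self.meth_sites if sample_id in s.counts], sample_id, p)
            files[f"methylation/{sample_id}"] = p.name
        sync = outdir / "pools.sync"
        write_pool_counts(self.snp_sites, self.pool_ids, sync)
        files["sync"] = sync.name
        bed = outdir / "genes.bed"
        write_annotation(self.genes, bed)
        files["annotation"] = bed.name
        expr = outdir / "expression.tsv"
        write_expression(self.expression, expr)
        files["expression"] = expr.name
        lam = outdir / "lambda_counts.tsv"
        with open(lam, "w") as fh:
            fh.write("meth_count\ttotal_count\n")
            for m, t in self.lambda_counts:
                fh.write(f"{m}\t{t}\n")
        files["lambda"] = lam.name
        truth_path = outdir / "truth.json"
        with open(truth_path, "w") as fh:
            td = asdict(self.truth)
            for key in ("genetic_windows",):
                td[key] = sorted(td[key])
            td["shifted_sites"] = {k: sorted(v) for k, v in td["shifted_sites"].items()}
            json.dump(td, fh, indent=1, sort_keys=True)
        files["truth"] = truth_path.name
        manifest = {"run_id": self.truth.run_id, "seed": self.config.seed,
                    "pool_ids": list(self.pool_ids),
                    "contigs": dict(self.contigs),
                    "config": asdict(self.config),
                    "files": files}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest


# ---------------------------------------------------------------------------
# Pieces
# ---------------------------------------------------------------------------

def _coverage_gamma_shape(mean: float, median: float) -> float:
    """Gamma shape whose unit-mean median equals median/mean.

    Per-site capture efficiency f ~ Gamma(k, mean 1) multiplies the mean
    coverage; solving the median of f fixes the coverage median while the
    Poisson read draw fixes the mean.
    """
    target = median / mean
    if not (0 < target < 1):
        raise ValueError("median must be below the mean for a skewed coverage model")
    return float(brentq(
        lambda k: gamma_dist.ppf(0.5, k, scale=1.0 / k) - target, 0.05, 50.0))


def wright_fisher(p0: np.ndarray, s: np.ndarray, n_generations: int,
                  ne: int, rng: np.random.Generator) -> np.ndarray:
    """Evolve allele frequencies by Wright-Fisher binomial resampling.

    ``s`` is the per-site selection coefficient favoring the alt allele
    (genic selection p' = p(1+s) / (1+ps)); 2*ne chromosomes per
    generation.
    """
    p = np.asarray(p0, dtype=float).copy()
    two_ne = 2 * ne
    for _ in range(n_generations):
        p_sel = p * (1 + s) / (1 + p * s)
        p = rng.binomial(two_ne, p_sel) / two_ne
    return p


def shifted_mean(mu: float, delta: float, up: bool) -> float:
    """Shift a methylation mean by delta, flipping direction if clipping
    would eat more than a fifth of the intended shift."""
    lo, hi = 0.02, 0.98
    target = mu + delta if up else mu - delta
    if up and target > hi and (mu - delta) >= lo:
        target = mu - delta
    elif not up and target < lo and (mu + delta) <= hi:
        target = mu + delta
    return float(min(max(target, lo), hi))


def simulate_lambda_spikein(efficiency: float, n_sites: int, coverage: int,
                            rng: np.random.Generator) -> list[tuple[int, int]]:
    """Unmethylated spike-in calls: residual methylation = 1 - efficiency."""
    if not (0.0 <= efficiency <= 1.0):
        raise ValueError("efficiency must lie in [0, 1]")
    m = rng.binomial(coverage, 1.0 - efficiency, size=n_sites)
    return [(int(mi), coverage) for mi in m]


def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a complete synthetic experiment with its truth table.

    Deterministic for a fixed config (the seed lives in the config):
    independent substreams are spawned per component so adding sites to one
    stage never perturbs another.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (rng_genome, rng_wf, rng_dnapool, rng_meth, rng_expr,
     rng_lambda) = [np.random.default_rng(c) for c in ss.spawn(6)]

    run_id = f"sim-{config.seed}-{config.n_contigs}x{config.contig_len}"
    truth = TruthTable(run_id=run_id)
    contigs = {f"c{i:02d}": config.contig_len for i in range(1, config.n_contigs + 1)}
    L = config.window_len

    # --- windows and classes -------------------------------------------------
    window_ids: list[tuple[str, int, int, int]] = []  # (chrom, k, start, end)
    for chrom, length in contigs.items():
        for k in range((length + L - 1) // L):
            window_ids.append((chrom, k, k * L, min((k + 1) * L, length)))
    epi_windows: dict[str, list[str]] = {}   # window_id -> affected treatments
    for chrom, k, start, end in window_ids:
        wid = f"{chrom}:{start}-{end}"
        u = rng_genome.uniform()
        if u < config.frac_genetic:
            cls = "genetic"
        elif u < config.frac_genetic + config.frac_epigenetic:
            cls = "epigenetic"
        else:
            cls = "neutral"
        truth.window_class[wid] = cls
        has_genetic = cls == "genetic"
        has_epi = cls == "epigenetic"
        if has_epi and rng_genome.uniform() > config.kappa:
            has_genetic = True  # dual-response window at kappa < 1
        if has_genetic:
            truth.genetic_windows.add(wid)
        if has_epi:
            affected = [t for t in TREATMENTS
                        if rng_genome.uniform() < config.epi_response_probs.get(t, 0.3)]
            if not affected:
                affected = ["OWA"]
            epi_windows[wid] = affected
            truth.window_epi_treatments[wid] = affected

    # --- SNPs: placement, founder frequencies, Wright-Fisher ----------------
    snp_meta = []  # (snp_id, chrom, pos, wid, p0, selected)
    for chrom, k, start, end in window_ids:
        wid = f"{chrom}:{start}-{end}"
        n_snp = rng_genome.poisson(config.snp_per_window_mean)
        n_snp = min(n_snp, end - start)
        if n_snp == 0:
            continue
        pos = np.sort(rng_genome.choice(np.arange(start, end), size=n_snp, replace=False))
        is_epi = wid in epi_windows
        for p in pos:
            p0 = (rng_genome.uniform(*config.epi_founder_maf) if is_epi
                  else rng_genome.uniform(*config.founder_maf))
            snp_meta.append((f"{chrom}:{int(p)}", chrom, int(p), wid, p0,
                             wid in truth.genetic_windows))
    p0_arr = np.array([m[4] for m in snp_meta])
    sel_mask = np.array([m[5] for m in snp_meta])

    pool_ids: list[str] = []
    pool_freqs: dict[str, np.ndarray] = {}
    for rep in range(1, config.n_founder_samples + 1):
        pid = f"F0_r{rep}"
        pool_ids.append(pid)
        pool_freqs[pid] = p0_arr  # founders: no drift yet
    for line in (CONTROL,) + TREATMENTS:
        s_vec = np.where(sel_mask & (line != CONTROL), config.selection_coefficient, 0.0)
        for rep in range(1, config.n_replicates + 1):
            pid = f"{line}_r{rep}"
            pool_ids.append(pid)
            pool_freqs[pid] = wright_fisher(p0_arr, s_vec, config.generations,
                                            config.effective_population_size, rng_wf)

    # --- pool-seq read counts (two-stage sampling, vectorized per pool) ------
    n_chrom = 2 * config.dna_pool_individuals
    n_sites = len(snp_meta)
    nb_p = config.snp_cov_shape / (config.snp_cov_shape + config.snp_cov_mean)
    pool_reads: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pid in pool_ids:
        g = rng_dnapool.binomial(n_chrom, pool_freqs[pid])
        r = np.maximum(2, rng_dnapool.negative_binomial(config.snp_cov_shape, nb_p,
                                                        size=n_sites))
        y = rng_dnapool.binomial(r, g / n_chrom)
        pool_reads[pid] = (y, r)
    snp_sites: list[SnpSite] = []
    for i, (snp_id, chrom, pos, wid, p0, _sel) in enumerate(snp_meta):
        counts = {pid: (int(pool_reads[pid][0][i]), int(pool_reads[pid][1][i]))
                  for pid in pool_ids}
        truth.snp_true_freq[snp_id] = {pid: float(pool_freqs[pid][i])
                                       for pid in pool_ids}
        snp_sites.append(SnpSite(snp_id, chrom, pos, counts, n_chrom, "A", "T"))

    # --- genes, plasticity, CpG baselines ------------------------------------
    genes: list[GeneAnnotation] = []
    gene_of_window: dict[str, GeneAnnotation] = {}
    for chrom, k, start, end in window_ids:
        if end - start < L:
            continue  # no gene on the trailing stub
        wid = f"{chrom}:{start}-{end}"
        gid = f"g_{chrom}_{k}"
        gs, ge = start + 150, start + 1350
        gene = GeneAnnotation(gid, chrom, gs, ge, "+",
                              exons=[(gs, gs + 500), (gs + 600, ge)])
        genes.append(gene)
        gene_of_window[wid] = gene
        truth.gene_plastic[gid] = bool(rng_expr.uniform() < config.plastic_fraction)
        truth.gene_window[gid] = wid

    design_samples: dict[str, SampleInfo] = {}
    for rep in range(1, config.n_founder_samples + 1):
        design_samples[f"F0_r{rep}"] = SampleInfo(CONTROL, "F0", rep)
    for line in (CONTROL,) + TREATMENTS:
        for rep in range(1, config.n_replicates + 1):
            design_samples[f"{line}_r{rep}"] = SampleInfo(line, "F25", rep)
    design = DesignTable(design_samples)

    cov_shape = _coverage_gamma_shape(config.meth_cov_mean, config.meth_cov_median)
    conc_genic, conc_inter = 12.0, 4.0
    meth_sites: list[MethylationSite] = []
    truth.shifted_sites = {t: set() for t in TREATMENTS}
    phi = config.phi
    bb_conc = (1.0 - phi) / phi
    for chrom, k, start, end in window_ids:
        wid = f"{chrom}:{start}-{end}"
        n_cpg = rng_meth.poisson(config.meth_per_window_mean)
        n_cpg = min(n_cpg, end - start)
        if n_cpg == 0:
            continue
        pos = np.sort(rng_meth.choice(np.arange(start, end), size=n_cpg, replace=False))
        gene = gene_of_window.get(wid)
        affected = epi_windows.get(wid, [])
        # the shift magnitude is regional: one draw per window, shared by its
        # shifted sites (direction stays per-site)
        window_delta = float(rng_meth.uniform(*config.meth_delta_range))
        for p in pos:
            site_id = f"{chrom}:{int(p)}"
            genic = gene is not None and gene.start <= p < gene.end
            if genic:
                mean0 = (config.plastic_meth_mean if truth.gene_plastic[gene.gene_id]
                         else config.nonplastic_meth_mean)
                a, b = _beta_params(mean0, conc_genic)
            else:
                a, b = _beta_params(config.intergenic_meth_mean, conc_inter)
            mu0 = float(np.clip(rng_meth.beta(a, b), 0.02, 0.98))
            mu25 = float(np.clip(mu0 * config.f25_methylation_scale, 0.02, 0.98))
            mus = {"F0": mu0, CONTROL: mu25}
            shift_here = affected and rng_meth.uniform() < config.meth_shift_site_frac
            delta = window_delta
            up = bool(rng_meth.uniform() < 0.5)
            for t in TREATMENTS:
                if shift_here and t in affected:
                    mus[t] = shifted_mean(mu25, delta, up)
                    truth.shifted_sites[t].add(site_id)
                else:
                    mus[t] = mu25
            truth.site_true_mu[site_id] = dict(mus)
            f = rng_meth.gamma(cov_shape, 1.0 / cov_shape)
            site = MethylationSite(site_id, chrom, int(p), {})
            for sample_id, info in design_samples.items():
                mu = mus["F0"] if info.generation == "F0" else mus[info.line]
                n_reads = max(1, int(rng_meth.poisson(f * config.meth_cov_mean)))
                p_rep = rng_meth.beta(mu * bb_conc, (1.0 - mu) * bb_conc)
                m = int(rng_meth.binomial(n_reads, p_rep))
                site.counts[sample_id] = (m, n_reads)
            meth_sites.append(site)

    # --- expression ----------------------------------------------------------
    expression: list[ExpressionRecord] = []
    for gene in genes:
        gid = gene.gene_id
        wid = truth.gene_window[gid]
        member = [truth.site_true_mu[s.site_id] for s in meth_sites
                  if s.chrom == gene.chrom and gene.start <= s.pos < gene.end]
        max_delta = 0.0
        mean_meth = 0.0
        if member:
            max_delta = max(abs(m["OWA"] - m[CONTROL]) for m in member)
            mean_meth = float(np.mean([m["OWA"] for m in member]))
        divergence = max(0.0, config.expression_beta * max_delta
                         + rng_expr.normal(0.0, config.expression_sigma))
        truth.gene_true_divergence[gid] = divergence
        sign = 1.0 if rng_expr.uniform() < 0.5 else -1.0
        mean_expr = float(np.exp(rng_expr.normal(
            5.0 - config.expression_meth_slope * mean_meth, 0.4)))
        if divergence > config.de_divergence_threshold:
            adj_home = float(rng_expr.uniform(1e-6, 0.04))
        else:
            adj_home = float(rng_expr.uniform(0.06, 1.0))
        plastic = truth.gene_plastic[gid]
        recs = [("OWA_vs_AM", sign * divergence, adj_home)]
        for contrast, is_plastic in (("OWA_to_AM", plastic),
                                     ("AM_to_OWA", plastic if rng_expr.uniform() < 0.8
                                      else not plastic)):
            lfc = float(rng_expr.normal(0.0, 1.5)) if is_plastic else float(
                rng_expr.normal(0.0, 0.2))
            adj = (float(rng_expr.uniform(1e-4, 0.04)) if is_plastic
                   else float(rng_expr.uniform(0.1, 1.0)))
            recs.append((contrast, lfc, adj))
        for contrast, lfc, adj in recs:
            if rng_expr.uniform() < config.expression_na_prob:
                adj = None
            expression.append(ExpressionRecord(gid, contrast, lfc, adj, mean_expr))

    lambda_counts = simulate_lambda_spikein(
        config.conversion_efficiency, config.lambda_n_sites,
        config.lambda_coverage, rng_lambda)

    return SimulatedExperiment(
        config=config, contigs=contigs, design=design, meth_sites=meth_sites,
        snp_sites=snp_sites, pool_ids=pool_ids, genes=genes,
        expression=expression, lambda_counts=lambda_counts, truth=truth)


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    run_id: str
    dm_sensitivity: dict[str, float]
    dm_fdr: dict[str, float]
    window_label_sensitivity: dict[str, float]
    window_label_specificity: dict[str, float]
    observed_diff: dict[str, float]
    observed_diff_positive: dict[str, bool]
    regression_slope: float | None
    regression_rho: float | None
    ks_direction_nonplastic_higher: bool | None


def evaluate_recovery(run_id: str, truth: TruthTable,
                      sig_sites: dict[str, set[str]],
                      windows=None, perm_results=None,
                      regression=None, ks_result=None) -> RecoveryReport:
    """Compare pipeline outputs against the generating truth.

    ``sig_sites`` maps treatment -> called site ids; ``windows`` (with
    sig_meth flags filled) yields window-label sensitivity/specificity
    against the epigenetic-response truth; ``perm_results`` maps treatment
    -> PermutationResult. Raises if the truth belongs to a different run.
    """
    if run_id != truth.run_id:
        raise ValueError(f"run id mismatch: outputs {run_id!r} vs truth {truth.run_id!r}")
    dm_sens, dm_fdr = {}, {}
    for t, called in sig_sites.items():
        true_set = truth.shifted_sites.get(t, set())
        dm_sens[t] = (len(called & true_set) / len(true_set)) if true_set else float("nan")
        dm_fdr[t] = (len(called - true_set) / len(called)) if called else 0.0
    w_sens, w_spec = {}, {}
    if windows is not None:
        for t in truth.shifted_sites:
            true_pos = {w.window_id for w in windows
                        if t in truth.window_epi_treatments.get(w.window_id, [])}
            true_neg = {w.window_id for w in windows} - true_pos
            called_pos = {w.window_id for w in windows if w.sig_meth.get(t)}
            w_sens[t] = (len(called_pos & true_pos) / len(true_pos)
                         if true_pos else float("nan"))
            w_spec[t] = (len(true_neg - called_pos) / len(true_neg)
                         if true_neg else float("nan"))
    obs = {t: r.observed_diff for t, r in (perm_results or {}).items()}
    return RecoveryReport(
        run_id=run_id, dm_sensitivity=dm_sens, dm_fdr=dm_fdr,
        window_label_sensitivity=w_sens, window_label_specificity=w_spec,
        observed_diff=obs,
        observed_diff_positive={t: v > 0 for t, v in obs.items()},
        regression_slope=None if regression is None else regression.slope,
        regression_rho=None if regression is None else regression.spearman_rho,
        ks_direction_nonplastic_higher=(
            None if ks_result is None else ks_result.mean_false > ks_result.mean_true))


__all__ = [
    "TREATMENTS", "CONTROL", "SimulationConfig", "TruthTable",
    "SimulatedExperiment", "simulate_experiment", "simulate_lambda_spikein",
    "wright_fisher", "shifted_mean", "evaluate_recovery", "RecoveryReport",
]
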