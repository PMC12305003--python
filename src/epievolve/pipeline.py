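"""End-to-end orchestration: filter -> DM test -> F_ST/pi -> windows ->
permutation tests -> pi bins -> expression linkage, with a deterministic
manifest.

The pipeline can run from files (via :mod:`epievolve.io_formats`) or
directly from an in-memory :class:`~epievolve.synthetic_data.SimulatedExperiment`.
A single seed is expanded into independent per-stage substreams so adding
a stage never perturbs earlier stages' randomness.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression_link as el
from . import io_formats as io
from . import methylation_stats as ms
from . import omics_integration as oi
from . import popgen_stats as pg
from .synthetic_data import CONTROL, TREATMENTS, SimulatedExperiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds in one place; defaults are the analysis defaults."""

    min_coverage: int = 15
    max_coverage_quantile: float = 0.975
    q_threshold: float = 0.05
    delta_threshold: float = 0.10
    window_len: int = 1500
    min_snps: int = 5
    min_meth: int = 5
    n_permutations: int = 10_000
    pi_window_len: int = 100
    pi_bins: tuple = oi.DEFAULT_PI_BINS
    alpha: float = 0.05
    min_gene_sites: int = 5
    seed: int = 0
    treatments: tuple = TREATMENTS
    control: str = CONTROL
    replicate_mode: str = "pooled"

    def validate(self) -> None:
        if self.min_coverage <= 0 or self.window_len <= 0 or self.n_permutations < 1:
            raise ValueError("thresholds must be positive")
        edges = list(self.pi_bins)
        if any(not (x < y) for x, y in zip(edges, edges[1:])):
            raise ValueError("pi bin edges must be strictly increasing")


@dataclass
class PipelineResult:
    run_id: str
    filter_report: ms.FilterReport
    dm_results: dict[str, list]                 # treatment -> MethylationTestResult
    sig_sites: dict[str, set[str]]
    overlap: dict
    windows: list
    window_report: oi.WindowReport
    perm_results: dict[str, object]             # treatment -> PermutationResult
    pi_ks: dict[str, object]                    # treatment -> KsResult
    pi_bin_tests: dict[str, dict]
    gene_records: list
    regression: object | None
    plasticity_ks: object | None
    expression_level: object | None
    conversion_efficiency: float | None
    manifest: dict = field(default_factory=dict)


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def load_experiment(indir) -> SimulatedExperiment:
    """Load a written experiment bundle (manifest + files) back into memory.

    The design is reconstructed from the sample naming convention
    (``LINE_rN`` at F25, ``F0_rN`` founders). Raises FileNotFoundError
    naming any missing input.
    """
    from dataclasses import fields as dc_fields

    from .synthetic_data import (SimulationConfig, SimulatedExperiment as SE,
                                 TruthTable)

    indir = Path(indir)
    man_path = indir / "manifest.json"
    if not man_path.exists():
        raise FileNotFoundError(f"manifest not found: {man_path}")
    manifest = json.loads(man_path.read_text())
    raw_cfg = manifest.get("config", {})
    known = {f.name for f in dc_fields(SimulationConfig)}
    cfg = SimulationConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                              for k, v in raw_cfg.items() if k in known})
    contigs = {k: int(v) for k, v in manifest["contigs"].items()}
    pool_ids = list(manifest["pool_ids"])
    per_sample: dict[str, list] = {}
    for key, fname in manifest["files"].items():
        if not key.startswith("methylation/"):
            continue
        sample_id = key.split("/", 1)[1]
        path = indir / fname
        if not path.exists():
            raise FileNotFoundError(f"methylation counts not found: {path}")
        per_sample[sample_id] = io.read_methylation_counts(path, sample_id)
    meth_sites = io.merge_methylation_samples(per_sample)
    design_samples = {}
    for sid in per_sample:
        line_part, rep_part = sid.rsplit("_r", 1)
        if line_part == "F0":
            design_samples[sid] = ms.SampleInfo(CONTROL, "F0", int(rep_part))
        else:
            design_samples[sid] = ms.SampleInfo(line_part, "F25", int(rep_part))
    design = ms.DesignTable(design_samples)

    def _required(key, label):
        fname = manifest["files"].get(key)
        path = indir / fname if fname else None
        if path is None or not path.exists():
            raise FileNotFoundError(f"{label} not found: {path or key!r}")
        return path

    snp_sites, _rep = io.read_pool_counts(_required("sync", "pool count table"),
                                          pool_ids)
    for s in snp_sites:
        s.pool_haploid_size = 2 * cfg.dna_pool_individuals
    genes = io.read_annotation(_required("annotation", "gene annotation"))
    expression = io.read_expression(_required("expression", "expression table"))
    lam_path = _required("lambda", "lambda spike-in counts")
    lambda_counts = []
    with open(lam_path) as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                m, t = line.split("\t")
                lambda_counts.append((int(m), int(t)))
    truth = TruthTable(run_id=manifest["run_id"])
    truth_file = manifest["files"].get("truth")
    if truth_file and (indir / truth_file).exists():
        td = json.loads((indir / truth_file).read_text())
        truth = TruthTable(
            run_id=td["run_id"], window_class=td["window_class"],
            window_epi_treatments=td["window_epi_treatments"],
            genetic_windows=set(td["genetic_windows"]),
            shifted_sites={k: set(v) for k, v in td["shifted_sites"].items()},
            site_true_mu=td["site_true_mu"], snp_true_freq=td["snp_true_freq"],
            gene_true_divergence=td["gene_true_divergence"],
            gene_plastic=td["gene_plastic"], gene_window=td["gene_window"])
    return SE(config=cfg, contigs=contigs, design=design, meth_sites=meth_sites,
              snp_sites=snp_sites, pool_ids=pool_ids, genes=genes,
              expression=expression, lambda_counts=lambda_counts, truth=truth)


def run_pipeline(experiment: SimulatedExperiment,
                 config: PipelineConfig | None = None,
                 outdir=None) -> PipelineResult:
    """Run the full analysis on a (simulated or loaded) experiment.

    When ``outdir`` is given, result tables are written as TSV and a
    manifest (seed, thresholds, output checksums) as JSON; identical
    inputs and config reproduce identical bundles.
    """
    config = config or PipelineConfig()
    config.validate()
    seeds = _stage_seeds(config.seed, 8)
    design = experiment.design

    # 1. coverage filter
    filtered, freport = ms.filter_by_coverage(
        experiment.meth_sites, config.min_coverage, config.max_coverage_quantile)
    logger.info("coverage filter: %d -> %d sites", freport.n_input, freport.n_retained)

    # 2-3. differential methylation + FDR + calls, per treatment; the
    # dispersion is pooled across sites once and shared by every contrast
    phi_hat = None
    if filtered:
        phi_hat = ms.estimate_common_dispersion(filtered, design)
        logger.info("common dispersion phi = %.4g", phi_hat)
    dm_results: dict[str, list] = {}
    sig_sites: dict[str, set[str]] = {}
    for t in config.treatments:
        res = [ms.test_differential_methylation(s, design, t, config.control,
                                                phi=phi_hat)
               for s in filtered]
        ms.apply_fdr(res)
        sig_sites[t] = ms.call_significant_sites(res, config.q_threshold,
                                                 config.delta_threshold)
        dm_results[t] = res
    overlap = oi.overlap_counts(sig_sites)

    # 4. F_ST per site per (treatment, replicate), paired by replicate index
    fst_by_pair: dict[tuple[str, int], dict[str, float]] = {}
    for t in config.treatments:
        for rep in range(1, 1 + max(i.replicate for _s, i in design
                                    if i.line == t and i.generation == "F25")):
            fst_by_pair[(t, rep)] = pg.fst_all_sites(
                experiment.snp_sites, f"{t}_r{rep}", f"{config.control}_r{rep}")

    # 5. windows + membership + per-window statistics
    windows, wreport = oi.build_and_filter_windows(
        experiment.contigs, experiment.snp_sites, filtered,
        config.window_len, config.min_snps, config.min_meth)
    snp_map = {w.window_id: w.snp_ids for w in windows}
    for (t, rep), site_fst in fst_by_pair.items():
        wmean = pg.window_mean_fst(site_fst, snp_map)
        for w in windows:
            w.mean_fst[(t, rep)] = wmean[w.window_id]
    oi.flag_window_methylation_significance(windows, sig_sites)
    delta_by_site = {t: {r.site_id: abs(r.delta) for r in dm_results[t]}
                     for t in config.treatments}
    for w in windows:
        for t in config.treatments:
            vals = [delta_by_site[t][sid] for sid in w.meth_ids
                    if sid in delta_by_site[t]]
            w.mean_abs_delta_meth[t] = float(np.mean(vals)) if vals else float("nan")

    # 6. permutation tests per treatment
    perm_results = {}
    for i, t in enumerate(config.treatments):
        try:
            perm_results[t] = oi.fst_vs_methylation_test(
                windows, t, n_perm=config.n_permutations,
                seed=seeds[0] + i, replicate_mode=config.replicate_mode)
        except ValueError as exc:
            logger.warning("permutation test skipped for %s: %s", t, exc)

    # 7. pi per pool (first replicate per treatment), window means, KS + bins
    pi_small = {}
    for t in config.treatments:
        for rep in (1,):
            pid = f"{t}_r{rep}"
            pi_small[pid] = pg.pi_windows(experiment.snp_sites, experiment.contigs,
                                          pid, config.pi_window_len)
    for pid, piws in pi_small.items():
        by_key = {}
        for pw in piws:
            by_key.setdefault((pw.chrom, pw.start // config.window_len), []).append(pw.pi)
        for w in windows:
            vals = by_key.get((w.chrom, w.start // config.window_len), [])
            w.pi[pid] = float(np.mean(vals)) if vals else float("nan")
    pi_ks, pi_bin_tests = {}, {}
    for i, t in enumerate(config.treatments):
        pid = f"{t}_r1"
        try:
            pi_ks[t] = oi.ks_compare_pi(windows, t, pid, n_tests=len(config.treatments))
        except ValueError as exc:
            logger.warning("pi KS skipped for %s: %s", t, exc)
        pi_bin_tests[t] = oi.pi_stratified_fst(
            windows, t, pid, bins=config.pi_bins,
            n_perm=config.n_permutations, seed=seeds[1] + i,
            replicate_mode=config.replicate_mode)

    # 8. expression linkage (focal treatment OWA vs control)
    focal = "OWA" if "OWA" in config.treatments else config.treatments[0]
    test_map = {r.site_id: r for r in dm_results[focal]}
    line_samples = {line: design.sample_ids(line=line, generation="F25")
                    for line in (focal, config.control)}
    gene_records = el.summarize_gene_methylation(
        experiment.genes, filtered, test_map, line_samples, scope="gene")
    home = {r.gene_id: r for r in experiment.expression
            if r.contrast == f"{focal}_vs_{config.control}"}
    for g in gene_records:
        if g.gene_id in home:
            g.expression_divergence = abs(home[g.gene_id].log2fc)
            g.mean_expression = home[g.gene_id].mean_expression
    cohort = [g for g in el.regression_cohort(gene_records, config.min_gene_sites)
              if np.isfinite(g.expression_divergence)]
    regression = None
    if len(cohort) >= 3:
        try:
            regression = el.regress_methylation_expression(
                [g.max_abs_delta_meth for g in cohort],
                [g.expression_divergence for g in cohort])
        except ValueError as exc:
            logger.warning("regression skipped: %s", exc)
    plastic_labels, _n_na = el.classify_plastic_genes(
        experiment.expression, f"{focal}_to_{config.control}", config.alpha)
    plasticity_ks = None
    try:
        plasticity_ks = el.compare_methylation_by_plasticity(
            gene_records, plastic_labels, line=focal)
    except ValueError as exc:
        logger.warning("plasticity comparison skipped: %s", exc)
    expression_level = None
    with_expr = [g for g in gene_records
                 if np.isfinite(g.mean_expression) and focal in g.mean_methylation]
    if len(with_expr) >= 3:
        try:
            expression_level = el.correlate_expression_level_methylation(
                [g.mean_expression for g in with_expr],
                [g.mean_methylation[focal] for g in with_expr])
        except ValueError as exc:
            logger.warning("expression-level correlation skipped: %s", exc)

    conv = None
    if experiment.lambda_counts:
        conv = ms.conversion_efficiency(experiment.lambda_counts)

    result = PipelineResult(
        run_id=experiment.truth.run_id, filter_report=freport,
        dm_results=dm_results, sig_sites=sig_sites, overlap=overlap,
        windows=windows, window_report=wreport, perm_results=perm_results,
        pi_ks=pi_ks, pi_bin_tests=pi_bin_tests, gene_records=gene_records,
        regression=regression, plasticity_ks=plasticity_ks,
        expression_level=expression_level, conversion_efficiency=conv)
    if outdir is not None:
        result.manifest = _write_bundle(result, config, Path(outdir))
    return result


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _write_bundle(result: PipelineResult, config: PipelineConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    dm_rows = [{"treatment": t, "site_id": r.site_id, "delta": r.delta,
                "p_value": r.p_value, "q_value": r.q_value,
                "significant": r.significant}
               for t, res in result.dm_results.items() for r in res]
    io.write_tsv(pd.DataFrame(dm_rows).sort_values(["treatment", "site_id"]),
                 outdir / "differential_methylation.tsv")
    files.append("differential_methylation.tsv")
    win_rows = []
    for w in result.windows:
        row = {"window_id": w.window_id, "chrom": w.chrom, "start": w.start,
               "end": w.end, "n_snps": len(w.snp_ids), "n_meth": len(w.meth_ids)}
        for t in config.treatments:
            row[f"sig_meth_{t}"] = w.sig_meth.get(t)
            reps = [v for (tt, _r), v in w.mean_fst.items() if tt == t]
            row[f"mean_fst_{t}"] = float(np.nanmean(reps)) if reps else float("nan")
        win_rows.append(row)
    io.write_tsv(pd.DataFrame(win_rows).sort_values("window_id"),
                 outdir / "windows.tsv")
    files.append("windows.tsv")
    perm_rows = [{"treatment": t, "observed_diff": r.observed_diff,
                  "n_perm": r.n_perm, "n_ge": r.n_ge, "p_value": r.p_value,
                  "seed": r.seed}
                 for t, r in result.perm_results.items()]
    io.write_tsv(pd.DataFrame(perm_rows), outdir / "permutation_tests.tsv")
    files.append("permutation_tests.tsv")
    manifest = {
        "run_id": result.run_id,
        "seed": config.seed,
        "thresholds": {
            "min_coverage": config.min_coverage,
            "max_coverage_quantile": config.max_coverage_quantile,
            "q_threshold": config.q_threshold,
            "delta_threshold": config.delta_threshold,
            "window_len": config.window_len,
            "min_snps": config.min_snps,
            "min_meth": config.min_meth,
            "n_permutations": config.n_permutations,
        },
        "outputs": {f: _checksum(outdir / f) for f in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]
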