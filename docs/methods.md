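# Methods

`epievolve` implements an integrated analysis of replicated
experimental-evolution lines of a marine copepod: reduced-representation
bisulfite sequencing (RRBS) of pooled samples for DNA methylation,
pool-seq allele counts for genetic differentiation and diversity, and
gene-level differential-expression summaries from a reciprocal transplant.
The scientific question the pipeline addresses is whether genetic and
epigenetic responses to selection occupy the same or different regions of
the genome, and whether epigenetic change is linked to expression change.

## Differential methylation

Each CpG site carries methylated/total read counts for every sample
(pools of 30 individuals; 4 treatments x 4 replicates at generation F25
plus founder samples). Counts are modeled as beta-binomial: given a group
mean `mu_g` and dispersion `phi` (correlation parameterization,
`alpha + beta = (1 - phi)/phi`), replicate pool proportions scatter
around `mu_g` with variance `mu(1-mu)(phi + (1-phi)/n)` at coverage `n`.

Two inference paths are provided:

* **Pooled-dispersion test (pipeline default).** One dispersion is
  estimated for the whole site set by maximizing a Cox–Reid adjusted
  profile likelihood: every (site, replicate-group) block contributes its
  likelihood at the block's count-weighted mean, minus half the log
  Fisher information of that mean. The adjustment matters: the unadjusted
  profile estimate is biased low by roughly (r−1)/r with r replicates per
  block, which in turn inflates the type-I error of downstream tests.
  Each site is then tested by a likelihood-ratio statistic with the
  dispersion fixed, referred to chi-square(1). Sharing the dispersion
  across sites is the same moderation idea used by the established
  count-model toolkits for this assay and is what gives small-replicate
  designs usable power.
* **Per-site test.** Means and dispersion are ML-estimated from the
  site's own eight observations (Nelder–Mead on logit scale, dispersion
  floored at 1e-8 and capped below 1). Because three parameters come from
  eight observations, the LRT is referred to F(1, N − G) (the
  quasi-likelihood residual-df convention) rather than chi-square(1),
  which would reject at roughly twice the nominal rate. This variant is
  self-contained but cannot produce very small p-values (the F(1,6) tail
  is heavy), so it is not the default for FDR-corrected site calling.

Simulated type-I error at alpha = 0.05 under beta-binomial nulls
(phi = 0.1, coverages 15x/50x/124x) is 0.05–0.06 for the pooled test and
0.04–0.07 for the per-site test (asserted in the test suite).

Calls: Benjamini–Hochberg across sites per contrast (treatment F25 vs
ambient F25; founders are carried in the design but not contrasted), a
site is a differentially methylated locus (DML) when q < 0.05 **and**
|delta| > 0.10, both strict. Ties at either threshold are not called.

Other methylation operations: the coverage filter keeps sites with
>= 15x in every sample and no sample above the 97.5% quantile of all
site-by-sample totals (strict >; a per-site-mean variant is available);
per-sample mean methylation averages per-site proportions (a
count-pooled variant is available); bisulfite conversion efficiency is
1 − (pooled methylated fraction) on the unmethylated lambda spike-in;
group mean-methylation comparisons use one-way ANOVA plus Tukey HSD.

## Pool-seq estimators

**F_ST.** Read counts from a pool are a two-stage sample: chromosomes
into the pool, reads from chromosomes. Two distinct reads from a pool of
n haploid genomes match with probability `1/n + (1 − 1/n) Q1`, so the
read-pair matching rate, inverted, gives an unbiased within-pool
identity-in-state `Q1`; reads from different pools never share a
chromosome, so the cross-pool product estimates `Q2` directly. The
per-site estimator is `(Q1 − Q2)/(1 − Q2)` with the two pools' `Q1`
averaged. It retains negative values (unbiased null behavior; the mean
over 10,000 no-divergence sites is within ±0.005 of zero) and converges
to the Weir–Cockerham two-population estimator (haploid form) as read
depth grows, for equal pool sizes — the study design uses 50 individuals
per DNA pool throughout. A naive frequency-based (Ht − Hs)/Ht mode is
shipped as a cross-check. F_ST is computed per (treatment replicate,
ambient replicate) paired by replicate index; window values average
member sites, missing sites excluded.

**pi.** Per-site heterozygosity from `a` alternate reads of `r` total is
`2a(r − a)/(r(r − 1))`, which is unbiased under read sampling; sites with
fewer than 2 reads are excluded. Window pi sums site terms over
non-overlapping 100 bp windows and divides by window length. The
additional finite-pool correction n/(n−1) is available but off by
default, since the upstream study does not state whether it was applied;
it scales all values by ~1% and cannot change any rank-based comparison.
Trailing partial windows are kept but flagged, and excluded from per-bp
comparisons by default.

## Window integration and randomization tests

Contigs are tiled into non-overlapping windows (1.5 kb default; trailing
stub kept, flagged); SNPs and CpGs are assigned by half-open containment
(`start <= pos < end`); windows with at least 5 SNPs and 5 methylation
sites are retained. A window is methylation-significant for a treatment
if it contains at least one DML.

The core test compares mean window F_ST between windows without and with
significant methylation change: the observed statistic is
`mean(F_ST | not significant) − mean(F_ST | significant)`, labels are
reshuffled preserving class sizes (default 10,000 permutations), and the
one-sided p-value is `(n_ge + 1)/(n_perm + 1)` with ties counting toward
`n_ge` (conservative). The add-one convention guarantees p > 0 and gives
exactly 1/10,001 under complete separation. By default every
(window, replicate) point enters the statistic, matching a per-replicate
display; averaging replicates first is available as a mode. The same
machinery runs in reverse (mean |delta methylation| across windows with
versus without allele-frequency divergence — divergence labels are
consumed, not computed; the synthetic truth supplies them), within pi
bins (left-closed edges 0, 0.005, 0.01, 0.015, 0.02, 0.03, inf; a bin is
skipped when either class has < 3 windows), and across a robustness grid
of window lengths {1500, 5000} and site minima {3, 4, 5}. Window pi
distributions by methylation class are compared with two-sample KS tests,
Bonferroni-corrected by the number of treatments.

## Expression linkage

Genes (BED6/BED12; exon sub-intervals from block arithmetic) are
summarized from member CpGs by half-open containment in the gene body or,
in the exon-scope variant, in exons only. Genes overlapping several
annotations contribute to each. The regression cohort requires >= 5
methylation sites and >= 1 significant site; expression divergence is
|log2 fold change| between the combined-stressor and ambient lines in
home conditions (a signed mode exists). The cohort is analyzed by OLS
(R^2, slope p) and Spearman rank correlation (the data are not close to
normal). Plastic genes are those with adjusted p < 0.05 (strict) for the
within-line transplant contrast; genes with missing adjusted p are
excluded from both classes and counted. Gene methylation by plasticity
class is compared with a two-sample KS test plus class means ± SE, and
expression magnitude versus methylation level with Spearman correlation.

## Synthetic data generator

The generator emulates the study's structure, not its genome: windows of
a small multi-contig genome are assigned to *genetic*, *epigenetic*, or
*neutral* response classes. The coupling parameter kappa is the
probability that a response window is exclusively one class; at the
default kappa = 1 the inverse genetic/epigenetic relationship is injected
structurally (disjoint classes) and the measured negative association is
emergent, not a fitted correlation.

* Alleles: founder frequencies U(0.05, 0.5) (U(0.3, 0.5) in epigenetic
  windows, which elevates their diversity); per-replicate Wright–Fisher
  binomial resampling for 25 generations at Ne = 3000, with genic
  selection s = 0.1 on SNPs in genetic windows under the stress
  treatments. Pool counts are two-stage samples: 100 chromosomes into the
  pool, then negative-binomial read depth (mean 60x) and binomial read
  draws.
* Methylation: per-site baselines are beta-distributed with means 0.026
  (genic, plastic gene), 0.115 (genic, nonplastic), 0.35 (intergenic) —
  the genic values follow the printed plastic/nonplastic contrast.
  Epigenetic windows shift a fraction (0.35) of their CpGs by a
  *regional* magnitude drawn once per window from U(0.12, 0.30)
  (direction per site, flipped when clipping would destroy the shift);
  affected treatments are drawn per window with the combined stressor
  most likely. All F25 baselines are scaled by 0.90 to emulate the
  founder-to-F25 methylation decline. Coverage is gamma-Poisson with the
  gamma shape solved so the marginal hits mean 124x / median 77x, and the
  per-site gamma factor is shared across samples (capture efficiency is a
  site property). Counts are beta-binomial with replicate dispersion
  phi = 0.05 — pools of 30 individuals average out individual variation,
  so pool-level dispersion is set below the single-individual scale.
* Expression: gene divergence = 4–5 x (true max |delta methylation| in
  the gene) + Gaussian noise (sd 0.10), truncated at zero; adjusted
  p-values come from the truth (small when the gene is truly divergent or
  plastic); mean expression declines log-linearly with gene methylation,
  injecting the negative expression–methylation association. About 2% of
  adjusted p-values are emitted as missing to exercise the exclusion
  path.
* Lambda spike-in: methylated calls ~ Binomial(coverage, 1 − 0.984).

Deterministic for a fixed config: one seed feeds independent substreams
(genome, drift, pool sampling, methylation, expression, spike-in), so
enlarging one component does not perturb the others; identical seeds
produce byte-identical files.

**Problem sizes.** Defaults are 12 contigs x 15 kb (120 windows, ~1,250
CpGs, ~8,400 SNPs, 20 pools), and the recovery analyses in the test suite
use 20 seeds at this scale (24 contigs for the expression regression,
whose cohort grows with genome size). These are the package's desk-scale
choices: two orders of magnitude below the study (96,207 CpGs, 394,667
SNPs), which is why injected effects are set strong — selection s = 0.1
and regional shifts up to 0.30 give per-window contrasts detectable from
~100 windows, where the study's weaker genome-wide effects (window F_ST
0.006–0.012, regression R^2 0.02 at n = 197) needed thousands of loci.
Consequences worth knowing: the synthetic window F_ST contrast
(~0.17 vs ~0.003) is an order of magnitude larger than the study's, the
expression correlation (rho ~ 0.6–0.7) is far stronger than the printed
rho = 0.15, and the global F0-to-F25 methylation decline, while emulated
in direction, is not statistically detectable from ~900 sites. The
generator also concentrates CpGs in gene bodies (gene spans 80% of its
window) to give gene-level analyses usable cohort sizes, which lowers the
global mean methylation (~0.14) below the study's (~0.23–0.25).

What the generator does **not** emulate: linkage between SNPs,
recombination maps, sequence-level reads (counts only), strand structure
of CpGs, methylation inheritance mechanics (only the F25 endpoint
contrast is modeled — the data cannot distinguish transmission from
re-establishment), environment-responsive methylation within a
generation, and expression quantification noise models. Passing tests
therefore demonstrate that the estimators and tests are correct and
calibrated and that the pipeline recovers known structure from data with
this noise anatomy — not that the study's biological effect sizes would
be recovered from real RRBS at desk scale.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere; 1-based dialects
  (Bismark coverage, sync) convert on read and restore on write. Strand
  is ignored; each reported CpG is an independent locus.
* Sync biallelic reduction: the two alleles with the highest read totals
  across pools define the site (ties broken in A,T,C,G column order);
  `alt` is the overall minor one; sites with a third allele above 5% of
  reads are dropped and counted; N/deletion columns never define alleles.
* Permutation ties: `permuted >= observed` uses a relative 1e-12
  tolerance, keeping the count invariant to affine transforms of the
  values.
* Dispersion bounds [1e-8, 1 − 1e-6] avoid likelihood degeneracies at
  both ends; group means are clipped to [1e-6, 1 − 1e-6].
* Zero-coverage pools, all-missing windows, and single-class label
  vectors return missing values or raise, as documented per function;
  empty inputs produce empty outputs with zeroed reports.
* ANOVA on identical values reports p = 1 (F is 0/0; no evidence of
  group differences).

## Known limitations

* The pooled-dispersion test assumes one dispersion describes all sites;
  real RRBS shows site-to-site dispersion variation, for which a trended
  or shrunken per-site estimate would be the next step.
* The F_ST estimator averages the two pools' Q1 without weighting; for
  the equal pool sizes used throughout this is exact, for very unequal
  pools a weighted form would be preferable.
* Genome-wide (ratio-of-averages) F_ST, Tajima's D, sliding windows,
  LD-aware corrections, and DML region merging are out of scope.
* Allele-divergence window labels for the reverse analysis are inputs;
  the package does not reproduce the upstream selection scan.
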