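# Methods

## The NB location-scale model

RNA-seq counts for one gene across donors are modeled as negative binomial
with donor-specific mean and overdispersion,

    y_i ~ NB(mu_i, sigma_i),  Var(y_i) = mu_i + sigma_i * mu_i^2,

where `sigma` (= 1/theta in the size-parameter convention) is the squared
biological coefficient of variation: the component of variability left after
removing Poisson sampling noise. Both parameters are given log links,

    log mu_i    = x_i' * beta_mu + offset_i
    log sigma_i = z_i' * beta_sigma,

with the offset `log(library_size * norm_factor)` absorbing sequencing
depth. The log-likelihood per observation, with r = 1/sigma, is

    lgamma(y + r) − lgamma(r) − lgamma(y + 1)
      + r*log(r/(r + mu)) + y*log(mu/(r + mu)),

which converges to the Poisson log-pmf as sigma → 0; sigma is floored at
1e-8 and evaluated on the Poisson branch below that, because genes that look
underdispersed otherwise drive r to overflow during fitting.

**Fitting.** The joint coefficient vector is maximized by a damped Newton
method using the exact gradient and observed-information Hessian on the link
scale, with ridge escalation when the Hessian is not usable and step
halving until the log-likelihood is non-decreasing. Warm starts: Poisson
IRLS for `beta_mu` and a method-of-moments estimate for the dispersion
intercept. Convergence requires a relative log-likelihood change below 1e-8
and a maximum gradient component below 1e-5, with a 200-iteration cap;
stragglers are polished with L-BFGS and flagged `converged=False` if the
gradient still exceeds 1e-3. The whole procedure is batched across
responses (genes, permutations, simulation replicates) sharing a design, so
a genome's worth of fits or a gene's worth of permutation refits is a single
vectorized Newton solve; trigamma is computed by a shift-to-asymptotic
series (relative error < 1e-9) because that is the per-iteration hot spot.

**Testing.** Nested models are compared by chi-square likelihood-ratio
tests. Dropping the sex term from the dispersion model (or the mean model)
removes one coefficient, so both sex tests use 1 degree of freedom. A
reduced-model log-likelihood exceeding the full model's beyond tolerance is
treated as a fit failure, not clipped silently.

## SDV discovery pipeline

Order of operations within one tissue:

1. **CPM and outlier screen.** CPM uses the column total as library size.
   PCA (samples as observations, genes as centered features) runs on
   log2(CPM+1) of all genes; along every component explaining > 5% of total
   variance, samples outside the Tukey fences (1.5 IQR beyond the quartiles
   of the scores) are removed, in a single pass. The +1 pseudocount is a
   dialect choice: the screen runs before gene filtering, where zero CPM
   values still exist.
2. **Gene filter.** After outlier removal, genes with zero CPM in any
   remaining individual are dropped, so every tested gene is expressed in
   every donor.
3. **Normalization.** Upper-quartile factors: the 75th percentile of a
   sample's counts over expressed genes divided by its library size,
   rescaled to geometric mean 1; offset = log(library_size * factor).
4. **Models.** Model 1: mu and sigma each on
   sex + age + ischemic time + RIN + PC1..PC5 (continuous covariates
   z-scored for conditioning; sex coded female = 0, male = 1, so
   beta_sigma_sex > 0 means more variable in males). Model 2 drops sex from
   sigma; model 3 drops sex from mu. p_sigma,sex and p_mu,sex come from the
   two LRTs; BH correction is applied per test family over all converged
   genes.
5. **Permutation null.** Genes passing BH q_sigma,sex < 0.05 are re-fitted
   under B = 1000 permutations of the sex labels alone (all other
   covariates stay attached to their samples). The empirical p is the
   fraction of permutations with |beta_perm| strictly greater than
   |beta_obs| — denominator exactly B, no +1 smoothing, so zero p-values
   can occur and are passed to BH as-is. BH for the empirical p runs over
   the screened family (the genes that entered permutation); a gene whose
   permutation fits fail to converge in more than 20% of draws is flagged
   unreliable and excluded from calling.
6. **Call.** SDV iff BH q_sigma,sex < 0.05 and BH-adjusted empirical
   p < 0.05 and all fits converged; direction from the sign of
   beta_sigma,sex.

**Replication analysis.** Donors are split 70/30 stratified by sex. The
full procedure (both FDR gates) runs on the discovery set; a discovery call
replicates when, in the replication set, the dispersion LRT p and the
permutation p are both below 0.05 (nominal) and the more-variable sex
agrees. The null reference re-tests random draws of discovery-tested genes
of the same size as the discovery-significant set; its median exceeds the
FDR level because random draws contain true effects too.

## Power simulations

Two groups are drawn from NB distributions with common mean 1500 and
overdispersions sigma and sigma + delta; total n = 400, split 200/200 or
320/80. Fligner–Killeen and Levene (mean-centered by default; a
median-centering flag gives Brown–Forsythe) are applied to ln(counts+1), the
NB LRT (sigma ~ group, mu ~ group vs constant sigma, df = 1) to raw counts.
The baseline grid sigma ∈ {0.05, 0.1, 0.2, 0.4} with delta ∈
{0, 0.25, 0.5, 1}·sigma spans dispersions typical of bulk tissue; power/FPR
is the fraction of 1,000 replicates below alpha = 0.05, with binomial Monte
Carlo standard errors reported per cell.

## Enrichment meta-analysis and eGene depletion

Per-tissue overrepresentation of a gene set for one variability label uses
the upper-tail hypergeometric probability P(X ≥ overlap) (observed value
included). Tissue p-values are combined with T = −2 Σ ln p, but the
chi-square reference for T assumes continuous uniform p-values, which
discrete hypergeometric tests violate; the null for T is therefore built by
permuting gene labels independently within each tissue (10,000 rounds by
default) and recomputing every per-tissue p. The empirical p is the
fraction of permuted T at least as large as observed; per-tissue p-values
are floored at the smallest positive double before the log. Tissues enter
only with at least 20 genes carrying the target label; highly
tissue-specific sets can be excluded by name via a config list.

eGene depletion uses the same within-tissue label permutation: per tissue a
2×2 SDV × eGene table, fold enrichment = observed overlap / (expected under
independence), a two-sided Fisher exact test (BH across tissues), and a
one-sided test of the cross-tissue **median** fold — the empirical p is the
fraction of permutation rounds whose median fold is ≤ the observed one.
Tissues need ≥ 20 SDV genes in the shared universe.

Group comparisons of continuous scores (e.g. τ of SDV vs non-SDV genes) use
the two-sided Mann–Whitney U test with tie correction.

## Cell-type specificity

Raw single-cell counts are summed within each cell-type label; each
pseudo-bulk vector is scaled to CPM and log2(CPM+1) transformed (the
pseudocount keeps zero-CPM genes defined; genes with all-zero profiles get a
missing τ). For per-type expression x,
τ = Σ(1 − x/max(x)) / (len(x) − 1) ∈ [0, 1]; 0 means uniform, 1 exclusive.

## Evolution simulator

A population of exactly 500 diploid individuals with non-overlapping
generations. Three unlinked additive loci: one shared between the sexes and
one expressed only in each sex (the opposite-sex locus is carried and
transmitted silently). Phenotype P = sum of the two allelic effects at the
shared locus + at the own-sex locus + E, with E ~ N(0,1) drawn fresh for
each newborn. Fitness w = exp(−s·P²) acts on viability only, with
s = 0.005/0.005 (equal condition) or 0.005 male / 0.05 female
(sex-specific condition). Each generation: Bernoulli(w) survival (redrawn,
up to 100 times, if a sex has no survivors — selection is soft at the
demographic level); 100 fathers and 100 mothers sampled uniformly with
replacement from survivors; each pair produces 5 offspring, each inheriting
one uniformly chosen allele per parent per locus (free recombination);
offspring sex is Bernoulli(1/2); mutation then adds a standard-normal
increment to one uniformly chosen allele per locus with probability 5e-3
per individual × locus. Allelic effects are initialized standard normal;
the initial sex ratio is exactly 1:1.

Recorded every 10 generations: phenotypic variance among males and among
females and the variance of the 1,000 shared-locus allelic effects (an
individual-sum variant is a flag-level alternative; both behave the same
qualitatively). **Equilibrium values are reported as per-replicate time
averages over the last 20% of recorded generations**: the single-generation
variance of 500 phenotypes is noisy enough that a final-snapshot comparison
misorders the sexes in ~20–25% of replicates even when the equilibrium
variances are clearly separated, and the analysis targets the equilibrium
level, not one draw of it.

## Synthetic data generator

`generate_study` emulates one GTEx-like tissue: per-gene baseline log-means
uniform on [log 500, log 5000] and baseline overdispersions uniform on
[0.05, 0.2] (the count and dispersion scale of well-expressed genes in bulk
tissue, matching the simulation mean of 1500); log-uniform library sizes
(5–20 million) entering the mean as a true offset; age uniform on [20, 70]
and the remaining covariates standard normal, each with small N(0, 0.05)
effects on log-mean so covariate adjustment is genuinely exercised; sex
assignment fixed by the configured group counts. A configured fraction of
genes (default 10%) receives ±1.5 on log-overdispersion in males (sign
random), an independent fraction ±0.5 on log-mean, and 2% of samples are
global expression outliers, realized as gene-specific log-mean
perturbations (sd = 3) — a uniform whole-sample shift would be a pure
library-size change and would vanish under CPM normalization, leaving
nothing for the PCA screen to find.

The generator does **not** mimic tissue-sharing correlation, batch effects,
gene-length variation, or realistic covariate distributions/effect sizes —
passing tests demonstrate that the statistics behave as designed under the
assumed NB model, not that they are robust to every failure mode of real
tissue data. The baseline ranges are deliberately placed where the CPM > 0
filter retains nearly all genes; lowly expressed, zero-inflated genes are
outside the tested regime (the real pipeline simply drops them).

## Problem sizes in the shipped analyses and tests

The analysis drivers use 1,000 genes × 400 donors with B = 1000
permutations, 1,000 replicates per power-grid point, 10,000 permutations for
the meta-analyses, and the full 30 × 2,000-generation simulation. The test
suite exercises the identical code paths at reduced sizes chosen so the
whole suite completes in minutes: 20 replicate studies with B = 200 for the
end-to-end recall/FDR check, 400–500 permutations for meta-analysis
calibration, and 10 × 1,000 generations for the simulator's qualitative
properties.

## Known limitations

- The permutation empirical p uses strict ">" with denominator B (no +1
  smoothing); it can be exactly zero, which is faithful to the two-stage
  calling rule but makes single-gene empirical p-values granular at 1/B.
- BH for permutation p-values runs over the screened family only; adjusting
  over all tested genes instead is a one-line config change
  (`perm_q` recomputed over the full index) and was not the default here.
- The PCA outlier screen is single-pass; no re-screening after removal.
- Non-converged genes are reported but never called SDV; with the default
  Newton + L-BFGS fallback, non-convergence is rare (none observed in the
  shipped analyses).
- The NB LRT's chi-square reference is asymptotic; at very small group
  sizes (tens of samples) it drifts conservative/liberal depending on
  dispersion — the permutation stage exists precisely to protect the final
  calls from such miscalibration and from gene-level outliers.
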