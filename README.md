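# sdvar — sex differences in gene expression variability

Most transcriptomic comparisons between the sexes ask whether *mean*
expression differs. This package asks a complementary question: for which
genes does the *interindividual variability* of expression differ between
males and females? Such sex-differentially variable (SDV) genes are
candidates for sex-biased disease risk and for sex-specific selective
constraint, and detecting them requires statistics designed for count
dispersion, not means.

`sdvar` provides, as a tested library plus a set of analysis drivers:

- **an NB location-scale engine** (`sdvar.nb`): negative binomial regression
  with log-linear models for both the mean μ and the overdispersion σ
  (Var = μ + σμ², σ being the squared biological coefficient of variation;
  σ = 1/θ in the size-parameter convention), fitted by damped Newton
  iteration batched across genes/permutations, with nested
  likelihood-ratio tests;
- **the SDV discovery pipeline** (`sdvar.pipeline`): CPM filtering,
  PCA-based global-outlier removal, upper-quartile library-size offsets,
  per-gene dual LRTs for the sex terms
  (μ, σ ~ sex + age + ischemic time + RIN + PC1..PC5), Benjamini–Hochberg
  correction, a 1,000-permutation empirical null for the sex–dispersion
  coefficient, final SDV calls, and a discovery/replication split analysis;
- **power simulations** (`sdvar.power`) comparing the NB LRT with the
  Fligner–Killeen and Levene tests on ln(counts+1);
- **permutation-calibrated Fisher meta-analysis** of per-tissue
  hypergeometric overrepresentation and an eGene-depletion test
  (`sdvar.enrich`);
- **pseudo-bulk τ cell-type specificity** (`sdvar.tau`);
- **a forward simulator of sex-specific stabilizing selection**
  (`sdvar.evo`): a two-sex diploid population with one shared and two
  sex-specific additive loci, Gaussian viability selection
  w = exp(−s·(G+E)²), Mendelian inheritance and additive mutation;
- **synthetic data generators** (`sdvar.synth`) that emulate every input the
  analyses need — NB counts with planted SDV/SBE genes and outlier samples,
  gene sets with planted overrepresentation, eGene labels with planted
  depletion, and labeled single-cell counts — so the whole chain is testable
  without access-controlled data.

## Worked example

```python
from sdvar import synth, pipeline

study = synth.generate_study(synth.SynthConfig(seed=0))   # 1000 genes, 200/sex
res = pipeline.run_sdv(study.counts, study.sample_meta, B=1000, seed=0)
print(res[res.is_sdv].head())
```

The analysis drivers run the same steps end to end and print their findings;
on the default seeds:

```text
$ python analysis/01_simulate_study.py
wrote 1000 genes x 400 samples; 100 planted SDV genes (54 male-higher), 8 outlier samples

$ python analysis/03_sdv_discovery.py
tested 1000 genes (1000 converged); 109 SDV calls: 56 male-higher, 53 female-higher
against truth: recall 1.000, false-discovery proportion 0.083
```

The pipeline recovered all 100 planted dispersion effects (the planted
log-σ sex effect of 1.5 is large at 200 donors per sex) while 9 of 109 calls
were false — a realized false-discovery proportion consistent with the
nominal FDR of 0.05 plus permutation-resolution noise. The remaining drivers
report, for example:

```text
$ python analysis/02_power_simulations.py
unbalanced-design mean power: NB LRT 0.624 vs Fligner-Killeen 0.580 and Levene 0.618

$ python analysis/04_replication.py
discovered 111 genes; 54 replicated (rate 48.6%)
null replication rate over 2000 random gene draws: median 9.9%, max 20.7%

$ python analysis/08_evolution.py
equal selection: equilibrium var male 2.26 vs female 2.25 (sign test p = 0.58)
sex-specific selection: var male 1.85 vs female 1.35; female lower in 100% of replicates
shared-locus allelic variance: 0.248 (equal) vs 0.091 (sex-specific)
```

i.e. the NB LRT is the most powerful of the three dispersion tests
(especially for unequal group sizes), discovery calls replicate far above
the random-gene baseline, and tenfold-stronger stabilizing selection in
females produces both lower female phenotypic variance and depleted shared
genetic variance — the proposed evolutionary route to SDV expression.

A `sdv` console script exposes the same steps
(`sdv simulate-data`, `sdv run`, `sdv power`, `sdv enrich`,
`sdv egene-depletion`, `sdv tau`, `sdv evolve`); every run writes its
tables as TSV with a JSON provenance sidecar.

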