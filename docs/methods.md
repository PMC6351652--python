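# Methods

## The analysis model

The pipeline treats each subject's diagnostic record as a bag of PheWAS
codes and models the cohort with latent Dirichlet allocation: topic k is a
categorical distribution φ_k over the V retained codes, and subject i draws
each of their L_i code tokens by first drawing a topic from their mixture
θ_i, then a code from that topic. The per-subject mixtures θ — the topic
membership scores — are then used as K quantitative traits in a
single-variant association analysis: within each genotyping wave,
θ_ik is regressed on allele dosage (additive coding, 0–2 copies of the
minor allele) with the first 10 principal components as fixed covariates,
and per-wave estimates are pooled by inverse-variance-weighted
fixed-effects meta-analysis. Wave-stratified analysis absorbs batch effects
from separate genotyping/imputation runs; the fixed-effects model assumes
one common per-allele effect across waves, and Cochran's Q is reported as
a check on that assumption.

Experiment-wide significance is Bonferroni over the number of topics
(p < α/K, strict inequality; 0.05/50 = 0.001 at the defaults). Only
significant topics are examined further: each code with weight ≥ 0.01 in
the topic is tested as a presence/absence trait by logistic regression per
wave (PC-adjusted, then PC+BMI-adjusted), pooled identically on the
log-odds scale. The weight threshold comparison (≥ vs >) is configurable;
≥ is the default.

## Inference for the topic model

The sampler is collapsed Gibbs over token-level topic assignments with
symmetric priors: α on θ (default 50/K) and β on φ (default 0.1). After
`burn_in` sweeps, posterior-mean estimates

    φ_kv = (n_kv + β) / (n_k + Vβ),   θ_ik = (n_ik + α) / (n_i + Kα)

are averaged over every `thin`-th retained sweep (defaults: 500 sweeps,
200 burn-in, thinning 10). The collapsed joint log-likelihood is recorded
per sweep as a convergence diagnostic; it is monitored for an improving
trend, not asserted step-wise, since the chain is stochastic. A count of c
for a code contributes c separate tokens. Subjects with zero retained codes
get exactly the prior mean 1/K in every topic. Topic labels are arbitrary;
all comparisons against a reference model go through greedy cosine
alignment of the φ rows (`align_topics`).

Determinism: the kernel seeds its own generator, and tokens are processed
in a canonical (subject, code) sort order, so a fixed seed gives
bit-identical fits regardless of the storage order of the input matrix.
The pipeline likewise joins all inputs by subject id and sorts subjects and
codes canonically, so shuffling input file rows leaves every output
byte-identical.

## The synthetic cohort

The generator inverts the fitted model, which makes it the fair test
surface for the pipeline: data are drawn from exactly the family the model
assumes, and the generator returns the true φ, θ and planted effect for
recovery checks.

Defaults describe a four-wave cohort of 360/333/355/310 subjects (one
tenth of the study-scale waves, keeping every experiment in minutes on one
CPU) genotyped at a biallelic variant with minor allele frequency 0.079.
Genotypes are Binomial(2, MAF) hard calls — Hardy-Weinberg proportions —
with an optional Gaussian dosage-noise mode (clipped to [0, 2]) emulating
imputed fractional dosages, since real single-variant dosages may be either.
The planted effect enters the topic prior: subject i's Dirichlet
concentration is α₀ (default 0.3) for every topic except the risk topic,
which gets α₀ + δ·dosage_i. The additive-per-allele form mirrors the
additive regression downstream; because the Dirichlet mean is monotone in
its concentration, each minor allele raises the expected risk-topic share.
δ = 0 is the exact global null. The default δ = 1.0 was chosen by pilot
simulation to give essentially complete power at the default cohort size,
so recovery experiments measure pipeline correctness rather than borderline
power.

Other defaults: K_true = 20 topics over V = 200 codes with φ drawn from
Dirichlet(0.05·1_V) (well-separated, sparse topics, as empirical phecode
topics are); document lengths max(1, Poisson(30)) — a floor of one code
because enrolled biobank subjects have at least one encounter and empty
documents are uninformative for LDA; 10 independent standard-normal PCs
(no confounding by construction; stress-testing confounded PCs is out of
scope); BMI ~ Normal(27.6 + 0.3·dosage, 6.1), matching a cohort with mean
BMI 27.6 (SD 6.1) and a modest positive genotype–BMI slope so the
BMI-adjusted pass is non-trivial.

What the generator does *not* emulate: real ICD-9 ontology structure,
correlated/confounded ancestry, linkage disequilibrium, code-assignment
noise (miscoding), or longitudinal structure. Passing recovery tests
therefore demonstrates that the pipeline correctly estimates the model it
assumes — not that LDA topics faithfully summarize any particular health
system's coding behaviour.

## Numerical and design choices

- **Rollup boundary.** "Eliminate codes occurring in <0.5% of subjects" is
  read literally: prevalence is presence-based (≥1 occurrence) and codes at
  exactly the threshold are retained. Prevalence is computed on the pooled
  cohort, not per wave. Subjects left with all-zero rows are kept (their
  scores become the prior mean), since nothing requires their exclusion.
- **Regression backends.** OLS and logistic fits use statsmodels; the test
  suite verifies both against independent oracles (normal-equations OLS;
  the 2×2 cross-product odds ratio). Wald t (linear, residual df) and Wald
  z (logistic) match the conventions of standard GWAS tooling.
- **"NA" rule.** A wave is reported as `skipped_low_frequency` when the
  case count or the carrier-case cell of the 2×2 carrier-by-case table
  falls below `min_cases` (default 10); perfect separation or
  non-convergence is flagged `failed_separation`. Skipped waves are
  excluded from the pool and counted in `n_waves_used`.
- **p-value floor.** p is never reported as exactly 0; it is floored at the
  smallest positive normal double.
- **Meta-analysis.** Pooling uses only usable waves; a single usable wave
  reproduces that wave's estimate with Q = 0 on 0 df. Q is reported even
  though the primary decision rule does not use it.
- **HWE tests.** Both the exact test (conditional on allele counts, no
  mid-p; the default, as usual for QC) and the 1-df chi-square test are
  provided. The exact p moves in discrete heterozygote-count steps, so the
  two agree only to ~0.1 absolute at moderate sample sizes and the exact p
  snaps to 1 at the modal count.
- **VCF dosages.** The DS FORMAT field is preferred over GT and fractional
  values are preserved; note htslib stores FORMAT floats in 32 bits, so
  fractional dosages round-trip through VCF to ~1e-7 (hard calls and the
  TSV path are exact).
- **Recovery experiments.** Parameter-recovery runs fit with K = K_true and,
  for the topic-recovery experiment, with the fit prior α matched to the
  sparse-document regime of the corpus (α = 0.1); the default α = 50/K is a
  general-purpose smoothing choice and over-smooths corpora whose true
  document concentrations are far below 1.
- **Problem sizes.** The acceptance experiments use 1/10-scale waves
  (1358 subjects), K = 20 topics, 300 Gibbs sweeps (150 burn-in) for
  end-to-end replicates and 500 sweeps for single-fit recovery; the type-I
  calibration uses 1000 four-wave replicates of 500 subjects each. These
  sizes give stable Monte-Carlo estimates while keeping the full suite in
  a few minutes.

## Known limitations

- K is a free choice; the package deliberately ships no topic-count
  selection heuristic, exposing K in configuration instead.
- Collapsed Gibbs is exact in the limit but slower than variational
  inference for very large corpora; the implementation is a single-threaded
  numba kernel and has been sized for cohorts of order 10⁴–10⁵ tokens.
- Fixed-effects pooling assumes effect homogeneity across waves; no
  random-effects option is provided.
- The topic scores are compositional: a strong effect on one topic induces
  opposite-signed spillover associations on others. Interpretation should
  focus on the top-ranked topic, and the follow-up stage exists precisely
  to ground a topic hit in individual codes.
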