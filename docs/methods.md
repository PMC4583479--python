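# Methods

`finemapsim` evaluates how well single-causal-variant Bayesian fine-mapping
localizes causal variants in case-control GWAS, by simulating complete
studies on synthetic haplotype panels and scoring the resulting credible
sets. This note records the models, the numerical choices, and what the
synthetic data can and cannot say about real data.

## Fine-mapping model

For each variant the association evidence is summarized by the Wakefield
approximate Bayes factor computed from the meta-analysed log-odds-ratio
estimate `beta` and its squared standard error `V`:

    BF = N(beta; 0, V + W) / N(beta; 0, V)
       = sqrt(1 - r) * exp(z^2 r / 2),    r = W / (V + W),  z = beta / sqrt(V)

oriented so that larger values favor association (the reciprocal of the
null-favoring form; invert before comparing against tools using that
convention). `W` is the prior variance of the log-OR under association.
The default `W = 0.04` encodes a 95% prior belief that the odds ratio is
below 1.5 (prior SD = log(1.5)/1.96 ≈ 0.207). `W` is a single config key;
analyses preferring a flatter effect prior (e.g. `W = 0.4`) can override it.

Under a single-causal-variant assumption with prior weights `w_j`
(uniform by default), the posterior that variant `j` is causal is
`w_j BF_j / Σ_k w_k BF_k`, evaluated in log space with log-sum-exp; the
level-α credible set is the smallest descending-posterior prefix reaching
α, with ties broken by |z| then position. Variants measured in fewer than
70% of the maximum effective sample size (`n_eff = 4/(1/n_cases +
1/n_controls)` summed over contributing cohorts) are excluded from the
normalization; the rest have `V` rescaled by `n_eff/n_max` before the ABF.

## Synthetic haplotype panels

The panel generator replaces a sequenced reference panel (~200 haplotypes
per population). A 1 Mb region is split into blocks of exponentially
distributed length (mean 40 kb). Each block has K = 6 block-haplotypes with
symmetric-Dirichlet frequencies. Each panel haplotype carries one latent
uniform per block, shared between adjacent blocks with probability 0.9 and
redrawn otherwise; the block-haplotype is the inverse-CDF transform of that
uniform, so per-block marginals are exact and cross-block correlation decays
geometrically. Variant positions are uniform; folded MAFs follow a 1/p
density on [0.01, 0.5]; the alternate allele of a variant is painted onto
the clade of a random per-block genealogy whose frequency is nearest the
target, and a Poisson(0.3) number of individual haplotypes per variant have
their allele flipped ("private" carrier differences).

These choices were calibrated once against generic human-LD benchmarks
rather than any result being reproduced: a common variant should have
several strong proxies (we obtain ≈ 3-4 perfect, ≈ 2 at r² 0.9-1, ≈ 5-8 at
r² 0.5-0.9 within 1 Mb), mean r² should decay smoothly with distance, and
common variants should be imputable from a ~27% array subset with high
fidelity (median INFO ≥ 0.95, only a few percent below the 0.4 QC cut),
as dense-array imputation achieves in practice. The genealogy-clade painting
and the private-flip noise exist precisely to produce the near-perfect-proxy
stratum (r² just below 1) on which fine-mapping difficulty, r²-threshold
comparator sets, and coverage behaviour all depend; with independently drawn
allele subsets that stratum is empty and fine-mapping becomes unrealistically
easy.

A diverged population (AFR-like vs the source EUR-like) redraws each block's
haplotype frequencies from a Dirichlet with concentration `(1-F)/F` times
the source frequencies — the Balding-Nichols model, giving
`Var(p' - p) = F p(1-p)` for any clade aggregate — and subdivides blocks by
`recomb_scale` (default 2) so LD is visibly shorter. Defaults `F = 0.15`
and `recomb_scale = 2` are conventions of the right order for
European-vs-African panels; both are config keys.

## Case-control simulation

Disease risk is log-additive per allele: penetrance `f_g = f0 Π OR_i^{g_i}`
with `f0` solved by 1-d root finding so the population prevalence equals K
(default 0.55%, an ankylosing-spondylitis-like disease) under HWE at panel
frequencies. Sampling is retrospective and genotype-first: causal genotypes
are drawn from `P(g|case) ∝ P(g) f_g` (controls from `P(g)(1 - f_g)`), then
each individual is assembled from two panel-haplotype mosaics conditioned on
carrying the required causal alleles. At prevalence 0.55%, prospective
rejection sampling would need ~180 population draws per case; the
genotype-first scheme is exact under the model. Controls are unaffected
individuals, not population samples (negligible difference at this
prevalence).

Mosaic donors switch along the region as a Poisson process with the
population-scaled haplotype-copying rate `4 Ne c / H` (Ne = 11,418,
c = 1.2e-8 per bp, H = 200), about one switch per 365 kb. This keeps
simulated individuals from being panel copies while preserving local LD;
a faster switch rate measurably destroys the correlation between a variant
and its typed neighbors and makes linear imputation (below) much worse than
real imputation, which distorts every downstream comparison.

## Association and meta-analysis

Per cohort and variant: maximum-likelihood logistic regression of phenotype
on dosage (Newton-Raphson, tolerance 1e-8, ≤ 25 iterations), Wald beta/se.
Monomorphic and (quasi-)separated variants are flagged and excluded rather
than reported as numbers. Hard-call variants are fit on 2×3 sufficient
statistic tables; continuous (imputed) dosages use a compiled per-variant
Newton, with identical dosage columns (perfect proxies) fit once. Cohorts
are combined by fixed-effects inverse-variance meta-analysis with allele
alignment by EA/NEA; a variant simply omits cohorts where it is absent or
flagged. Wald (not score) statistics are used because the ABF consumes
`beta` and `V = se²`; at these sample sizes the difference is negligible.

## Imputation and QC

Untyped variants are imputed with a panel-LD linear predictor: a ridge
regression (k = 30 nearest typed variants, ridge 1e-3) of the variant's
allele on typed alleles, fit across haplotypes and applied to dosages
(haplotype coefficients transfer additively; intercept doubled). This is
the package's largest methodological simplification: it replaces
per-individual hidden-Markov haplotype imputation. Two consequences are
documented rather than hidden: (i) fitting on the raw 200-haplotype panel
overfits (k/H ≈ 15% optimism), so predictors are fit on a mosaic-augmented
panel of 1,000 haplotypes resampled from the panel with the cohort
simulator's switch process — panel information only, matched to the data
the predictor will see; (ii) even so, a linear predictor cannot localize
donor switches the way an HMM can, so imputation fidelity for low-MAF
variants remains below what HMM tools achieve, and rare causal variants are
QC-censored somewhat more often than in the reference analyses.

INFO is the dosage-variance ratio `Var(imputed dosage) / (2 p̂ (1 - p̂))`,
capped at 1 (≈1 well-imputed, ≈0 uninformative; only behaviour at the 0.4
threshold matters here). QC retains variants with INFO strictly above 0.4
and MAF at least 1%; the INFO rule applies per cohort (a failing variant
leaves that cohort, and leaves the region only when no cohort retains it);
the MAF rule applies to the meta-analysed frequency. Cohort-level genotype
failures are imputed per cohort with predictors refit without the failed
variants; failed typed predictors are mean-substituted.

## Evaluation

Per replicate: the causal rank by |z| (ties by position), set sizes and
causal membership at the 95%/99% levels, r²-threshold comparator sets
around the lead variant (r² to the lead strictly above 0.5/0.8/0.9 on the
majority-ancestry panel), and the four-way success category using the
"fewer than ten variants" criterion (strict). Replicates whose causal
variant is removed by QC are censored: counted as non-covered for coverage
(conservative) and excluded from rank statistics; both tallies are
reported. Quantiles use the nearest-rank convention. "Median coverage" is
the median over grid settings of per-setting coverage rates (the headline
convention); per-replicate aggregation is available from the same tables.

Analytic power uses the unmatched case-control allele-count z-test:
HWE genotype frequencies, penetrances from (K, OR), expected case/control
allele frequencies, two-sided alpha (default 5e-8, genome-wide) with the
standard error under the alternative and both rejection tails (so the null
model recovers exactly alpha).

## Problem sizes and reproducibility

The reference design is ten cohorts of 1,000 cases and 1,000 controls per
replicate region, RAF ∈ {5, 10, 20, 50}%, OR ∈ {1.0, 1.1, 1.2, 1.5}. The
package defaults to 1,000 replicates per setting; the shipped evaluation
scripts and tests use 16-75 replicates per setting with panels of ~600
common variants/Mb for the coverage grids and ~3,000/Mb (the full
common-variant density) for the flat-posterior, functional-prior, and
directional comparisons — coverage medians and fold changes stabilize well
below a thousand replicates. Every replicate's random stream derives from
(master seed, setting index, replicate index, redraw attempt), so runs are
bit-reproducible, resumable record by record, and scale-free in replicate
count. Regions whose constraints cannot be satisfied (no variant within
0.5 pp of the target RAF — common at RAF 50% where the 1/p spectrum is
thin — no weakly-linked multi-causal pair, or a causal variant lost to
drift in the diverged panel) are redrawn with a fresh seed before any
cohort is simulated.

## Known limitations

- The LD substrate is a block model, not a coalescent: no allele-age/
  frequency-LD coupling, no recombination hotspot map, no gene conversion
  tracts, no indels or multi-allelics. Proxy counts are calibrated to be
  plausible, but any statistic dominated by the extreme tail of real LD
  (e.g. loci like *SH2B3* with hundreds of high-r² variants) is out of
  reach; passing tests show method behaviour under human-like LD, not
  agreement with any particular locus.
- Linear-predictor imputation under-imputes low-MAF variants relative to
  HMM imputation; array-scenario results at RAF 5% are conservatively
  degraded (more censoring of the causal variant).
- Trans-ethnic benefits depend on the balance between LD-discrimination
  gains and drift-induced power loss; at reduced panel density (sparser
  proxy competition) the simulated benefit shrinks or reverses, so the
  trans-ethnic comparisons are run at full variant density.
- Single-causal posteriors only; multi-causal regions are simulated and
  scored, but joint/conditional fine-mapping is out of scope.
- No covariates, stratification confounding, or X chromosome.
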