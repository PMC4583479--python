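# finemapsim

Simulation-based evaluation of Bayesian fine-mapping for common-variant
GWAS loci.

After a genome-wide association study flags a 1 Mb region, linkage
disequilibrium (LD) usually leaves tens to hundreds of variants that could
be the causal one. A standard refinement strategy computes, for every
variant, Wakefield's approximate Bayes factor (ABF) from the association
summary statistics,

    ABF = N(β̂; 0, V + W) / N(β̂; 0, V) = √(1 − r) · exp(z²r/2),
    r = W/(V + W),  z = β̂/√V,

turns the ABFs into single-causal-variant posterior probabilities
π_j ∝ w_j·ABF_j, and reports the smallest set of variants whose cumulative
posterior reaches 95% (or 99%) — the *credible set*. How well calibrated
and how tight those sets are, under realistic study designs, is an
empirical question. This package answers it by simulation: it generates
phased haplotype panels with human-like LD, simulates case-control cohorts
under an additive disease model, runs logistic association and
fixed-effects meta-analysis, applies array-downsampling / imputation /
genotype-failure / trans-ethnic / functional-prior / multi-causal study
designs, fine-maps every replicate, and scores coverage of the causal
variant, credible-set sizes, and fine-mapping success against analytic
power. It is aimed at statistical geneticists designing or interpreting
fine-mapping studies; the fine-mapping core also runs directly on published
summary statistics.

## Worked example

Fine-map a locus from summary statistics (tab-delimited with columns
SNPID, CHR, POS, EA, NEA, EAF, BETA, SE, Z, N_EFF, N_STUDIES):

```python
import numpy as np
from finemapsim import GridConfig, run_grid

cfg = GridConfig(replicates=20, raf_levels=(0.1,), or_levels=(1.2,),
                 scenarios=("gold",), panel_density=600.0, seed=7)
summary, outcomes = run_grid(cfg)
row = summary.table[summary.table.level == 0.95].iloc[0]
print(f"coverage={row.coverage:.2f} median_size={row.median_size:.0f} "
      f"rank1={row.rank1_rate:.2f} power={row.power:.3f}")
```

prints

```
coverage=1.00 median_size=5 rank1=0.65 power=0.599
```

meaning: across 20 simulated 1 Mb regions with a causal variant of risk
allele frequency 10% and allelic odds ratio 1.2, studied in ten cohorts of
1,000 cases / 1,000 controls each, every 95% credible set contained the
causal variant (coverage 1.00), the median set held 5 variants, the causal
variant was the top association signal in 65% of replicates, and the
analytic power to detect the locus genome-wide was 59.9%.

The same machinery is exposed as a CLI:

```bash
finemapsim simulate-panel --out panel.vcf --seed 1        # phased VCF panel
finemapsim run-grid --config grid.yaml --outdir run/      # full grid, resumable
finemapsim finemap-summary --summary locus.tsv --out credible.tsv
finemapsim evaluate --records run/outcomes.jsonl --out summary.tsv
```

`finemap-summary` is the entry point for real (published) GWAS summary
statistics: it rescales variances to the maximum effective sample size,
computes ABFs and posteriors, and writes the ordered credible-set table.

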