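# indelenrich

Are insertions and deletions (indels) more likely than SNPs to be the causal
variant at trait-associated loci? `indelenrich` answers that question from
GWAS single-variant summary statistics alone. It classifies biallelic
variants from their allele strings, applies post-imputation QC, builds
nonoverlapping 1 Mbp loci around genome-wide-significant lead variants,
computes per-locus posterior probabilities of causality and 95% credible
sets under a one-causal-variant model, and estimates a per-annotation
enrichment parameter λ with a likelihood-ratio test. It is aimed at
statistical geneticists who have per-trait association results (χ² or
p-values, MAF, imputation quality) and want a summary-statistic-level answer
about a variant class — indels, missense SNPs, coding indels, or any other
binary annotation.

## Model

Each retained locus is assumed to harbour exactly one causal variant. For
variant *i* with 1-df association statistic χ²ᵢ, the evidence is the
asymptotic Bayes factor

    log BFᵢ = χ²ᵢ / 2,

and a binary annotation *aᵢ* enters through a within-locus softmax prior

    πᵢ(λ) = exp(λ·aᵢ) / Σⱼ exp(λ·aⱼ),

so e^λ is the prior odds multiplier for annotated variants and λ = 0 is the
uniform prior. Posterior probabilities of causality are πᵢ·BFᵢ normalised
within the locus; the 95% credible set is the shortest posterior-ranked
prefix reaching 0.95 mass. λ is estimated by maximising the marginal
likelihood Σ_loci log Σᵢ πᵢ(λ)·BFᵢ via EM — the M-step is a
posterior-weighted 2×2 log odds ratio of annotated vs unannotated causal
mass against background variant counts — and tested against λ = 0 with a
1-df likelihood-ratio test. A Wakefield approximate Bayes factor from
(β, SE) is available as an alternative evidence model.

## Worked example

Everything is testable without external data through the built-in
generator, which plants a known enrichment and known causal variants:

```python
from indelenrich import (SimulationConfig, simulate_variant_genome,
                         simulate_trait_associations, run_full_analysis,
                         exp_transform)

cfg = SimulationConfig(n_loci=89, lambda_true=1.0, seed=3)
genome, coding, lowc = simulate_variant_genome(cfg)
sumstats, truth = simulate_trait_associations(genome, cfg, coding)
results = run_full_analysis(sumstats, coding, lowc)

fit = results["enrichment"]["indel"]
print(f"retained loci: {results['n_loci']}")
print(f"indel enrichment: lambda = {fit.lambda_hat:.2f} "
      f"(fold = {exp_transform(fit.lambda_hat, ndigits=2)}), "
      f"LRT p = {fit.p_value:.3f}")
s = results["credible_summary"]
print(f"credible sets: {s['snps_in_sets']} SNPs + {s['indels_in_sets']} indels; "
      f"{s['loci_with_indel_top']} loci with an indel on top")
```

prints

```
retained loci: 78
indel enrichment: lambda = 0.55 (fold = 1.74), LRT p = 0.174
credible sets: 70 SNPs + 8 indels; 8 loci with an indel on top
```

78 of the 89 simulated loci have a genome-wide-significant lead
(p ≤ 5×10⁻⁸) and survive overlap resolution. The planted λ = 1 is
recovered with the right sign but wide uncertainty — with a 5.5% indel
fraction, one cohort of this size carries limited information about λ,
which is why a single nonsignificant estimate is not evidence of no
enrichment (the calibration studies below quantify this). Credible sets
are small because the causal noncentrality (40) is strong; 8 of 78 loci
rank an indel on top.

The same analysis runs from the shell:

```bash
indelenrich simulate --out sim/ --seed 3 --lambda-true 1.0
indelenrich run --sumstats sim/sumstats.tsv --coding-bed sim/coding.bed \
    --lowcomplexity-bed sim/lowcomplexity.bed --out report/
indelenrich tables --counts 792 17533 3354 304956
```

The `run` subcommand writes `loci.tsv`, `credible_sets.tsv`,
`enrichment.tsv` (one row per annotation: λ, e^λ, LRT statistic, p,
convergence and boundary flags, plus a low-complexity-excluded sensitivity
rerun) and a JSON run manifest with stage counts.

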