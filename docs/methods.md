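# Methods

## The estimation problem

Given single-variant GWAS summary statistics for one or more quantitative
traits, we ask whether variants carrying a binary annotation — indel status,
missense status, coding-indel status — are more likely to be causal at
trait-associated loci than unannotated variants. The analysis never touches
genotypes: it consumes per-variant χ² statistics (1 df), MAF and imputation
quality, plus interval files describing coding sequence and low-complexity
regions.

## Variant model and QC

Variants are biallelic SNPs and indels in VCF convention: 1-based
positions, the reference footprint of an allele pair being
`[pos, pos + len(ref) − 1]`. Classification is purely length-based: equal
single-base alleles are SNPs, longer ref is a deletion, longer alt an
insertion; equal-length multi-base substitutions are rejected because the
intended call sets contain none, and silently reinterpreting them would
corrupt class counts. Inputs are assumed normalized (left-aligned); no
realignment is attempted, and reference-list lookups are exact 4-tuple
matches with chromosome-dialect mismatches ("chr1" vs "1") treated as
errors rather than silently reconciled.

QC is the two-stage post-imputation filter used for Minimac-style dosage
data: imputation RSQR > 0.3 for variants with MAF ≥ 1% and > 0.6 below 1%,
then an analysis-set cutoff of MAF ≥ 1%. Both stages are inclusive at the
MAF boundary. The filter returns rejects with per-record reasons so stage
counts always partition the input.

## Loci

A locus is the ±500 kb window around a genome-wide-significant lead
(p ≤ 5×10⁻⁸, inclusive; p derived from χ² when absent). Construction is
greedy and deterministic: within a trait, the most significant remaining
variant absorbs all significant variants in its window; across traits,
windows are pooled, sorted by lead p, and retained only if disjoint from
every previously retained window on the same chromosome. Tie-breaks are
fixed (smaller p, larger χ², trait label, then coordinates) so results are
invariant to input row order. Windows are clamped at position 1; both
bounds are inclusive. The wide window is deliberate: it keeps every
plausible causal variant inside the credible-set computation regardless of
local LD structure, at the cost of diluting the locus with nulls.

## Fine-mapping

Exactly one causal variant per locus is assumed. Evidence is the
asymptotic Bayes factor `log BF = χ²/2`; with uniform priors the posterior
is a softmax of χ²/2, computed via log-sum-exp. This BF grows faster in |z|
than a proper point-alternative Bayes factor, making posteriors
concentrate on the top statistic; for credible-set construction from χ²
summary data this is the standard pragmatic choice, and a Wakefield
approximate BF (`wakefield_log_abf`, prior effect variance W = 0.04,
i.e. prior SD 0.2 on the standardized effect) is provided where β and SE
exist. The 95% credible set is the shortest posterior-ranked prefix
reaching 0.95; descending-order prefixes are minimum-cardinality sets, a
property the tests verify against exhaustive subset enumeration for small
loci. Posterior ties are broken by larger χ², then coordinates.

## Enrichment parameter λ

The prior odds of an annotated variant being causal are multiplied by e^λ
through a within-locus softmax prior π_i(λ) ∝ exp(λ·a_i). The marginal
log-likelihood is

    ℓ(λ) = Σ_loci log Σ_i π_i(λ)·exp(log BF_i).

Estimation is EM over the latent causal indicator. The E-step computes
posterior causal probabilities at the current λ; the M-step maximizes the
expected complete-data log-likelihood, which reduces to solving

    C₁ = Σ_L n₁L·e^λ / (n₁L·e^λ + n₀L)

for λ, where C₁ is the posterior causal mass on annotated variants and
n₁L/n₀L are each locus's annotated/unannotated counts. When all loci share
one composition the solution is in closed form the log odds ratio of the
2×2 table [annotated vs unannotated causal mass; annotated vs unannotated
background counts] — the posterior-weighted log-odds-ratio update — and
`posterior_log_odds_ratio` exposes that form. We solve the score equation
exactly (1-D bracketed root) rather than applying the closed form to
heterogeneous loci, because the exact M-step keeps the EM ascent provably
monotone; the tests assert monotone likelihood traces on every synthetic
run, and that iterating the closed form converges to the same optimum in
the equal-composition case.

Convergence is |Δλ| < 10⁻⁶ or 1000 iterations, followed by a bounded 1-D
refinement of ℓ on λ ∈ [−20, 20]; the refinement is accepted only when it
improves ℓ by more than 10⁻⁹, so flat likelihoods (annotation carrying no
information) report λ̂ = 0 rather than an arbitrary interior point. λ̂ at
±20 sets a boundary flag — sparse annotations that never coincide with the
causal signal produce large negative λ̂ with tiny likelihood gain, and the
flag surfaces these near-degenerate fits instead of hiding them. Inputs
where no locus mixes annotated and unannotated variants are unidentifiable
(every pure locus contributes a constant in λ) and return λ̂ = 0, p = 1
with `identifiable=False`.

Significance is a 1-df likelihood-ratio test of λ = 0 (two-sided in λ by
construction); a Wald standard error from the numerical observed
information is attached for diagnostics. The low-complexity sensitivity
rerun removes flagged variants from every locus and from background counts
and refits; loci emptied by the exclusion are dropped with a warning.

## Contingency tests

The 2×2 chi-square is computed from the closed form
N(|ad−bc|−c)²/(r₁r₂c₁c₂), with the Yates term c = N/2 floored so the
corrected statistic is never negative, and both conventions are always
reported because published 2×2 statistics mix them. p-values that
underflow double precision are reported as "< 1E-300" alongside log₁₀ p,
computed through the normal-tail identity sf_χ²₁(x) = 2Φ̄(√x), which stays
finite where the direct log-survival evaluation underflows. Mann-Whitney U
uses exact enumeration when both groups have ≤ 8 tie-free observations and
the tie-corrected normal approximation otherwise.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets and is
the basis of every calibration claim. Defaults, chosen once: 89 loci of 50
variants plus 5,000 background variants; indel fraction 0.055 among common
variants; 58% of indels deletions; geometric indel lengths with P(1) =
0.56 (capped at 12 bp); coding rates 0.007 (SNPs) and 0.002 (indels) with
half of coding SNPs missense; low-complexity rates 0.011 (SNPs) and 0.043
(indels); causal noncentrality 40, which makes ~80–90% of locus leads
genome-wide significant. Variants sit on 16-bp slots inside ±200 kb of
locus centres spaced 3 Mb apart, so reference footprints never collide,
interval files built from flagged footprints have exact membership truth,
and each locus fits one 1 Mb window. Locus variants are drawn QC-passing
(MAF uniform on [0.01, 0.5], RSQR uniform on [0.35, 1]), because the
emulated loci are defined on the post-QC variant set; background variants
span both QC thresholds (15% of MAFs below 1%, an RSQR mixture reaching
below 0.3) so the filters are exercised end to end.

Association statistics are simulated directly on the χ² scale: one causal
variant per locus drawn with probability ∝ exp(λ_true·a_i), causal
χ² ~ noncentral χ²₁(ncp), nulls central χ²₁, with an optional exchangeable
correlation r applied on the underlying normal scores. Effect sizes are
derived as β = z·SE with SE = 1/√(2N·MAF(1−MAF)) at N = 5,000.

What this does *not* emulate: realistic LD (exchangeable correlation does
not create proxies that tag the causal signal, so simulated fine-mapping
is easier than real fine-mapping and credible-set coverage runs near 100%
rather than near the nominal 95%), rare variants, multi-causal loci,
cross-trait sample overlap, and imputation-quality-dependent power loss
for indels. Passing calibration here shows the estimator and pipeline are
correct under their own model assumptions, not that real-data enrichment
estimates are unbiased under LD misspecification.

## Calibration results the tests compute

Under the default-style conditions (200 loci × 50 variants, annotation
frequency 0.2, ncp 30): mean λ̂ over 100 replicates is within 0.2 of
planted values 0.5 and 1.5, and the EM estimate matches a grid-search
argmax of ℓ to 0.01. Over 500 null cohorts (100 loci × 30 variants) the
LRT rejects at 5% with frequency in [0.03, 0.08]. At ncp 40 the 95%
credible set contains the planted causal variant in ≥ 90% of 1000 loci
with mean set size ≈ 1 (see the LD caveat above for why coverage exceeds
the nominal level). Problem sizes for these studies were fixed once at
values that make the Monte-Carlo error small relative to the tolerances.

## Known limitations

- The exp(χ²/2) Bayes factor is an asymptotic device, not a generative
  model; λ̂ inherits a mild dependence on the evidence model (the Wakefield
  alternative gives slightly different posteriors for low-MAF variants).
- One trait per locus: the lead trait's statistics define the locus's
  credible set; no meta-analysis or colocalization across traits.
- No LD-aware fine-mapping; with strong local correlation the one-causal
  softmax overstates certainty in the top variant.
- Boundary estimates (|λ̂| = 20) should be read as "annotation carries ~no
  causal mass", not as a finite effect size.
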