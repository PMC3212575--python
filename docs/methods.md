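# Methods

## The simulation model

Each of `n_populations` diploid populations of constant size `N`
(`n_individuals`) evolves independently under discrete, non-overlapping
generations. An individual is a pair of binary haplotypes over
`L = n_loci_selected + n_loci_neutral` markers; allele 1 at a selected locus
adds `x` (`effect_x`) to an additive, codominant trait. Writing `m` for the
individual's count of trait-increasing alleles over the selected loci
(0 ≤ m ≤ 2·n_loci_selected), viability is the Gaussian stabilizing kernel

    w(m) = exp(−(m − µ)² x² / (2 s)),

so `µ` (`optimum_mu`) is the allele count at the fitness optimum and `x²/s`
sets the strength of selection. Each offspring draws two parents with
replacement with probability ∝ w (soft selection: N is constant by
construction, which is the only reading of "viability selection at fixed
sample size" that keeps the census size exact); each parent transmits one
gamete formed by copying one of its haplotypes and switching the source
haplotype between adjacent loci with probability `recomb_rate`. There is no
mutation, migration, dominance, epistasis or environmental variance; fixed
loci therefore stay fixed, and with `effect_x = 0` the model reduces exactly
to neutral Wright–Fisher reproduction (the test suite checks the martingale
property of allele frequencies over 500 replicates).

Fitness weights are divided by their maximum before normalization: selection
depends only on relative viability, and the rescaling removes underflow when
`(m−µ)²x²/(2s)` is large.

Parameter defaults and rationale:

| parameter | default | why |
|---|---|---|
| `n_individuals` | 1,000 | drift-visible scaling of the reference setting N = 10,000; the qualitative dynamics (allele-subset splitting) are unchanged, only faster |
| `n_loci_selected`, `n_loci_neutral` | 10, 10 | the 20-marker toy-model layout |
| `effect_x`, `optimum_mu`, `strength_s` | 5, 10, 10 | reference parameterization; µ = half the selected allele copies means many distinct subsets maximize fitness |
| `init_freq` | 0.5 | all markers start at frequency 0.5; Bernoulli sampling (the expected-frequency reading), with `exact_init=True` available for exact counts |
| `n_generations` | 200 | no canonical value exists; at N≈10³ and this selection strength the selected loci resolve well before 200 generations |
| `recomb_rate` | 0.5 | no genetic map is specified; unlinked markers are the minimal assumption (selected loci occupy the first half of the vector, which only matters for linked runs) |

Randomness: one master seed; population `i` uses the substream
`default_rng([seed, i])`, so runs are bit-reproducible and populations
independent.

## The Weir–Cockerham estimator

For one biallelic SNP observed in `r` samples with sizes `n_i`, reference
allele frequencies `p_i` and observed heterozygote proportions `h_i`:

    n̄ = Σn_i/r,  n_c = (Σn_i − Σn_i²/Σn_i)/(r−1),
    p̄ = Σn_i p_i / Σn_i,  s² = Σn_i(p_i−p̄)²/((r−1)n̄),  h̄ = Σn_i h_i / Σn_i
    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
    c = h̄/2,   θ = a/(a+b+c)

Numerical and edge-case choices:

* θ is **not clipped**: negative values are legitimate small-sample outcomes
  and populate the lower tail used by the outlier trim.
* A SNP monomorphic for the same allele in every sample has a = b = c = 0 and
  θ flagged undefined (excluded downstream), never coerced to 0.
* Samples with `n_i = 0` are dropped per SNP; fewer than two remaining samples
  raises an "insufficient samples" error, and `n̄ ≤ 1` a degenerate-size error.
* Inputs are genotype counts, so `h_i` is observed heterozygosity; a
  frequency-only dialect imputes `h_i = 2p_i(1−p_i)` (Hardy–Weinberg) and tags
  the panel `mode="hwe"`. Simulator-derived panels exercise the observed-h
  path, which matters because populations under selection are not at HWE.
* Counts are floats: HWE-imputed "counts" are generally non-integral.
* The per-SNP θ is the pipeline statistic; `multilocus_fst` (ratio of
  averages Σa/Σ(a+b+c)) is a utility for estimator-recovery checks.

The vectorized panel path groups SNPs by their pattern of sampled populations
and is tested for exact (1e−12) agreement with the scalar path and with an
independently coded transcription of the equations.

## The comparison battery

Stage order: filter → per-SNP θ → full-set test → tail trim → core-set test →
LD-confound removal → post-LD test → score-tail enrichment.

* **Filtering.** A SNP is removed iff unsampled in every sample, monomorphic
  in every sampled sample, or MAF < `maf_min` (default 0.05) in **every**
  sample. The all-samples reading is the default because the source rule says
  "in all samples"; `maf_any_sample=True` gives the stricter alternative.
* **Mann–Whitney.** U counts candidate-beats-background pairs with half
  credit for ties; the alternative is one-tailed, candidates greater. The
  p-value is permutation-exact by enumeration whenever the number of
  labelings C(m+n, m) ≤ C(16, 8) = 12,870 (this covers every split with
  m + n ≤ 12 and any split with both sizes ≤ 8, and handles ties correctly,
  which closed-form exact tables do not); larger inputs use the tie-corrected
  normal approximation with continuity correction (scipy). An exhaustive test
  checks enumeration agreement for all splits with m + n ≤ 12.
* **Trimming.** Thresholds are the empirical `tail_fraction` and
  `1 − tail_fraction` quantiles of the background θ (numpy linear
  interpolation — the common default; on large backgrounds the definition
  shifts thresholds by O(1/n)). Removal is strict (`<` low, `>` high), and
  under exchangeability the removed fraction converges to 2·tail_fraction.
* **LD confounds.** A candidate is removed iff some table row links it to a
  non-height-trait variant with r² strictly > `r2_threshold` (default 0.8) in
  at least one population; r² = 0.8 exactly is kept, matching the strict
  inequality of the rule.
* **Enrichment.** Per population, the threshold is the `1 − tail_fraction`
  quantile of the background (non-candidate) scores; candidates strictly
  above count as hits, tested two-sided with an exact binomial against
  `tail_fraction`. The rule applies to the signed score (`abs_scores=True`
  switches to |score|); the consumed track is assumed already normalized.
  No multiple-testing correction is applied across the three Mann–Whitney
  stages — the battery reports each stage's p as is.
* Candidates absent from the filtered panel are logged and skipped, never
  imputed. The background for every test is the set of non-candidate SNPs
  with defined θ.

## The synthetic panel generator

Balding–Nichols: per SNP an ancestral frequency p̄ ~ Uniform(`ancestral_maf_range`,
default (0.1, 0.9)); per population p_i ~ Beta(p̄(1−F)/F, (1−p̄)(1−F)/F)
(point mass at p̄ for F = 0; F = 1 is rejected); genotypes trinomial at HWE.
The Beta's intraclass correlation equals F, giving a ground-truth F_ST for
recovery tests — that, not realism, is why the model was chosen. Candidate
SNPs are generated identically at their own `F_candidate`. Defaults — 3
populations, 90 diploids each, background F = 0.1 — mimic HapMap-era panel
sizes and inter-continental human differentiation, so estimator noise is
realistic.

What the generator deliberately does **not** emulate: chromosomal LD
structure (SNPs are independent; the LD table is a separate fixture),
SNP-array ascertainment bias, population growth or migration, and real
allele-frequency spectra. Passing tests therefore demonstrate correctness of
the estimator and the battery's statistical calibration under a clean
generating model, not agreement with any particular human dataset; real-data
runs enter through the panel TSV dialect.

Auxiliary fixtures: `synth_ld_table` gives a chosen fraction of candidates
one LD row with r² uniform in configurable bounds; `synth_scores` draws
background scores i.i.d. standard normal per population and places each
candidate in the top tail with probability `enrichment_factor ×
tail_fraction` (factor 1 = null, 0 = never, 3 ≈ 15 % expected tail mass).

## Problem sizes used by tests and the acceptance script

Estimator recovery uses 10,000 SNPs × 3 populations × 100 diploids at
F = 0.1; null calibration 300 replicates of 5,000 background + 150 candidate
SNPs; power 100 replicates at F 0.15 vs 0.09; the simulator experiment 50
replicates at N = 1,000 for 200 generations with θ estimated from 200
sampled individuals per population. These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands while keeping a full run in the
low minutes on one core.

## Known limitations

* Per-SNP θ for two or three samples is noisy; set-level comparisons, not
  individual SNP calls, are the intended use.
* The exact Mann–Whitney path enumerates labelings and is exponential; it is
  capped at 12,870 labelings by design.
* The frequency dialect assumes HWE within samples, which is wrong for
  populations under strong selection — use genotype counts there.
* No decomposition of the candidate-set θ excess into phenotypic-mean vs
  pure-genetic components is attempted; the battery measures the excess, not
  its cause.
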