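# polyfst

Population-genetic analysis of **polygenic adaptation through allele-frequency
differentiation**. When a quantitative trait is under Gaussian stabilizing
selection and many interchangeable loci can satisfy the optimum, independent
populations each commit stochastically to a different subset of trait alleles —
a symmetry-breaking dynamic that inflates among-population differentiation
(F_ST) at the trait loci as a *set*, without producing hard-sweep outliers.
`polyfst` provides the three pieces needed to study this signal:

1. **`polyfst.simulate`** — a forward Wright–Fisher simulator of diploid
   populations carrying selected + neutral biallelic markers. With `m` the
   number of trait-increasing alleles an individual carries, viability is

   `w(m) = exp(−(m − µ)² x² / (2s))`,

   maximal at the optimum `µ` (defaults: 10 selected + 10 neutral loci,
   effect `x = 5`, optimum `µ = 10`, strength `s = 10`, initial frequency 0.5,
   three independent populations).
2. **`polyfst.fst`** — the per-SNP Weir–Cockerham (1984) unbiased F_ST
   estimator from genotype counts: variance components `a` (among
   populations), `b` (among individuals within), `c` (within individuals) and
   `θ = a/(a+b+c)`, with sample pooling (e.g. CHB+JPT→ASN) and a multilocus
   ratio-of-averages utility.
3. **`polyfst.setcompare`** — the candidate-set vs genomic-background battery:
   MAF/monomorphism filtering, one-tailed Mann–Whitney test (candidates
   stochastically greater), 5 % tail outlier trimming ("core set"),
   LD-confound removal (r² > 0.8 with other-trait variants), and
   per-population top-tail enrichment of an iHS-like selection score with an
   exact binomial test.

`polyfst.synthetic` generates HapMap-like panels under the Balding–Nichols
model, whose `F` parameter is the ground-truth F_ST — so every stage is
testable without external downloads. Real genotype-count tables in the
documented TSV dialect run through the identical code path.

## Worked example

```sh
python analysis/02_selected_vs_neutral_fst.py --seed 1 --n-rep 50
```

prints

```
under selection: selected-set mean theta exceeds neutral in 100% of 50 replicates (mean 1.000 vs 0.135)
drift-only control: ordering holds in 46% (label exchangeability => ~50%)
```

i.e. after 200 generations at N = 1,000 the ten selected loci have resolved to
fixation or loss — a *different* subset in each population, so their mean θ
saturates at 1 — while the ten neutral loci show only drift-level
differentiation (θ ≈ 0.13 at this N and time depth). Switching selection off
(`x = 0`) makes the selected/neutral labels exchangeable and the ordering
drops to a fair coin.

The full battery on a synthetic candidate panel:

```sh
python analysis/05_candidate_pipeline_demo.py --seed 1
```

```
background SNPs: 19925
candidates: 176 given, 175 analyzed (1 absent from panel)
median theta: candidates 0.09592 vs background 0.06765
full set: U=2011694.5, one-tailed p=0.000224 [asymptotic]
core set: 158 SNPs after trimming (13 top, 4 bottom); p=0.006438
LD-confounded removed: 10; post-LD p=0.01371
score tail [pop1]: 13/175 = 0.074 in top tail, binomial p=0.161
score tail [pop2]: 8/175 = 0.046 in top tail, binomial p=1
score tail [pop3]: 11/175 = 0.063 in top tail, binomial p=0.386
```

The candidate set (generated at F = 0.13 over a 0.10 background) shows a
median-θ excess that survives outlier trimming and LD-confound removal, while
the null score table shows no tail enrichment — the qualitative fingerprint of
a distributed polygenic signal rather than a few sweeping outliers.

Other drivers: `analysis/01_simulate_trajectories.py` (trajectory TSV +
figure), `analysis/03_estimator_validation.py` (Balding–Nichols recovery),
`analysis/04_null_and_power.py` (calibration and power). A thin CLI wraps the
same library: `polyfst {synth,simulate,fst,compare} --help`.

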