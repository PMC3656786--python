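# Methods

This note records the statistical models behind each module, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that a maintainer would
otherwise have to reverse-engineer from the code.

## Data model and encodings

A genotype is an unordered pair of allele codes per (individual, locus);
codes are fragment sizes in bp. Two sentinels exist: MISSING (no call;
half-missing cells are rejected at parse time) and NULL, a *scorable*
allele state representing a non-amplifying allele. NULL is treated as a
real allele class throughout — a null homozygote contributes two copies of
the null allele to frequency counts, and NULL==NULL counts as
identical-by-state in coancestry — because codominant 999/999 scoring of
null homozygotes preserves allele counts. Writers emit sorted allele pairs.

Dialects: Genepop (3-digit codes with a `<file>.alleles.tsv` size↔code
sidecar so bp sizes round-trip; code 99/999 = null, 00/000 = missing; the
dialect groups individuals by population, so matrices with non-contiguous
population blocks come back reordered), STRUCTURE (two rows per individual,
−9 missing, 999 null) and a CSV with `a/b` cells (`?/?` missing, `999`
null).

## Diversity

* Unbiased gene diversity uses n = sampled allele copies (2·called
  individuals), the GenAlEx convention.
* F_IS is computed per locus as 1 − Ho/UHe and averaged over polymorphic
  loci; the averaging order is a convention choice (per-locus then mean).
* % polymorphic uses the strict ≥2-alleles criterion; no 95%/99% frequency
  criterion is applied.
* Rarefaction is the exact hypergeometric expectation; private allelic
  richness multiplies each allele's presence probability in the focal
  population by its absence probability in every other population
  (independence across populations holds exactly, which is why the
  exhaustive-enumeration oracle in the tests matches to 1e-9). The default
  standardization g is twice the smallest compared population size.
* Rare alleles (frequency < 0.05) are counted on each population's own
  frequencies; the pooled row uses pooled frequencies.
* Undefined values are dropped pairwise per statistic, never listwise.

## Coancestry

Caballero–Toro molecular coancestry; pairwise deletion over loci. The
diagonal is f_ii = 1 − Ho_i/2 ∈ [0.5, 1]. Group summaries average over
unordered within-group pairs (i < j) and over all cross-group pairs.

## Phylogeny

Individual-level Nei minimum distance: per locus
D = (Σx² + Σy²)/2 − Σxy with x, y ∈ {0, ½, 1} genotype frequency vectors,
averaged over loci called in both individuals. Neighbor joining follows the
Q-criterion with ties broken by the lexicographically smallest pair of
cluster tags (a cluster's tag is its smallest leaf label), so results are
reproducible regardless of input order. Negative branch lengths are clamped
to zero and the clamped total is reported on the tree. Bootstrap support is
the percentage of locus-resampled replicate trees containing each internal
bipartition of the point tree.

## Population structure

* **LD thinning** drops loci with pooled MAF < 0.05, then scans each
  linkage group in map order keeping a locus only if r² ≤ 0.4 with every
  previously kept locus of that group. Unmapped loci are retained.
* **PCoA** is the Gower double-centering of −d²/2 with eigenvalues sorted
  descending; "% variation" shares are computed over positive eigenvalues
  only. Distances are already per-locus means, which is the "data
  standardization" the field's tools apply.
* **Admixture model**: cluster allele frequencies ~ Dirichlet(λ=1),
  admixture rows ~ symmetric Dirichlet(α) with α updated by random-walk
  Metropolis (sd 0.25, uniform prior on (0, 10]), latent per-copy origins
  by Gibbs. Reduced fidelity relative to the original program: no linkage
  model, no prior population information, λ fixed. lnP(D) is the documented
  mean(lnL) − var(lnL)/2 estimator over kept sweeps. K = 1 returns Q ≡ 1
  exactly. Defaults (burn-in 10 000, 100 000 sweeps) mirror common
  practice; the analysis scripts and tests use a few hundred sweeps, which
  is sufficient at their data sizes (separable two-group data is recovered
  perfectly, and replicate lnP(D) spread feeds Evanno's Δk).
* **Evanno Δk** = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)-replicates), interior
  K only; invariant to adding a constant to all lnP(D).
* **F_ST**: Weir–Cockerham (1984) multiallelic θ (components summed over
  alleles and loci) is primary; Nei G_ST = 1 − ΣHs/ΣHt is emitted as a
  cross-check. Permutation p-values permute individuals between the pair
  and use the add-one rule (b+1)/(m+1). Note θ and G_ST estimate different
  quantities at small deme counts (G_ST of two demes ≈ θ/2).

## Linkage disequilibrium

Haplotypes are taken from individuals homozygous and called at both loci —
heterozygotes are treated as missing, defensible because the material is
~98% selfing. Multiallelic r² is the frequency-weighted average of
allele-pair r² values; for two biallelic loci it reduces exactly to the
classical 2×2 r². Pair significance is a chi-square test on the haplotype
contingency table, df = (k−1)(l−1), with a permutation fallback whenever an
expected cell is below 5. Quantiles use linear interpolation (type 7).

Decay is fitted by least squares of linked (d, r²) pairs to the Hill–Weir
drift-recombination expectation

    E[r²] = (10+C)/((2+C)(11+C)) · (1 + (3+C)(12+12C+C²)/(n(2+C)(11+C))),

C = ρ·d, parameterized as log ρ with three starts to avoid local minima.
The LD-block scale is the d where the fitted curve crosses a threshold
(default r² = 0.1), found by bracketing plus Brent root-finding; 0 if the
curve starts below the threshold, ∞ (flagged poor) if the asymptote ≈ 1/n
exceeds it. A flat or rising r²-vs-distance cloud is flagged as a poor fit.
Group decay comparisons bin linked pairs into intervals equal to the
genome-wide block estimate.

## Selection scan

The scan compares two predefined groups (e.g. fiber vs oil types). The
second group can be balanced to the first's size by drawing 100 random
subsets and keeping the one whose total allele count is closest to the
mean — selecting a *typical* subset rather than a diversity-maximizing one.

* **Ewens–Watterson**: F = Σp² per (group, locus); the null is simulated
  from the Ewens sampling formula via a vectorized Hoppe urn with θ tuned
  so E[k] matches the observed allele count, then rejection-conditioned on
  k. p is the two-tailed rank of F; the flag requires Dh/sd < −2.5 *and*
  p < 0.05 (Dh/sd standardizes H = 1 − F against the null). The null
  depends only on (n, k), so one simulated null is shared across loci with
  the same configuration. This double threshold is deliberately stringent:
  its null flag rate is well under 1%.
* **ln RH**: RH is the ratio of (1/(1−He))² − 1 between groups (the
  SMM-based θ estimator); ln RH is standardized across loci and |z| > 1.96
  flagged (a one-sided mode is available). Loci with He ≥ 1 or a zero θ
  estimate in either group are excluded — a locus fixed in exactly one
  group would give log 0, and substituting any floor would distort the
  ±1.96 calibration the test relies on.
* **FDIST-style scan**: the null joint distribution of (He, F_ST) comes
  from a structured-coalescent island model (default 100 demes, 2 sampled)
  with stepwise mutation reflected into 30 allele states. Each observed
  individual contributes *one* haploid allele copy (homozygous-line
  convention; heterozygous cells dropped) so observed and simulated
  sampling match. Per-locus mutation rates for the null are resampled from
  the observed He spectrum (inverting the SMM equilibrium
  He = 1 − 1/√(1+2θ), jittered ×[0.7, 1.4]); migration and a global θ
  scale are tuned (≤20 iterations) until the simulated trimmed multilocus
  θ is within 0.01 of the observed target and mean He within 0.02. The
  recentering target is the **ratio of summed** Weir–Cockerham components
  over the centrally trimmed loci (a trimmed mean of per-locus ratios is
  upward-biased and was found to misplace the null entirely). A locus is
  flagged above the 0.95 quantile of simulated F_ST conditional on He
  (equal-count He bins, ≥50 simulated loci each, mid-rank position).
* **Hierarchical scan**: identical machinery with demes arranged in two
  groups of k demes and within-group migration 10× the between-group rate
  (configurable); with ratio 1 it reduces to the plain island model, which
  the tests verify.
* **Consensus**: a locus is an outlier iff ≥2 of the four tests flag it.
  No multiple-testing correction is applied — the consensus rule plays
  that role.

Candidate windows: with the outlier and its neighbor on one scaffold and
r² > 0.4, window = (|Δbp|/|ΔcM|) × ΔcM (the local kb/cM ratio times the
genetic span); different scaffolds or r² < 0.2 gives a fixed ±10 kb;
moderate LD (0.2–0.4) multiplies the ratio by the distance at which group
LD decays to 0.4 (from the decay fit). A zero-cM span falls back to ±10 kb
with a warning.

## Bottleneck tests

Equilibrium He conditional on the observed allele count k is simulated by a
single-deme coalescent at the θ whose Ewens-expected allele count equals k,
keeping only genealogies whose realized allele count is exactly k; mutation
is two-phase (default p_smm = 0.70, multi-step geometric jumps with
variance 30 — the standard documented defaults; the geometric success
probability solves (1−p)/p² = variance). One subtlety the tests pin down:
conditional on k, SMM gives *higher* equilibrium He than an
infinite-alleles-like model, because reaching the same k under homoplasy
requires a larger θ. The sign test counts loci with He_obs above the
simulated equilibrium mean; each locus's null excess probability is the
fraction of simulated draws above that mean, and the p-value is the exact
two-tailed Poisson-binomial tail (dynamic programming, no normal
approximation). The mode-shift test bins pooled allele frequencies into ten
0.1-wide classes and calls "L-shaped" iff the (0, 0.1] class is the strict
mode.

## Synthetic-data generator

Forward Wright–Fisher demes (default sizes in the presets below);
per-generation steps: sweep-aware fitness, migration (island, or
hierarchical within/between-group rates), selfing with probability s else
within-deme outcrossing, gamete formation with Haldane recombination along
the cM map (crossover switch probability ½(1−e^(−2d/100)), fresh coin at
each linkage-group start), stepwise/two-phase mutation moving sizes by one
repeat unit (2 bp), null-allele mutation, uniform missingness at sampling.
Founders draw from per-locus ladders of k₀ alleles with Dirichlet
frequencies. The truth record stores realized allele counts, a
per-generation multilocus FST (census Weir–Cockerham θ over demes, on up
to 50 tracked loci for speed), per-locus final FST, sweep fixation status
and (optionally) the exact pedigree coancestry of the sample.

Sweeps model divergent selection: carriers of the target allele gain
fitness 1+s inside the swept group and (by default) 1/(1+s) outside it;
the default target is the locally favored allele (largest in-group minus
out-group frequency) at the start generation. A finding worth knowing: in
a 98% selfing population, mechanistic divergent selection at several loci
collapses between-group gene flow genome-wide (migrants carry all the
wrong alleles and effectively cannot recombine), so *every* locus diverges
and per-locus outlier scans lose their contrast. The power experiments
therefore use `engineer_sweeps`, which plants a completed sweep (a novel
allele near-fixed in one group) on a neutral background; the mechanistic
sweep remains available and demonstrably elevates swept-locus FST.

Presets:

* `flaxlike_preset` — 6 demes of 80 in two groups (migration 0.04 within /
  0.012 between), selfing 0.98, TPM(0.70, 30) at 1e-3/locus/generation,
  k₀ = 8 founder alleles at Dirichlet(0.4), 100 generations, 15 linkage
  groups, 20 sampled per deme, 1% missing, 0.1% null mutations. Calibrated
  once to: realized FST ≈ 0.1, ~5–7 alleles/locus, Ho ≈ 0.02–0.04.
* `two_deme_neutral_config` — 2 demes of 100 (m = 0.02), SMM at 1e-3,
  50 diploids sampled per deme; the substrate for the ln RH calibration.
* `two_group_scan_config` — 2 groups × 4 demes of 50 (migration 0.08
  within / 0.02 between), selfing 0.98, TPM, 60 generations, 8 sampled per
  deme; calibrated once to mild group divergence (multilocus θ ≈ 0.02–0.09).

What the generator does **not** emulate: genotyping error and allele-size
binning artifacts, locus-specific mutation rate variation, population
growth/admixture history of a real collection, gametic-phase input
(genotypes only), or selection on standing variation along a realistic
domestication timeline. Passing tests therefore demonstrate estimator
correctness and calibration under the stated model, not robustness to
those real-data complications.

## Pipeline

`pipeline.run_pipeline` executes load → EW pre-filter → diversity →
NJ/bootstrap → PCoA → LD-thinned admixture over a K range with Δk →
coancestry (all loci, by convention) → LD/decay → selection scan (with
balanced subset) → bottleneck tests, writing one artifact per stage plus a
JSON log of seeds, parameters and locus counts (which can only decrease
along the pipeline). A stage failure halts with the stage name; earlier
artifacts and the log are preserved. Reruns with the same config are
byte-identical.

## Problem sizes

The test suite and the analysis scripts run everything at desk scale,
chosen as the package's own study conditions: panels of 60–240 individuals
and 25–500 loci; 1 000–10 000 coalescent loci per island-model null (the
error-rate and power experiments use a 30-island null, which matches the
100-island default to within Monte-Carlo error once migration is recentered,
at a fifth of the cost);
10–200 bootstrap replicates; Gibbs chains of a few hundred sweeps; 20
seeded replicates for error-rate and power experiments. The acceptance
script averages its calibration number over ten 500-locus replicates.

## Known limitations

* The admixture sampler reports no label-alignment across replicates
  (no CLUMPP); Δk uses lnP(D) only, which is label-free.
* FDIST-style conditional quantiles inherit the island-model assumption;
  strong deviations (e.g. recent admixture) shift the null.
* The EW flag at Dh/sd < −2.5 ∧ p < 0.05 is intentionally conservative
  (null rate ≪ 1%); in the four-test consensus it almost never contributes.
* Genepop output reorders individuals into population blocks; sizes
  round-trip only via the sidecar allele table.
* The coalescent kernels cap allele ladders (30 states in the scans, 60 in
  the bottleneck null) with reflecting boundaries; extremely diverse loci
  saturate slightly below their true diversity.
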