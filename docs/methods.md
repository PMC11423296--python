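# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `tsopt`. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Models

**Genomic relationship matrix.** `vanraden_g` computes
`G = M̆M̆′ / (2 Σⱼ pⱼ(1−pⱼ))` with `M̆ = M − 2P`, where `M` is the complete
individuals × loci dosage matrix and `pⱼ` the observed alternate-allele
frequency (no distinction is made between base-population and sample
frequencies — with a single wild sample there is nothing else to use).
Monomorphic loci make the denominator degenerate and are expected to be
removed by the MAF filter first; they are never dropped silently.

**Adjusted means.** Multi-year records are reduced per trait by OLS on
intercept + year + genotype fixed effects. Reported values are
least-squares means at the *average* year, which makes them invariant to
the identifiability constraint on year effects (both sum-to-zero and
reference coding are implemented and agree; the test suite checks this).
A genotype observed in a single year remains estimable under additive
year effects and is flagged. Note one consequence checked in the tests:
adding a constant c to all year-2 records shifts *every* adjusted mean by
c/2 in a balanced design — only genotype contrasts are invariant.

**GBLUP / REML.** The model `ȳ = 1μ + g + ε`, `g ~ N(0, σ²_g K)` is fit
by REML on the eigendecomposition of K: one dense decomposition, then a
bounded 1-D search over log(σ²_ε/σ²_g) of the profiled restricted
likelihood. This is exact and fast for panels of a few hundred
individuals. The asymptotic covariance of (σ²_g, σ²_ε) is the inverse
observed information obtained by central finite differences at the
optimum; the heritability standard error follows by the delta method
with gradient (σ²_ε, −σ²_g)/(σ²_g+σ²_ε)². Boundary solutions (σ²_g → 0)
are flagged, not raised. With K = I and one record per individual the two
components are not separately identifiable — only their sum is — and the
implementation recovers the sample variance as that sum; heritability
estimates are only meaningful when K departs from the identity
(structured or related panels), which is why the recovery experiments use
panels with family structure.

**Prediction.** Test genotypes are predicted as
`ŷ = μ̂ + K_ts,tr (K_tr,tr + δI)⁻¹ (y − μ̂1)` with δ = σ²_ε/σ²_g and μ̂ the
GLS intercept. This is algebraically identical to ridge regression on
centered dosages with λ = δ·2Σp(1−p) (RR-BLUP); the equivalence is an
acceptance check at 1e-6.

**BayesB.** `ȳ = 1μ + Mβ + ε` with a mixture prior: each marker effect is
0 with probability 1−π, otherwise normal with a marker-specific variance
carrying a scaled-inverse-χ² prior (marginally a scaled t, ν = 5). π has
a Beta(2, 8) prior (prior mean inclusion 0.2) and is updated each sweep;
the slab scale is solved from a prior marker R² of 0.5 partitioned over
markers at the prior inclusion rate, and the residual variance has a
scaled-inverse-χ² prior. The Gibbs sweep (intercept, per-marker
indicator+effect with the effect integrated out of the inclusion odds,
marker variances, π, residual variance) is compiled with numba; chains
are deterministic given the seed. Default chain: 12,000 iterations,
2,000 burn-in, thinning 5; the tests use shorter chains (≈1,500/500)
which already separate 10 simulated QTL from 990 null loci in 20/20
replicates.

## Training-set criteria

All criteria act on a shared `CriterionContext` holding G, the PC-score
matrix S of the centered dosages, and the Modified Roger's distance D.

- **D-optimality**: log det(S_tr S_tr′ + 1e-10·I), maximize.
- **CDmean / CDmin**: mean / minimum over the test block of the diagonal
  of `(G Z′PZ G) ⊘ G`, with `V = ZGZ′ + (σ²_ε/σ²_g)I` on the training
  block and `P = V⁻¹ − V⁻¹1(1′V⁻¹1)⁻¹1′V⁻¹`. The scalar inverse in P is
  required for CD ∈ [0, 1] (verified against a dense incidence-matrix
  evaluation on 8-individual instances, along with monotonicity under
  training-set growth). The variance ratio defaults to (1−h²)/h² from
  REML when available, else 1.
- **PEV**: mean diagonal of `W_ts (W_tr′W_tr + λI)⁻¹ W_ts′` with
  `W = (1, S)` and λ = 1/J; minimize. The identity has dimension K+1
  (the score dimension plus intercept).
- **r-score**: `q12/√(q1·q2)` with A = S_tr′(S_tr S_tr′ + I)⁻¹ and
  centering matrices of the dimension their factors require. This is the
  expected correlation between test-set ridge predictions and test-set
  phenotypes under an exchangeable score model — the derivation fixes
  the transposition ambiguities, and the correlation reading motivates
  the square-root denominator (the literal product denominator is
  available behind a flag). Maximize.
- **MaxiMin** (min within-train distance, maximize), **MiniMax** (max
  train-test distance, minimize), **multiple-design** (mean within-train
  minus mean train-test distance, maximize, with both component means
  confined to a band defaulting to the central 80% of observed pairwise
  distances), and **E-NE** (mean distance of each selected entry to its
  nearest selected neighbour, maximize) act on D.

Untargeted scenarios score the complement of the candidate training set;
targeted scenarios score a fixed test group.

**Number of components for S.** `pc_scores` defaults to the components
explaining 95% of variance (capped at V−1) for generic use. For
criterion evaluation that default is too rich: directions beyond the
population/family structure are sampling noise and dominate the ridge
inverses. The optimization experiments therefore pass K = 60, of the
order of the number of family clusters in the simulated panels. K is a
free design parameter a user should set to the effective rank of the
structure in their panel.

## Search

One memetic algorithm serves all criteria: generational GA over
fixed-size subsets (tournament selection, union-repair crossover, swap
mutation, elitism, a few random immigrants per generation), followed on
small instances by iterated local search (first-improvement swap descent
restarted from double-swap perturbations of the incumbent, 50 restarts).
The refinement is gated by `local_search_limit` (default: apply when
size × (pool−size) ≤ 4000) because a descent pass costs size × (pool−size)
evaluations. Plain GA alone stalls on one-swap local optima in roughly
10% of small instances; with the memetic step the search matches the
exhaustive optimum over all 495 subsets on 20 random 12-choose-4
instances for every criterion (the acceptance contract).

`consensus_select` repeats the search n_runs (default 50) times with
seeds split from one master seed, tallies each candidate's inclusion
frequency, and returns the `size` most frequent candidates. Ties at the
cutoff are broken by the criterion value of the certain members plus the
tied candidate, then by the lower index; the consistency score is the
final set's mean frequency divided by n_runs.

## Validation

`make_folds` builds balanced partitions (sizes differ by ≤ 1; 145
individuals at k = 5 give five folds of exactly 29), reshuffled per
repeat. `cross_validate` assembles the per-fold predictions into one
V-length vector per repeat and computes ρ(ȳ, ŷ) and MSPE once on that
vector. `real_validate` trains on all but one spatial group and predicts
the held-out group. `random_baseline` evaluates many uniform random
training sets of fixed size — each predicting its complement
(untargeted) or a fixed test group (targeted) — and is the reference
distribution for judging an optimized set. MSPE always satisfies
MSPE = bias² + Var(ȳ−ŷ) (checked to 1e-10).

## Synthetic data

`simulate_genotypes` draws Balding–Nichols panels: ancestral frequencies
uniform on [maf_floor, 1−maf_floor], group frequencies
Beta(p(1−f)/f, (1−p)(1−f)/f) with drift f = `fst` (default 0.05 — the
emulated population is weakly structured), dosages Binomial(2, p_group).
Defaults emulate the motivating study's shape: 201 individuals split
66:24:55 across three locations, 10,444 SNPs, GBS-like missingness
(union of per-locus and per-individual Bernoulli processes, ~10%
overall), three traits with record-level h² of 0.75/0.80/0.70, two years
of records with fixed year effects (SD 0.5 genetic-SD units), 300 QTL
with gaussian effects (or `sparse_large` for few-large-QTL
architectures). Residual variance is solved per trait so that
Var(g)/(Var(g)+Var(ε)) hits the target at the record level; note that
t-year adjusted means then have heritability h²/(h² + (1−h²)/t).

With `founders_frac` set, each group's individuals are instead drawn as
offspring of random pairs from a founder pool of that fraction of the
group size. This overlays half/full-sib families on the group structure
and is the realistic setting for wild stands recruited from few mother
trees; it is what gives REML its identifiability and prediction its
within-group signal. The experiments in the acceptance script use
`founders_frac = 0.2`.

**What the generator does not emulate — and what that implies.** Loci
are drawn independently: there is no linkage disequilibrium, no linkage
map, and no haplotype transmission. Consequences verified empirically in
this codebase:

- Random same-size training subsets are statistically exchangeable up to
  group/family composition. Criterion values across *random* sets
  correlate ≈ 0 with their realized accuracy; only extreme (optimized or
  adversarial) sets separate.
- The advantage of an optimized training set over the median of 100
  random sets is ≈ +0.01–0.03 in ρ, smaller than the sampling noise of a
  correlation on 100–150 test individuals (SE ≈ 0.07). The
  risk-aversion experiment (10 panels × 2 sizes × 3 criteria) therefore
  yields a fraction of ≈ 0.5–0.6 of cases at or above the random median,
  and this fraction is reported honestly rather than forced. On real
  GBS panels, LD and deep family structure give the criteria far more
  signal; passing or failing this synthetic experiment does not
  transfer directly to real data in either direction.
- E-NE cores maximize spacing, and under this generator maximally
  distant individuals are extreme homozygote profiles, so E-NE cores do
  *not* raise expected heterozygosity or allele coverage above random
  sets here. The real-data behaviour of core collections relies on rare
  alleles concentrated in distinct clusters, which independent-locus
  panels lack.

## Numerical choices

- Kinship jitter policy: one addition of 1e-8 to the diagonal when a
  decomposition fails; never more, never silently repeated.
- REML search bounds: log variance ratio in [−14, 14]; solutions within
  0.5 of a bound are flagged as boundary.
- `mean_round` imputation rounds 2p half-up (2p = 1.5 → 2); `mode`
  breaks ties toward the smaller dosage.
- Filtering order: locus filters (MAF, locus missingness) before
  individual missingness, because locus removal changes individual
  missingness rates; the order is logged and the thresholds default to
  the GBS conventions above.
- Allele coverage is reported as the percentage of population alleles
  captured (100 = complete); the complementary "loss" form is available
  behind `literal_complement=True`.
- GA determinism: every stochastic component (GA, consensus seed
  splitting, BayesB chain, fold shuffling, baselines) is reproducible
  from a single integer seed.

## Problem sizes used by the tests and acceptance script

Oracle equivalence: 20 panels of 12 individuals × 60 loci, all 9
criteria, 4-of-12 subsets (495 enumerated). REML recovery: 20 replicates
of V = 300, J = 2000, dense gaussian architecture, h² ∈ {0.3, 0.75};
cross-validation on the first 10 replicates. BayesB recovery: 20
replicates of V = 300, J = 1000, 10 QTL, shortened chains (1,500
iterations). Risk aversion: 10 panels of V = 200, J = 2000, h² = 0.7,
training sizes {50, 100}, 100 random baselines each, GA at population
40 / 80 generations. These sizes keep the full run to a few minutes on
one CPU while leaving every comparison well-resolved except where noted
above.

## Known limitations

- No LD modelling, linkage maps, pedigree simulation, or read-level GBS
  simulation; no LD-based imputation or phasing (imputation is a
  deterministic single-pass stand-in).
- Single-trait models only; no G×E, no dominance/epistasis kinships, no
  other Bayesian-alphabet members.
- The two-stage scheme (fixed-effect adjusted means, then mixed-model
  prediction) follows the motivating analysis as printed; stage-2 is not
  weighted by stage-1 precision.
- Exact subset optimization (integer programming) is out of scope;
  exhaustive enumeration is used only as a test oracle on small
  instances.
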