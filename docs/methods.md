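# Methods

This note documents the models, the synthetic data generator, the numerical
choices, and the known limitations of `f2impute`.

## Imputation model

**State space.** A diploid sample is modelled as two independent copying
chains over K latent ancestral haplotypes (Li–Stephens style). The hidden
state at SNP *t* is the ordered pair (k₁, k₂) ∈ {1..K}²; the forward–backward
recursions run exactly over all K² states (no pseudo-haploid or gridding
approximations), which keeps the engine amenable to brute-force verification
and is comfortable at desk scale for K ≤ 16.

**Transitions.** Across the interval between adjacent SNPs each chain jumps
independently with probability ρ_t = 1 − exp(−nGen · expRate · d_Mb / 100), a
Haldane-style map from genetic distance to jump probability scaled by the
number of generations since founding. When a chain jumps it re-samples its
haplotype from weights α, the current haplotype included (so a "jump" need
not change state). Chromosome boundaries force ρ = 1, i.e. the chains reset
to the α ⊗ α prior. For an F2 cross nGen = 2: two meioses separate an F2
haplotype from the founder haplotypes.

**Emissions.** Ancestral haplotype k carries the alternate allele at SNP t
with dosage θ_{k,t} ∈ [0, 1]. Conditional on (k₁, k₂), each read is
independently alternate with probability p(1−ε) + (1−p)ε where
p = (θ_{k₁,t} + θ_{k₂,t})/2 and ε is the per-read base error (default 0.01,
a typical short-read post-filter error rate). The emission likelihood is the
product of per-read probabilities; binomial coefficients are constant across
states and omitted.

**EM.** The E-step computes exact posteriors (scaled recursions, exact
log-likelihood). The M-step is closed-form:

- θ′_{k,t} = (alternate-allele draws attributed to haplotype k at t) /
  (all draws attributed to k at t), where a read's attribution weights the
  two chains of each pair state by their relative read likelihoods. Sites
  with no attributed evidence keep their previous value. θ is clipped to
  [10⁻⁴, 1 − 10⁻⁴] to avoid degenerate emissions.
- α′ is proportional to the expected number of haplotype *adoption* events
  (initial states plus recombination-jump landings). This is the exact
  M-step for the copying prior, so the total log-likelihood is
  non-decreasing across iterations — a property the test suite asserts. A
  simpler variant (α from average posterior usage) is available through
  `em_update` for callers that only have site posteriors, but `run_em` uses
  the exact update precisely because the monotonicity guarantee is worth
  keeping.

θ is initialized Uniform(0.1, 0.9) from the run seed and α uniform. The
default iteration budget is 100.

**Label-switch repair.** Plain EM on cross data reliably converges to
*ancestral-label-switched* local optima: instead of one haplotype per
founder, two latent haplotypes represent complementary mosaics of two
founders, switching identity at some genomic breakpoint. Sample accuracy
degrades only mildly (chains hop between the mosaics) but the reconstructed
haplotypes are wrong, and the likelihood is measurably lower — every chain
crossing the breakpoint pays a jump penalty, which also makes the breakpoint
visible as a sharp peak in the expected-jump profile the E-step already
computes. `run_em` therefore periodically (every 10 iterations during the
first three quarters of the run) proposes swapping two haplotypes' tails at
the strongest such peaks, restricting proposals to the haplotypes carrying
the most jump landings there, and accepts a proposal only when the exact
total log-likelihood increases. Because the move is deterministic greedy
ascent, EM monotonicity is preserved — unlike the stochastic
shuffle/re-randomization heuristics common in this model family, which are
deliberately not reproduced here. In the single-cross benchmark this repair
takes founder-haplotype recovery from a mean absolute error of ≈ 0.1–0.4
(label-switched) to ≈ 0.003.

**Multi-start.** EM occasionally lands in a poor basin that the repair
cannot fix (e.g. two founders merged into one haplotype). `run_em` runs
`n_starts = 3` independent initializations for a 10-iteration burn-in and
continues the one with the highest exact log-likelihood — the same guard
scikit-learn's mixture models use (`n_init`). Selection uses likelihood
only, never truth data. The reported log-likelihood trace is the winning
start's own path and remains monotone.

**Outputs.** Genotype posteriors treat the two allele draws as independent
Bernoulli(θ) given the pair posterior: P(g=0) = E[(1−θ_{k₁})(1−θ_{k₂})],
P(g=2) = E[θ_{k₁}θ_{k₂}], P(g=1) the complement; dosage = P(1) + 2P(2). The
per-site info score is the IMPUTE-style measure
1 − mean(Var[g]) / (2f̂(1−f̂)) with f̂ the mean dosage / 2, undefined (NaN)
at f̂ ∈ {0, 1}.

**Kernels.** The E-step is implemented twice: a numba-compiled per-sample
kernel (production path) and a vectorized numpy reference; the suite asserts
agreement to 10⁻¹², and forward–backward is additionally verified against
exhaustive path enumeration on small instances (K = 2, T ≤ 4) to 10⁻⁸.

## Synthetic cohorts

The generator emulates the statistical structure of a multi-parent F2
sequencing study:

- **Genome**: chromosomes with SNP positions drawn uniformly without
  replacement; a uniform genetic map (default expRate = 2 cM/Mb). The desk
  default is 1 chromosome × 5 Mb with 2000 SNPs; the full-genome
  configuration (24 chromosomes, 734 Mb) is expressible but not a test
  default.
- **Founders**: per site a population alternate-allele frequency is drawn
  Uniform(0.05, 0.95); each line's consensus allele is a Bernoulli draw from
  it; a fraction `residual_het` (default 0.01 — inbred but not perfectly so;
  configurable because real panels vary) of (line, site) pairs is made
  heterozygous. Sites fixed across the whole panel are redrawn, so every
  simulated SNP is a real SNP of the panel. Consequence worth knowing: in a
  *two*-line panel this forces nearly every site to differ between the two
  lines, which makes non-recombinant all-heterozygous F2s nearly
  uninformative for per-sample correlation. Single-cross scenarios should
  therefore simulate the full eight-line panel and cross two of its lines
  (`panel_lines=MEDAKA_LINES`), mirroring how a study-wide SNP set is
  applied to one cross; roughly 40% of panel SNPs then segregate within the
  cross.
- **Breeding**: F1s carry one gamete from each founder line; F2s carry
  gametes of two distinct F1 parents, so two explicit meioses separate F2
  haplotypes from the founders (this is what makes nGen = 2 correct).
  Meiosis draws Poisson(expRate · L_Mb / 100) crossovers per chromosome at
  uniform positions. The default truth plan flags one F1 per cross plus two
  F2s of the 72-2 × 55-2 cross as high-coverage truth samples (12 for the
  ten-cross design).
- **Sequencing**: per-sample mean depth ~ Gamma(mean = target, CV = 0.5)
  (low-pass studies show substantial per-sample depth spread; a fixed-depth
  mode exists for tests), truth samples at 40×; per-site read totals
  Poisson(depth); alternate-read counts binomial with the emission model
  above. No read-level sequence simulation, alignment, duplicates, or
  library-prep bias.

What passing tests on these cohorts does *not* show: robustness to
alignment artifacts, segmental duplications, batch effects between library
preparations, or non-uniform recombination — real-data accuracies will sit
below same-size synthetic ones.

## Refinement, evaluation, design exploration

**SNP refinement** starts from sites polymorphic (minor allele count ≥ 1)
among the truth samples, then iterates: thin truth reads to 0.5× (so truth
samples resemble the cohort), impute all samples jointly, compute each SNP's
squared Pearson correlation (on dosages) against truth genotypes across the
truth samples, and keep SNPs with r² ≥ the iteration's threshold (defaults
0.5, 0.5, 0.75, 0.9, 0.9). SNPs with undefined r² (monomorphic in truth)
cannot be validated and are dropped.

**Concordance** is squared Pearson correlation of dosage vs truth genotype:
per truth sample across sites (averaged unweighted across samples), and
pooled over (site, sample) pairs within MAF bins of width 0.05 (last bin
closed at 0.5; bin label = mean observed MAF of member sites). Observed MAF
comes from truth-sample genotypes by default; an imputed-cohort MAF source
is equally valid and supported by passing any per-site MAF vector.

**Design exploration**: depth downsampling is per-read binomial thinning
with factor min(1, d_target/d_original) per sample (samples already below
target are untouched; truth samples are thinned to the cohort's target, or
to 0.5× when the cohort keeps its original depth). Sample downsampling
always retains truth samples. Cross downsampling removes all samples (truth
included) of every cross involving a named founder line; a reciprocal cross
counts as one cross in the (lines, crosses) bookkeeping. K is set to twice
the number of founder lines present. The cost model is
cost(n, d) = (n·d·g/f)·c_f + n·c_p with genome size g = 734,040,372 bp,
flow-cell output f = 273,542,732,637 bp and cost ratio c_f/c_p = 683.89
(costs are reported in units of one library prep, c_p = 1; only the ratio
matters for relative costs). Sequencing is treated as continuously divisible
— no flow-cell packing.

## Problem sizes and precision choices

Test and acceptance runs use desk-scale cohorts chosen so the whole suite
runs in minutes on one CPU:

- Parameter recovery: one cross of the eight-line panel, 400 F2 + 3 truth
  samples, 2000 SNPs on 1 × 5 Mb, 1× fixed-seed depth, ε = 0.01,
  residual_het = 0 (so founder consensus is the ground-truth haplotype),
  K = 4, 100 EM iterations. Founder recovery compares the two most-used
  reconstructed haplotypes with the crossed lines' consensus haplotypes
  under best assignment.
- Design sweep: same cross with 800 SNPs, residual_het = 0.01, base depth
  1.4×; depth grid {0.25, 0.5, 1}×, cohort grid {100, 400}, K = 4, 60 EM
  iterations, 5 replicates. Five replicates rather than three because the
  curvature comparison (marginal gain of the second depth doubling vs the
  first) contrasts two nearly-equal differences and needs tighter averages
  than the simple orderings; r² is scored on all simulated samples, since
  in simulation every genotype is known and three truth samples would give
  needlessly noisy cell means.
- Refinement properties: the eight-line design scaled to ~5% of its
  published per-cross sizes (120 F2 + 12 truth), 300 SNPs, 1.4×, K = 16,
  20 EM iterations.

Numerical details: scaled forward–backward with per-site normalization
(floor 10⁻³⁰⁰); posteriors renormalized defensively; undefined statistics
(zero-variance r², info at fixed frequency) are NaN sentinels, and
undefined-r² SNPs count as below any refinement threshold. Ties in K
selection go to the smaller K. All randomness flows from explicit seeds
through `numpy.random.Generator`; seeded runs are bit-reproducible.

## Known limitations

- The exact K²-state recursion is quadratic in K; K beyond ~24 calls for the
  pseudo-haploid approximations this package deliberately omits.
- The label-switch repair proposes single-breakpoint tail swaps among at
  most three candidate haplotypes per peak; pathological multi-breakpoint
  mosaics may survive (multi-start mitigates, but does not eliminate, this).
- The genetic map is uniform; hotspots are not modelled.
- Residual heterozygosity is i.i.d. across (line, site) pairs, whereas real
  inbred lines carry *blocks* of residual heterozygosity.
- The cost model ignores flow-cell quantization and assumes deduplicated
  output scales linearly with depth.
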