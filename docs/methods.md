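# Methods

## The phenotype and its error structure

Each backcross male contributes one binomial observation: `minutes_mel`
courtship minutes directed toward the *melpomene*-type female out of
`n = minutes_mel + minutes_cyd` total courtship minutes, aggregated over
repeated 15-minute choice trials. Courtship minutes are far from
independent Bernoulli draws — males differ consistently in preference — so
every model carries a per-male random intercept on the logit scale. With
one aggregated observation per male this is an observation-level random
effect: it absorbs extra-binomial variation rather than separating
within- from between-male variance. Males with zero total courtship minutes
carry no information about the courtship *proportion* and are excluded from
proportion models (they are listed in `ScanResult.excluded_ids`).

## Genotype probabilities

A backcross genome is a two-state process (hom/het) along each chromosome.
Transition probability across a gap of d cM is the Haldane recombination
fraction r(d) = (1 − e^(−2d/100))/2 — no crossover interference, the same
model used by the simulator and the LD arithmetic, so all recombination
quantities in the package are mutually consistent. Emissions equal the true
state with probability 1 − ε (default ε = 0.001, exposed); missing markers
emit uniformly; the chromosome-start prior is 0.5/0.5. Posteriors come from
the scaled forward–backward algorithm, vectorized across individuals, on a
grid that is the union of marker positions and whole-cM steps (pseudo-
markers with uninformative emissions). The two-state posterior is validated
in the test suite against exhaustive enumeration over all genotype paths on
small chromosomes.

The sex chromosome receives no special treatment: the intended application
analyses backcross males only, for which the Z behaves like an autosome in
this two-state coding. That is a documented limitation, not an option.

## Genome scan and LOD convention

At each grid position the full model regresses the binomial response on the
posterior P(het) (a Haley–Knott-style regression carried into the mixed
model); the null model drops the genotype term. LOD = ΔlnL/ln 10, clamped
at 0 (the models are nested; tiny negative values can only arise from
quadrature round-off). The likelihood-ratio statistic 2ΔlnL = 2 ln 10 × LOD
is reported wherever model comparisons are made (drop-one tests, group
comparisons). Positions where the genotype covariate is constant across
males get LOD = 0 with a warning. Peak ties break to the lowest cM.

## Mixed-model likelihood: quadrature and optimization

The marginal likelihood integrates the scalar random effect per male.
Two evaluators are used:

* **Optimization** maximizes a fixed-order Gauss–Hermite approximation
  (41 nodes by default; 25 for batched genome scans) whose gradient and
  Hessian are exact in closed form because the nodes do not move with the
  parameters. Fitting is a damped (Levenberg-style) Newton ascent — the
  likelihood is not concave in σ, so the damping is raised per model until
  the step is an ascent direction — run *batched* across all scan positions
  or simulation replicates simultaneously, which is what makes
  1,000-permutation thresholds and 10,000-replicate winner's-curse grids
  tractable. Gradient tolerance 1e-8; σ is estimated on [1e-3, 20] and
  snapped to 0 when it converges to the lower bound with a negative score.
* **Reporting** re-evaluates the log-likelihood at the optimum with
  adaptive Gauss–Hermite quadrature (15 nodes, exact per-male mode and
  curvature; 1 node recovers the Laplace approximation). For binomial
  totals typical of courtship data (≲100 minutes) the fixed-order and
  adaptive values agree to ~1e-9, which the test suite checks; the adaptive
  value is what appears in every reported LOD and 2ΔlnL.

Setting `sigma=0` pins the variance and reduces every fit to a plain
binomial GLM; the suite verifies exact agreement with an independent GLM
implementation, and this pinned mode is the bridge to the closed-form
binomial likelihood-ratio oracles.

## Permutation thresholds

Permutations shuffle whole phenotype rows (both minute counts and the trial
count together) across males, preserving each male's trial structure —
the only permutation unit consistent with the per-male random-intercept
grouping. Each permutation rescans the genome; the per-chromosome maxima
are stored so thresholds for any chromosome subset of the same run are
exact (and a one-chromosome threshold can never exceed the genome-wide one
on identical data). The threshold is the (1 − α) linear-interpolation
quantile of the per-permutation maxima; genome-wide P values use the
add-one permutation estimator (k + 1)/(m + 1).

## Multi-QTL modeling

`fit_multiqtl` takes the scan peaks, builds the design from genotype
*probabilities* at those positions, and fits the saturated model with all
pairwise interactions. Simplification is stepwise: interactions are tested
jointly first, then eliminated singly (least significant first, threshold
P > 0.05 by χ² likelihood-ratio tests); main effects and the random
intercept are always retained. The retained model γ is scored by
pLODa(γ) = LOD(γ) − T·|γ|, an identity the suite checks to machine
precision. Per-QTL support is the change in pLODa when that QTL (and any
interaction touching it) is eliminated, plus the drop-one 2ΔlnL with its
χ² P value.

1.5-LOD support intervals are the smallest contiguous grid interval around
the peak where LOD ≥ peak − 1.5, clipped to the chromosome; a flat profile
returns the whole chromosome with a warning. Interval resolution is the
scan grid's resolution.

## Effect sizes

Genotype classes at a locus are maximum-posterior calls; calls with
P(het) ∈ [0.45, 0.55] are excluded from class means (they remain in model
fits, which use probabilities). Class means are minutes-weighted pooled
proportions Σy/Σn — males contribute information proportional to their
courtship time — with unweighted per-male means reported alongside; 95%
CIs are normal approximations on the logit scale of the pooled proportion
(they do not propagate between-male overdispersion and are therefore
slightly anticonservative; a documented simplification). The headline
effect scale is

    percent of parental difference = 100 · (mean_het − mean_hom) / (p_mel − p_cyd),

with the parental means always passed in, never hard-coded.

## Winner's-curse (Beavis) grids

For a focal genotype column, phenotypes are resimulated `n_reps` times at
each true effect on a 5–40% grid (defaults; both configurable). Each
replicate records the focal-locus mixed-model LOD and the minutes-weighted
effect estimate — the same estimator used empirically, so simulated and
observed effects are commensurable. Significance is assessed at the focal
locus against the genome-wide permutation threshold passed in, not by a
fresh genome-wide scan per replicate; this is the documented (and
switchable, by supplying a different threshold) interpretation that keeps
10,000-replicate grids tractable. `prob_significant_below` turns the grid
into curves of P(estimate < observed | significant) per true effect, with
cells lacking significant replicates flagged undefined.

## Windowed admixture (f_d)

Per-site components follow the dynamic-donor ABBA–BABA definition:
ABBA = (1−p1)·p2·p3·(1−p4), BABA = p1·(1−p2)·p3·(1−p4), and the denominator
substitutes pD = max(p2, p3) for both p2 and p3. Windows are half-open
[start, start+width) on 0-based physical coordinates, tiled from 0 with the
given step; defaults 100 kb windows, 20 kb step, ≥1 site — the window/step/
min-sites reading of the conventional "w100 m1 s20" naming, recorded here as
an interpretation. Windows failing the site filter or with non-positive
denominator are emitted with f_d = NaN and a `defined` flag; negative f_d
values are reported, never clipped, since clipping would bias genome
medians. f_d ≤ 1 is guaranteed only over sites whose own denominator
summand is non-negative (p1 ≤ pD); windows mixing such sites can exceed 1
and are reported as computed. VCF input polarizes the alternate allele
against the outgroup consensus and skips sites with fully missing outgroup
genotypes.

## LD decay arithmetic

r(d) uses Haldane by default; Kosambi is available for sensitivity
analysis. The default is pinned by a regression test: a 4.8 cM pair loses
4.6% of D per generation under Haldane but 4.8% under Kosambi, and only the
former matches the package's other recombination conventions. One
generation of random mating removes a fraction r of D (0.5 for unlinked
loci); t generations retain (1−r)^t. Percent losses are reported to one
decimal. Assortative mating — which would slow the decay at a preference
locus coupled to its cue — is deliberately out of scope.

## Synthetic-data generator: what it emulates, and what it does not

Defaults define a study-scale cross: 139 males, 21 chromosomes of 50 cM,
markers every 5 cM, genotyping error 0.001, missingness 0.02, trial counts
1 + Poisson(4.2) (median 5 trials per male), courtship minutes per trial
Poisson(1.65) (so the median proportion of 15-minute trial time spent
courting is ≈ 0.11), parental mean proportions (0.05, 0.95), and
overdispersion SD 1.0 on the logit scale. The overdispersion default was
chosen so that a planted 30% QTL yields focal LODs in the single-to-low-
double digits at n = 139 — the order observed in comparable real crosses —
rather than the implausibly clean scans smaller values produce. The
minutes-per-trial distribution is a stand-in (real data report it only
graphically) and is a first-class config knob (`CountSpec`).

Planted effects are calibrated *marginally*: the baseline and per-QTL logit
coefficients are solved (by root-finding on the logit-normal mean) so the
expected class-mean proportions land exactly on the nominal
percent-of-parental-gap targets after integrating over the overdispersion.
A raw logit offset would miss the nominal effect by up to ~2 percentage
points at SD 1.0. With several QTLs the calibration is exact for each
locus against the all-hom baseline; joint combinations remain additive on
the logit scale only.

Not emulated: sequence-level data (reads, RAD loci), linkage-map
estimation error, segregation distortion, crossover interference, shared
family structure among the backcross males, and any female-behavior
contribution to courtship time. Passing recovery tests on these synthetic
crosses therefore demonstrates correctness of the estimators under the
stated generative model, not robustness to pedigree artefacts or
map errors in real data. QTL positions are snapped to the nearest simulated
truth locus on the named chromosome; positions off the chromosome are
errors.

The four-population frequency generator draws conspecific populations
(P1, P2) from a shared Beta(1.5, 8), the donor P3 from Beta(8, 1.5), fixes
the outgroup ancestral, and mixes p2 ← (1−f)·p2 + f·p3 site-wise, so the
windowed f_d is centred near the nominal introgression fraction f.

## Problem sizes used in the shipped experiments

The packaged tests run the parameter-recovery experiment at 200 replicates
of the full default cross (scan grid 5 cM), the winner's-curse grid at
1,000 replicates per true effect, and permutation checks at 100
permutations of a marker-sparse 21-chromosome cross — sizes chosen so the
whole suite completes in minutes on a laptop while keeping Monte-Carlo
error well inside the tested margins. All seeds are fixed; every generator
is bit-reproducible given a seed.

## Known limitations

* Two-genotype backcross designs only; no F2/intercross state space, no
  X/Z-specific handling, no composite interval mapping or two-dimensional
  epistasis scans.
* Effect-size CIs ignore overdispersion (see above).
* The permutation engine assumes exchangeable males (one row each); it
  does not stratify by family.
* f_d input filtering (depth, genotype-quality) is upstream of this
  package; frequencies are taken at face value.
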