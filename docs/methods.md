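# Methods

## Statistical model

We consider a two-arm trial on a normally distributed endpoint with
common standard deviation σ across J disjoint subgroups of known
prevalence λ_j. Candidate populations for selection are unions of
subgroups; the package supports any collection of pairwise nested or
disjoint unions (partially overlapping candidates are rejected because
their joint law is not determined by prevalences alone). The statistic
of candidate s is Z_s = I_s·(Ȳ_{s,T} − Ȳ_{s,C}) ~ N(θ_s I_s, 1).

**Information convention.** I is the *reciprocal standard error* of the
mean-difference estimate, I = 1/(σ√(1/n_T + 1/n_C)) = √n/(2σ) under 1:1
allocation — not Fisher information. This is the only convention under
which all margins are unit-variance normal and accumulated information
adds in squares across independent stages, (I^{1:k})² = Σ_i (I^{(i)})²,
which the accumulated statistic Z^{1:k} = Σ_i I^{(i)}Z^{(i)}/I^{1:k}
requires.

**Selection.** The default rule takes the maximum statistic (the worst
case for both error inflation and selection bias, hence the calibration
target); a sequential three-candidate variant (S1 if it beats both,
else S1+2 if it beats F, else F) coincides with the maximum rule except
on measure-zero ties, which we resolve toward the larger population.
Custom vectorized rules are accepted by the simulator but never used in
calibration.

## Calibration

The joint density of the selected statistic and index,
p(z, w) = φ(z − θ_w I_w)·Ψ_{𝒮∖w}(z,…,z), uses the conditional
multivariate-normal CDF Ψ of the rival statistics given Z_w = z
(conditional mean affine in z with slope equal to the correlation
column; conditional covariance the Schur complement). Dimensions 0 and
1 use closed forms; dimension ≥ 2 uses scipy's Genz algorithm, which is
deterministic run-to-run in the installed version.

* **Critical value (single stage).** Brent root-finding on
  Σ_w ∫_C^∞ p(z, w; Θ₀) dz = α, bracketed by the single-test and
  Bonferroni quantiles; tolerance 1e-8 on C (≈1e-9 on the FWER scale).
  The value is sample-size-free because the null law depends only on
  prevalences, so it is computed once per design.
* **Outer integrals.** Gauss–Legendre with 256 nodes, truncated at
  θ_w I_w ± 8.5 (mass beyond < 1e-16).
* **Multistage.** After selection, recruitment is enriched: stages ≥ 2
  draw all patients from the selected population, so a population s
  accrues n^(k)·prev(s∩w)/prev(w) patients at stage k and the selected
  statistic advances by the independent-increment Gaussian transition
  law with mean z·I_prev/I_curr + θ_w (I²_curr − I²_prev)/I_curr and
  variance (I²_curr − I²_prev)/I²_curr. Stage-wise stopping
  probabilities propagate the stage-1 density through this kernel on a
  256-node grid per continuation interval; with this resolution the
  one-population two-stage O'Brien–Fleming constant reproduces the
  closed-form bivariate-normal value to better than 1e-4.
* **Boundary families.** O'Brien–Fleming upper bounds C·√(K/k) with a
  single free constant tuned so the summed efficacy crossings under the
  global null equal α (tolerance 1e-5); fixed lower (futility) bounds,
  binding by default — nonbinding bounds are set to −∞ during
  calibration but retained for conduct. Error-spending schedules are
  solved forward stage by stage; a zero increment yields an infinite
  bound (the "selection-only first stage" design is the special case
  spending nothing at stage 1).
* **Sample size.** Searches run on a continuous n (subgroup sizes λ_j·n
  stay fractional inside the information formulas) with Brent's method,
  then round **up to the smallest total giving every subgroup an
  integer count** (a multiple of 2 for halves, of 3 for thirds). This
  convention reproduces the reference totals 684, 552 (276/stage) and
  576 exactly. Two power definitions: probability of selecting a
  prespecified target population *and* rejecting its null, or of
  rejecting any null among an interest set. Multistage searches use
  equal per-stage totals by default and recalibrate nothing per
  candidate n (boundaries are size-free under an equal split).

## Simulation engine

The default mode draws **per-subgroup sufficient statistics**: the
observed mean difference of subgroup j at stage k is
N(θ_j, 4σ²/n_j^(k)); candidate statistics are the sample-size-weighted
pools of their subgroups. Nested correlations, enrichment reallocation,
and the naive pooled MLE — including the deliberate distortion that a
population strictly containing the selected one pools post-interim
patients drawn only from the selected subpopulation — then hold *by
construction*, not by approximation. A patient-level mode draws
individual outcomes and serves as an end-to-end check; an optional
multinomial-count mode replaces the fixed subgroup sizes with random
ones for sensitivity analyses. One `numpy` Generator seeded from the
config drives all draws in a fixed order, so identical configs yield
identical record streams.

What the generator does **not** emulate: non-normal or delayed
endpoints, time trends between stages, unknown prevalences, unequal
variances across subgroups, or overrunning patients. Passing tests
therefore validate the Gaussian sufficient-statistics model and its
bookkeeping, not robustness to those departures.

## Estimator assessment

Residuals are standardized at the stopping stage,
r = (θ̂_s − θ_s)·I_s^{1:M}, where I_s^{1:M} uses the patients actually
accumulated in s (after any enrichment). Reported per population ×
conditioning (none / selected / selected-and-rejected) × stage scope
(each stage, overall), plus family-wise rows that follow the selected
population's estimator. Two identities validate the standardization and
are asserted in the tests: the unconditional single-stage estimator has
bias/SE = 0 and √MSE/SE = 1, and overall values are the
stage-proportion-weighted mixtures of the stage-wise values (exactly,
in-sample). Family-wise rows with conditioning "none" pool every
candidate's residual with equal weight (there is no selected estimator
to follow), making them exactly symmetric — hence unbiased — under the
global null. Empty cells (e.g. a subgroup never selected at low
prevalence) are reported as missing values with proportion 0 rather
than dropped.

## Strategy comparison

For the two-subgroup planning example, separate per-subgroup studies
use the closed-form normal sample size per study and family-wise error
1 − (1 − α')^2; the selection designs use the calibrations above. The
duration model recruits from one stream at a constant rate; enrichment
to a subgroup scales the rate by its prevalence (screened non-members
are not enrolled), the endpoint delay is added once, and the
interim-analysis lag is absorbed into continued activities — the only
reading consistent with all four reference durations (27.64, 30.36,
25.08, 36.12 months). Separate studies recruit sequentially from the
same stream.

## Problem sizes and numerical defaults

Default study conditions follow the reference settings throughout:
α = 0.025 one-sided, 1 − β = 0.8, effect 0.5 (or 0.23 in the planning
example) in exactly one subgroup, σ = 1 (0.72), equal prevalences, and
10⁶ simulation replicates, which give Monte-Carlo standard errors of
≈0.03–0.05 percentage points on proportions and ≈0.001 on standardized
biases. Calibrations complete in seconds; a million-replicate
single-stage scenario simulates in under ten seconds on one CPU.
Quadrature tolerances: 1e-6 for density normalization, 1e-5 for
boundary calibration, 1e-8 for critical-value roots, ±8.5 truncation on
the z scale.

## Known limitations

* Only one interim selection; at most one population continues.
* Candidates must be pairwise nested or disjoint.
* Threshold-based selection rules are simulated but not calibrated
  (calibration assumes the maximum-rule worst case).
* No bias-corrected, shrinkage, or conditionally unbiased estimators
  and no confidence intervals — the package quantifies the naive MLE's
  error; correcting it is out of scope.
* The two-stage design with a zero futility bound treats that bound as
  binding in calibration; if the bound would be ignored in conduct, the
  type-I error is conservative rather than exact.
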