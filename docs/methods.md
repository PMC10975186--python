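# Methods

## Structural models

Dose input is a zero-order infusion of rate R = amount/duration.  The
one-compartment model solves dA/dt = input(t) − K·A with c = A/V; the
two-compartment model adds a peripheral amount with micro-constants KCP
(central→peripheral) and KPC (peripheral→central), elimination K from the
central compartment, and c = A₁/Vc.  Both are evaluated in closed form:
the two-compartment response is the bi-exponential in the hybrid constants
α, β (roots of λ² − (K+KCP+KPC)λ + K·KPC = 0), and a finite infusion is the
difference of two step responses, c(t) = (R/Vc)[G(t−t₀) − G(t−t₀−T)].
Multi-dose regimens superpose events over the full history; no
steady-state shortcut is used, and the number of doses preceding the
sampled infusion is an explicit argument of the regimen builder
(default 4, ≈24 h of q6h therapy before sampling).

Degenerate eigenvalues (α = β within 1e−10 relative) switch to the
l'Hôpital limiting form of the step response.  KCP = 0 is routed through
the one-compartment core exactly, so the reduction is exact rather than a
numerical limit.  Units everywhere: mg/L, hours, litres, 1/h.

Covariate variant: K = KI + KS·CRCL with CRCL in mL/min, constant within a
fitting window.  The clearance itself comes from the
unstable-renal-function mass balance
0.4·BW·(c₂−c₁)/T = P_adj − ((c₁+c₂)/2)·CCR·1440, solved for CCR (hundreds
of mL/min; the 1440 min/day factor fixes T to days).  P_adj uses the
literature per-kg production, linear in age (29.305 − 0.203·age for men,
25.3 − 0.175·age for women, mg/kg/day) with the 1.035 − 0.0337·SCr
correction when a mean serum creatinine is supplied; the constants are an
overridable table.

## Observation error

The assay polynomial SD(c) = c₀ + c₁c + c₂c² + c₃c³ is fitted per degree
1–3 by unweighted ordinary least squares on (nominal concentration,
replicate SD) pairs; the highest-r² degree is flagged selected (ties to
the lower degree; identical SDs yield slope 0 with r² reported as 0 and a
warning).  Total observation variance composes the polynomial with three
proportional terms — dosing error, model misspecification, sample-timing
error, each a fraction of the predicted concentration — added in
quadrature and scaled by γ² (γ ≥ 1).  The quadrature composition is this
package's convention for giving those three scalar settings an exact
meaning; with all three at 0 and γ = 1 the variance is exactly SD(c)².
Evaluation outside the fitted calibration range is allowed but logged; a
nonpositive SD raises.

## Population estimation

The population model is a discrete mixing distribution over support
points inside a parameter box (defaults: the piperacillin study's
posterior ranges).  Fitting alternates:

1. **Weights.**  On a fixed grid, the mixture weights maximizing
   ∑ᵢ log ∑ⱼ wⱼ Lᵢⱼ are found by the multiplicative EM update
   wⱼ ← wⱼ·meanᵢ(Lᵢⱼ/∑ₖwₖLᵢⱼₖ), which is monotone in the log-likelihood;
   iteration stops at a gain below 1e−8 or 5000 iterations (warning, not
   failure, at the cap).  Likelihoods are computed in log space and
   rescaled per subject by the row maximum to avoid underflow.  Each
   cycle's EM is warm-started from the previous solution (90% of the mass
   on the incumbent, 10% spread over new proposals): cold uniform starts
   on grids full of near-duplicate columns converge too slowly to be
   usable within the iteration cap.
2. **Support pruning and condensation.**  The EM leaves weight spread
   over statistically equivalent columns, whereas the exact nonparametric
   optimum concentrates on at most n_subjects points.  Three conservative
   reductions restore sparsity without meaningfully changing the
   likelihood: (a) greedy removal of columns whose exact, recomputed
   removal cost keeps the cumulative log-likelihood loss below a small
   budget (a tenth of the cycle tolerance, capped at 0.005) — majority
   columns (w > 0.5) are never candidates because the rank-one downdate
   cancels catastrophically there; (b) pooling of points that coincide to
   1e−4 of the range span in every coordinate *or* whose per-subject
   log-likelihoods differ by less than 0.02 (flat directions of the
   weight problem); (c) dropping points whose first-order multiplier
   meanᵢ(Lᵢⱼ/mixᵢ) certifies exclusion — applied only to points the EM has
   already driven below 1e−3 weight, because mid-iteration multipliers of
   mass-carrying points are not trustworthy.
3. **Refinement.**  Each surviving point (the 30 highest-weighted, for
   the 4–5-parameter models) proposes coordinate-wise ±Δ moves and all
   pairwise-diagonal ±Δ combinations, at scales (1, ¼, 1/16)·Δ, clipped to
   the box.  Diagonal proposals matter: infusion data constrain clearance
   K·V far more tightly than K and V separately, and axis-parallel steps
   alone stall on that ridge.  Δ starts at 20% of each range; it shrinks
   (by 0.5, floored at 1e−4 of the range) only on cycles whose gain fell
   below the tolerance, so progress at a working scale is not starved.

Cycles stop when the log-likelihood gain drops below `tol` (default 0.01)
with Δ at its floor, or at `max_cycles` (default 50).  The first cycle's
gain is measured against the uniform weighting of the initial grid, so an
infinite tolerance returns the one-pass solution on the initial grid.
The initial grid is `n_initial` (default 100) points of a scrambled Sobol
sequence; the whole fit is deterministic given the seed.

On noise-free single-truth cohorts this scheme places ≥99.9% of the mass
within 1% of the generating parameters, and it separates well-spaced
two-point mixtures exactly; on noisy 12-subject cohorts the recovered
marginal means sit within a few percent of the simulated truth means.
The returned support can still hold a handful of statistically equivalent
near-duplicates — equivalence, not minimality, is the contract.

## Fit diagnostics

−2LL is reported with the small-sample-corrected Akaike criterion
AICc = −2LL + 2P + 2P(P+1)/(N−P−1) and BIC = −2LL + P·ln N, where N is the
total observation count and P the number of random-effect parameters plus
one error parameter.  Weighted prediction errors (obs − pred)/SD(pred) of
the prior-weighted (population) predictions give bias (mean) and
imprecision (bias-adjusted mean square); posterior-weighted predictions
feed the second observed-vs-predicted regression.  Shrinkage per
parameter is 100 × mean individual posterior variance over the population
mixture variance.  Note that on cohorts whose truth is drawn uniformly
over the full parameter box the population-prediction imprecision is
intrinsically large — a single population curve cannot track individuals
spanning a ten-fold volume range; the posterior regression (r² ≈ 0.999 in
the bundled example) is the individual-level accuracy measure.

## Individual estimation and quasi-models

MAP Bayesian analysis reweights any discrete prior by one subject's
likelihood; the posterior keeps the prior's support.  Both the posterior
mean (default for comparisons) and the MAP point are always reported, and
fitted curves are posterior-weighted averages of the per-point curves, so
multi-modal posteriors (typical under quasi-model priors) keep their
structure.  The posterior-mixture MSE is bounded by the worst single
point's MSE (convexity).

A quasi-model draws n_points (default 399 — a default, not a cap) values
per parameter from independent uniform streams over the ranges, assembles
point j from the j-th draw of each parameter, and assigns probability
1/n_points.  Batches (default 30 models) derive per-model seeds from a
master seed through `numpy` seed sequences, keeping every seed below 2³¹.
Selection fits every model to the subject and keeps the minimal MSE, ties
to the lowest index; degenerate models are excluded with a warning.
Because selection uses the same concentrations later predicted, the
reported MSEs are in-sample — training and testing data coincide by
design, which flatters absolute MSEs but leaves the QM-vs-population
*comparison* fair since both priors face the same data.

## Synthetic cohorts

The generator emulates the study design: 4 g piperacillin every 6 h as
3-h infusions, six samples at 0.25/0.5/1/1.5/2/2.5 h after the sampled
infusion, truth drawn uniformly inside the parameter box, Gaussian noise
with the assay cubic's SD at the predicted concentration, negative draws
truncated at zero and counted.  Covariate cohorts draw CRCL uniformly in
30–150 mL/min — spanning the renal spread typical of an ICU pneumonia
cohort.  What it does *not* emulate: real covariate correlations,
time-varying renal function, sampling-time deviations, model
misspecification (the fitted structure is the generating structure), and
non-uniform parameter distributions.  Passing recovery tests therefore
demonstrate algorithmic correctness under the stated design, not clinical
performance on real patients.

## Problem sizes and defaults

| quantity | default | note |
|---|---|---|
| cohort | 12 subjects × 6 samples | study design |
| regimen | 5 × 4 g / 3 h infusions q6h | 4 pre-sampling doses |
| parameter boxes | study posterior ranges | per model type |
| initial grid | 100 Sobol points | seeded |
| cycle tolerance | 0.01 log-likelihood | `NPMLConfig.tol` |
| EM | gain 1e−8, ≤5000 iterations | per weight pass |
| quasi-models | 30 × 399 points | seeded batch |
| CRCL range (synthetic) | 30–150 mL/min | uniform |

Recovery and correlation tests in the suite run these sizes directly; the
property checks on the closed-form solutions use 200 random draws against
an adaptive ODE oracle at 1e−6 relative tolerance.

## Known limitations

Only the EM optimum on the final grid is guaranteed, not the global
nonparametric MLE; heavily multimodal five-parameter problems may need
more initial points or cycles.  The three proportional error settings are
a documented convention, not a reverse-engineered replica of any clinical
software's internals.  Shrinkage lacks a canonical nonparametric
definition; the posterior-variance ratio used here is stated explicitly
so its values are interpretable, but they are not comparable across
packages.  Time-varying covariates, oral absorption, nonlinear
elimination and three-compartment structures are out of scope.
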