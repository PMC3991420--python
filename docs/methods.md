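# Methods

## The model

Evidence unit: the mean change-score difference (treatment − control)
D̂ and its standard error, per trial contrast and instrument. For trial
*j* the stacked vector over reported cells is multivariate normal,
D̂_j ~ MVN(δ_j, S_j). Instruments a trial does not report are simply
absent from the vector; for a multivariate normal this restriction is the
exact missing-at-random marginalization, so no imputation is involved.

**Within-trial covariance.** Trials publish difference SEs but never
between-instrument correlations, so off-diagonals are assembled from an
external cross-sectional correlation matrix: S_rs = ρ_rs·se_r·se_s. This
reduced form equals the arm-level expression
ρ_rs(√(V_rT V_sT)/n_T + √(V_rC V_sC)/n_C) exactly when arm variances are
proportional across instruments; the arm-level route
(`covariance_from_arms`, `change_score_variance` with its conventional 0.5
baseline–follow-up correlation) is retained for data that include arm
summaries. Using a cross-sectional correlation for change scores is exact
under the conditional-independence assumption that baseline scores on one
instrument predict follow-up scores on another only through that
instrument's own baseline.

**Multi-arm trials.** Contrasts sharing a control arm are kept in one
block. Across contrasts h ≠ k the shared control contributes half of the
corresponding within-contrast term under equal allocation:
S[(h,r),(k,s)] = ρ_rs·se_hr·se_ks/2 (including r = s). Equivalently the
full block is a Kronecker-type product of the instrument correlation
structure with the 2×2 contrast matrix [[1, ½], [½, 1]], which keeps it
positive definite whenever the instrument submatrix is. Blocks are
checked for positive definiteness (relative eigenvalue tolerance 1e-10);
repair is never automatic — an explicit `shrink` argument scales
off-diagonal correlations toward zero when a user decides to.

**Treatment model.** On the reference instrument, δ_j1 ~ N(μ1, σ1²);
for a multi-arm trial the contrast effects are jointly normal with
between-contrast covariance σ1²/2 (homogeneous-variance convention).
All contrasts are treated as exchangeable active-versus-placebo effects;
no network meta-analysis across the active agents is attempted.

**Mappings.** Basic mappings β_{1→m} carry fixed signs taken from the
external correlations (`derive_signs`; the data cannot identify them and
the correlations leave no doubt). Magnitudes get half-normal(100) priors —
the zero-mean normal prior combined with a fixed sign and an absolute
value is exactly a half-normal, so the two readings of the sign constraint
coincide. Functional mappings are defined as ratios
β_{r→s} = β_{1→s}/β_{1→r} *per draw*, which makes invertibility and
transitivity machine-exact on every posterior draw; the tests assert this
over all pairs and triples. In the random-mapping model the hierarchy sits
on the trial-level basic mappings, β_{j,1→m} ~ N(β_{1→m}, β_{1→m}²φ²) with
one shared CV φ; trial-level functional mappings follow by ratio, the only
placement that preserves coherence within each trial. σ_{r→s} = |β_{r→s}|·φ
is evaluated at the current draw of β_{r→s}.

**Priors** (all configurable via `Priors`): μ1 ~ N(0, 100²),
σ1 ~ U(0, 10), mapping magnitudes half-normal(100), φ ~ U(0, 1). The
uniform upper bounds are hard truncations; if more than 1% of posterior
draws land within 1% of a bound the fit emits a prior-sensitivity warning.

## Sampling

The model is linear-Gaussian in the per-contrast effects δ given the
mappings, so δ is **marginalized analytically**: each trial contributes
MVN(μ1·B_j, S_j + σ1²·B_j C_j B_j') with B_j the cell-wise mapping design
and C_j the contrast prior correlation. The random-mapping model keeps
non-centered perturbations η_{jm} ~ N(0, 1) (β_{j,m} = β_m(1 + φη_{jm}))
for reported cells as latent variables. This removes the (σ1, δ) funnel
from the geometry the sampler sees: the fixed-mapping posterior is only
7-dimensional and the random-mapping one 31-dimensional on the bundled
network.

Sampling uses emcee's affine-invariant stretch move: 4 independent
ensembles (64 walkers fixed / 128 random by default) of 8000 steps, first
half discarded, thinned by 16. During development the differential-
evolution and snooker moves were found to truncate the σ1 tail on this
posterior even in the unimodal 7-parameter case (checked against the exact
marginal likelihood, verified by quadrature, and an independent Gibbs
implementation of the centered parameterization), so the stretch move is
used exclusively. Split-R̂ is computed across the independent ensembles
via ArviZ; effective sample sizes come from the integrated autocorrelation
time of the raw walker chains. The convergence gate (R̂ ≤ 1.05 and
ESS ≥ 400 per reported hyperparameter) flags a result rather than
discarding it.

After sampling, the per-contrast effects δ and per-cell predicted effects
are drawn from their **exact Gaussian conditionals** given each kept
hyperparameter draw, so the joint posterior is sampled exactly despite the
marginalization; trial-level mappings for instruments a trial never
reported are drawn from their hierarchical prior (posterior predictive).
All randomness flows from one user seed through `numpy.random.SeedSequence`
children; identical seeds give bit-identical results.

## Model criticism

Residual deviance D = Σ_j (D̂_j − δ_j)' S_j⁻¹ (D̂_j − δ_j), with S_j the
data covariance (not the marginal). D̄ is its posterior mean; adequate fit
means D̄ ≈ number of data points. pD is reported as D̄ − D(δ̄) with δ̄ the
posterior-mean predicted effects (plug-in); the half-variance variant is
computed alongside for reference. DIC = D̄ + pD. Per-trial deviances use
each trial's full block (one number per trial, the multi-arm trial
included as one 8-dimensional block); a trial is called adequate when its
posterior-mean deviance sits below the 97.5% quantile of χ²(n_points) — a
pragmatic reference, since the posterior-mean deviance is not exactly
χ² distributed. Residuals are observed minus posterior-mean predicted
effects, standardized by the marginal SE √S_mm (not the conditional), with
a per-instrument mean standardized residual for the systematic-bias check.
The sensitivity suite refits after scaling all off-diagonal correlations
by user-chosen factors (default ±10%) and reports percent changes.

## Synthetic-data generator

Individuals are simulated from the single-construct factor model:
Y_m = a_m + b_m(y + δ·treated) + c_m·ε_m with y, ε standard normal and ε
cross-correlated between instruments. Mappings are loading ratios, so the
generated truth is coherent by construction. Baseline and follow-up scores
share persistent person-level components of both y and ε with weight 0.5,
giving a baseline–follow-up correlation of 0.5 — matching the conventional
change-score assumption and making it testable — and implying change-score
correlations equal to cross-sectional ones. Random mappings are generated
by jittering the non-reference loadings multiplicatively, b_{jm} =
b_m(1 + φζ_{jm}), the exact generative analogue of the fitted hierarchy.

The default scenario mirrors the bundled network: 6 instruments, 8 trials
with the bundled reporting pattern including the three-arm trial, effects
μ1 = −2.3, σ1 = 0.42 (reference scale), φ = 0.13 and mapping magnitudes at
the values estimated from the ankylosing spondylitis synthesis; 140
patients per arm (trial sizes in this field run from a few dozen to a few
hundred per arm). Construct correlations (0.85, 0.83, 0.93, 0.88, −0.82,
−0.52) and cross-sectional SDs are chosen so instrument scales and the
implied correlation matrix resemble the external cohort; the ε
cross-correlations are back-solved from the target correlation matrix and
eigenvalue-projected to the nearest PSD correlation matrix. A compact
three-instrument, full-reporting scenario (`small_scenario`) drives the
recovery simulations.

What the generator does *not* emulate: bounded and skewed scales (scores
are unbounded normals), dropout and non-ignorable missingness (patterns
are fixed by design), follow-up-time heterogeneity, multiple treatment
classes with class-specific sensitivity, and multi-construct structure.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to their
violation.

## Numerical choices

- Positive definiteness: relative eigenvalue tolerance 1e-10 per block.
- Walker initialization is moment-based (BFS over the co-reporting graph
  multiplies mean effect ratios out from the reference) with ×(1 ± 0.2)
  jitter; initialization affects burn-in only.
- σ1 can be pinned near zero by setting `Priors(sigma1_upper=1e-3)`
  (used by the conjugate-limit test); the conditional-draw step guards
  1/σ² with a 1e-12 floor.
- The functional-mapping derivation guards against numerically zero basic
  mappings (impossible under the sign constraint; draws would be dropped
  with a warning).
- Deviance uses explicit inverses of the small (≤ 8×8) blocks.

## Problem sizes

Defaults fit the bundled dataset in roughly one to two minutes on one
core (4 × 8000 ensemble steps; ESS in the thousands). The test suite uses
shorter runs (2 × 2500 steps) for unit-level checks, the defaults for the
headline reproduction, and 50 replicates × (2 × 1200 steps) for coverage,
chosen so posterior-mean Monte-Carlo error is well inside the assertion
tolerances.

## Known limitations

- The multi-arm within-trial covariance uses the equal-allocation
  shared-control convention (half the within-contrast term); trials with
  strongly unequal allocation would need the arm-level route.
- Mapping signs must be supplied (or derivable from the external
  correlations); a zero correlation with the reference leaves the sign
  undefined and is refused.
- Instruments outside the co-reporting network are refused rather than
  imputed; mappings to instruments with no trial data cannot be derived.
- External correlations are treated as known constants; the sensitivity
  suite, not the likelihood, is the vehicle for their uncertainty.
- The fixed-mapping model's effective-parameter count is reported from
  this package's own deviance machinery; see the test suite for which
  published statistics are and are not reproduced from the printed data.
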