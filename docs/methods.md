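# Methods

## The analysis problem

A short-mission biomonitoring design observes a handful of subjects (default
four, with the roster's ages spanning 31–68 years and both sexes) at five
timepoints around a ~9-day exposure: 45 days pre-flight (`L-45`), flight
days 4 and 7 (`FD+4`, `FD+7`), and return days 1 and 7 (`R+1`, `R+7`).
Each blood draw yields DNA-methylation age estimates from a panel of 31
year-scale epigenetic clocks plus one pace-of-aging estimator, and predicted
fractions of 12 immune-cell types. With four subjects, classical
cross-subject inference is hopeless; the design instead treats the clock
panel as repeated measures of the same latent quantity and asks, per subject
and per timepoint pair, whether biological age moved.

## Age metrics

EAD subtracts chronological age directly. EAA and IEAA are residuals from
OLS fits pooled over all samples (all subjects and timepoints together):
with ~20 samples there is no room to stratify, and pooling matches the
convention of computing acceleration against a cohort-wide age/sex
expectation. The fitted coefficients and design rank are retained in an
audit table so alternative fitting windows can be compared downstream.

Two numerical details matter at this scale:

- **Simplex collinearity.** The 12 cell fractions sum to one, so the IEAA
  design drops one fraction (the last-listed by default). Residuals are
  mathematically invariant to which fraction is dropped — the span of
  {intercept, any 11 fractions} is the same — and a test asserts this.
- **Near-saturation.** With 20 samples and up to 14 design columns the IEAA
  fit has ~6 residual degrees of freedom. The implementation proceeds but
  emits a warning whenever residual df < 10; IEAA values from such fits are
  usable point estimates whose noise floor is visibly higher than EAA's.
  A constant sex column (single-sex cohort) or constant cell columns are
  dropped with a warning; a degenerate age column is an error, since
  acceleration against constant age is meaningless.

DunedinPACE never enters year-scale averages or the EAD/EAA/IEAA fits; it is
summarised as raw per-subject deltas against a chosen comparison timepoint
(both pre-flight- and in-flight-referenced deltas are produced, since the
pace trajectory is non-monotone).

## Inference

**Sign-flip permutation test.** For one subject and timepoint pair, the
vector of per-clock differences is reduced to its mean; the null is built by
assigning a random sign to each clock's difference and recomputing the mean,
10,000 times by default. The p-value is the plain proportion of permuted
means at least as extreme as the observed one — deliberately without +1
smoothing, so that a zero exceedance count is representable and reported as
`< 1/n_permutations`; the raw exceedance count is exposed so either
convention can be derived. Sign-flipping is exact when each clock's
difference is symmetric about zero under the null; it does not require
independence between clocks, which is the point — clock estimates are
strongly correlated and a test on 31 "independent" clocks would be wildly
anticonservative.

**Wilcoxon signed-rank.** Zeros are dropped (count reported), tied
magnitudes receive midranks. For n ≤ 25 the exact two-sided p is computed by
subset-sum dynamic programming over doubled midranks (exact even with ties);
beyond that, a normal approximation with continuity correction whose
variance is computed from the realised ranks. The implementation is verified
against scipy's exact method (tie-free case) and brute-force enumeration
(tied case).

**Mixed model.** Cohort-level effects come from
`value ~ timepoint + (1 | subject) + (1 | clock)` fitted by REML on the two
timepoints of each contrast. Crossed random intercepts are realised in
statsmodels' MixedLM as variance components within a single group; one test
cross-checks the fixed effect and residual variance against lme4. P-values
are Wald-z — the fit records the method, because degrees-of-freedom
corrections (Satterthwaite) are not available in the backend; with ~248
observations per contrast the Wald approximation is adequate for the fixed
effect, and all variance components are reported so users can judge
boundary fits (a component estimated at zero warns but does not fail).
Each pairwise contrast is fitted on its own two timepoints; a
whole-trajectory variant (all five timepoints against the reference) is
provided as an option.

**Leave-one-out sensitivity.** Every clock is excluded in turn and the mean,
Wilcoxon and permutation p recomputed; rows whose p crosses 0.05 relative to
the all-clock analysis flag clocks that single-handedly drive significance.
For panels of ≤ 20 clocks an exact-enumeration mode replaces the sampled
permutation p, making the flags deterministic.

**Multiple testing.** No correction is applied anywhere; all raw p-values
are emitted together with the comparison counts so any correction can be
applied downstream.

## Dominance analysis

The outcome is the per-(sample, clock) gap `EAA − IEAA`, stacked across all
clocks (a single R² per cell type across the panel); predictors are the
sample's 12 centred cell fractions repeated across its clock rows. All
2¹² − 1 = 4,095 subset regressions are computed from precomputed
cross-products; the general dominance weight of a predictor is its
incremental R² averaged first within, then across conditioning-subset
sizes. Weights sum to the full-model R² by a telescoping identity, asserted
to 1e-8 on every fixture and verified to 1e-10 against a brute-force
all-subsets OLS oracle at p = 5. Conditional (per-size) and complete
(pairwise) dominance matrices are emitted alongside.

Because the 12 fractions sum to one, the full predictor set is singular:
subsets containing all 12 are solved by minimum-norm least squares (R² is a
projection and remains well defined), with a warning. Rank below p − 1 —
collinearity beyond the simplex — is an error naming the offending columns.

One structural property deserves emphasis: when a single cell type truly
drives the gap, the other eleven centred fractions jointly reconstruct its
signal exactly (they sum to its negative), so averaging over subset sizes
caps the driver's share of the explained variance near one half, with the
remainder spread thinly over the passive cells. Dominance output on
compositional predictors should therefore be read as a ranking with
relative magnitudes, not as an exhaustive attribution; the driving cell in
simulations ranks first in every replicate and carries several times the
weight of any passive cell, but cannot approach 100% of R².

## Clock engine and deconvolution

A clock is applied as `age = intercept + Σ coef_j · beta_j`. Model CpGs
missing from the beta matrix are imputed from a user-supplied per-CpG
default table (e.g. tissue-specific medians) when available, otherwise
dropped; a coverage report counts measured/imputed/dropped CpGs, and the run
errors when more than `max_missing_fraction` (default 10%) of a model's
CpGs are neither measured nor imputable. A post-transform hook exists for
clocks needing a nonlinear output map; none ships enabled.

Cell fractions are estimated per sample by non-negative least squares
against pure-cell reference profiles over the shared CpGs, then renormalised
to sum to one. NNLS-plus-renormalisation was chosen over a fully constrained
quadratic program: it is the common practice for this reference family,
dependency-light, and empirically indistinguishable on the noise levels of
interest (per-cell RMSE 0.3% at beta-noise SD 0.02 on synthetic mixtures,
versus the few-percent errors typical of experimental references). The
per-sample residual norm is reported; a rank-deficient reference errors with
the collinear columns named.

## The synthetic cohort generator

The generator exists so every stage can be tested against known truth. A
year-scale clock value is

    value(c,i,t) = a_c + b_c·age_{i,t} + s_c·sex_i + u_i + γ_c·δ_t
                   + Σ_k w_{c,k}·(π_{i,t,k} − π̄_k) + ε,  ε ~ N(0, σ_c²)

with chronological age advancing across timepoints by calendar offsets
(−45, +4, +7, +10, +16 days from launch; ages are specified at the
pre-flight draw), a subject intercept u_i ~ N(0, σ_u²) drawn once per
cohort, a per-timepoint acceleration pulse δ_t (zero at the reference
timepoint by convention), and cell effects entering through fractions
centred at the cohort mean so that δ and w are separately identifiable.
Cell compositions are Dirichlet draws around a 12-cell baseline
(neutrophil-dominated, as in blood) with designated cell types shifted on
the logit scale per timepoint and the row renormalised, keeping every sample
exactly on the simplex.

Defaults are the study conditions: four subjects with the mission roster's
ages and sexes; δ = (0, +0.76, +1.91, −1.57, −0.30) years across the five
timepoints, reproducing a rise peaking at flight day 7, an overshoot below
baseline after return, and near-recovery a week later; σ_u = 1 yr; per-clock
noise σ_c = 1 yr; slopes b_c in [0.85, 1.10] (all year-scale clocks track
age strongly); cell-sensitivity weights loading mainly on regulatory T,
naive CD4 T and neutrophil fractions with heterogeneous signs across clocks
(some clocks read cell shifts as acceleration, others as deceleration), at
a default scale of 10 years per unit fraction; and logit shifts that move
Treg/CD4nv down in early flight, up at flight day 7 and down after return,
with neutrophils mirroring. The pace clock is generated by the same
expression on its own scale (intercept 0.65, slope 0.006/yr, noise 0.02,
acceleration multiplier 0.01). Where the emulated design documents no value
(clock intercepts, sensitivity weights, Dirichlet concentration 300), the
defaults were chosen once as field-plausible and are not calibrated against
any test outcome. The 12 cell labels follow the extended leukocyte panel
and are overridable, as is everything else.

Reproducibility: each generator stage draws from its own RNG stream derived
from the master seed by stage name, so adding a stage never perturbs
existing draws, and identical seeds give byte-identical cohorts.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: array-level artefacts (probe noise structure,
batch effects, normalisation residue); non-linear clock behaviour; diurnal
oscillation of epigenetic age; correlation between the deconvolution CpGs
and clock CpGs (in real data the cell fractions are estimated from the same
methylation profile as the clocks, which biases IEAA toward zero — the
generator's fractions are exact); and any Earth-bound control group.
Recovery of a simulated δ pulse demonstrates that the estimator chain is
unbiased under the model, not that real mission effects are identifiable
from four subjects.

## Problem sizes used in validation

Simulation-based checks run at the design scale (4 subjects × 5 timepoints
× 31 clocks) with seed counts chosen for stable Monte-Carlo estimates:
100 seeds for effect-recovery and attenuation means, 50 REML fits for the
mixed-model contrast, 4,000 replicates for the null calibration of the
permutation test (band = the 95% binomial interval around 0.05 for that
count), and 400 replicates for the p-value uniformity check. The
attenuation check uses a cell-sensitivity scale of 40 yr/unit fraction so
that the cell-mediated signal dominates the OLS noise floor — the mechanism
being demonstrated — and measures change magnitude as the mean over clocks
of the absolute per-clock change, since the default sign-heterogeneous
sensitivities make the signed cross-clock mean cancel by construction.

## Known limitations

- Wald-z p-values for mixed-model contrasts are anticonservative for very
  small group counts; with four subjects the subject-variance component is
  itself poorly determined (its REML estimate tracks the realised
  four-draw variance, not the population value).
- The sign-flip test conditions on the observed difference magnitudes; its
  power against alternatives that change clock dispersion without moving
  the mean is nil by design.
- IEAA inherits the deconvolution's errors; with predicted (rather than
  measured) cell fractions, cell-adjustment is partial and the EAA/IEAA
  contrast is a lower bound on cell mediation.
- Dominance weights on compositional predictors are structurally diluted
  (see above); ranks are stable, absolute shares are not interpretable as
  "percent of variance due to this cell alone".
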