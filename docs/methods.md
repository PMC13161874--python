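# Methods

This note documents the models, algorithms, defaults, and design
decisions implemented in `strokeconn`, and what the synthetic-data tests
do and do not establish.

## Data model and region aggregation

The unit of raw data is a *directed link*: a Granger-causal connection
detected between two of 84 cortical patches (ico-1 tiling, ids
`L00`–`L41`, `R00`–`R41`) in one 60-s resting-state segment ("trial") of
one subject at one of two visits.  Patches map to 22 anatomical regions
(11 per hemisphere) through a declarative atlas table.  The published
grouping of Desikan–Killiany labels into 11 regions is not available as a
table, so the packaged atlas (`src/strokeconn/data/patch_atlas_84.tsv`)
is a plausible reconstruction in which only the frontoparietal region
(FPC = precentral + postcentral + paracentral) and the medial temporal
labels are fixed by construction; any file with the same schema can be
substituted.  Every analysis below is invariant to the within-region
patch assignment because only region-level counts are consumed.

Before aggregation, subjects with a right-hemisphere lesion have all
patch ids hemisphere-flipped (an involution), so that *left =
ipsilesional* holds for every subject.  Aggregation sums links into one
directed 22×22 matrix per subject × visit × trial (row = source, column =
target; the diagonal holds within-region links).  The frontoparietal
view pools these into 4×4 over {Ipsi FPC, Ipsi ALL, Contra FPC,
Contra ALL}, where "ALL" is the union of the 10 non-FPC regions of a
hemisphere.  All three steps conserve total link counts, which the test
suite asserts.

## The zero-inflated Poisson mixed model

Link counts for a region pair are modelled as

    y_ij ~ pi * delta_0 + (1 - pi) * Poisson(lambda_ij)
    log lambda_ij = x_ij' beta + u_i,     u_i ~ N(0, sigma_u^2)

with `i` indexing subjects and `j` their trials.  The zero-inflation
mass `pi` is a single constant (intercept-only on the zero process): it
represents trial-level detection failure of the upstream detector at low
SNR, which is not obviously covariate-linked, and the random intercept
enters the Poisson log-rate only.  Parameters are estimated by direct
maximization of the marginal likelihood; the 1-D random-effect integral
per subject is evaluated by adaptive Gauss–Hermite quadrature (default
15 nodes) with the nodes re-centred at the per-subject posterior mode.
One quadrature node gives exactly the Laplace approximation, used as the
fast mode inside permutation loops; the reported coefficient tables come
from full-quadrature fits (see "Symmetry of the test statistic" below
for how the permutation test treats the observed data).  Internally the parameters are
`[beta, log sigma_u, logit pi]`, bounded to `sigma_u in [1e-3, 5]` and
`pi in [1e-4, 0.95]`.

Two optimizer paths share this objective:

- **Batched damped Newton** (`fit_zip_batch`): fits B models with a
  common observation layout simultaneously (one model per region pair,
  or per permutation × pair).  Gradients are analytic with quadrature
  nodes frozen within an optimizer round; nodes are re-adapted between
  rounds until the marginal log-likelihood is stable to 1e-6 (relative)
  or the parameters stop moving (below 1e-4 per round — the Laplace
  objective value jitters slightly as nodes re-centre even at a
  parameter fixed point).  The search direction is a BHHH step (inverse
  empirical Fisher from per-subject score outer products — positive
  definite, hence always ascent, and free of extra likelihood
  evaluations) when more than one node is used; in the single-node mode,
  where the score outer product is a poor curvature proxy, it is a
  modified Newton step from a finite-difference Hessian with clamped
  eigenvalues.  A backtracking line search guards every step, a trust
  region caps per-step moves of the variance and zero-inflation
  parameters, and items that fail to converge in the single-node mode
  are automatically retried with 7 nodes.  Every item is initialized
  from its own data (Poisson-IRLS coefficients, observed zero excess,
  method-of-moments intercept spread), which keeps permutation refits
  statistically interchangeable with the observed refit.  This vectorization is what
  makes ~3,600 refits per permutation dataset run in a few seconds on
  one CPU, and replaces process-level parallelization of the permutation
  loop (shuffles are pre-drawn from a `SeedSequence`, so results are
  independent of chunking).
- **Single-model quasi-Newton** (`fit_zip_glmm`): L-BFGS-B with node
  re-adaptation at every evaluation.  Heavily structured models (e.g. a
  deliberately misspecified intercept-only fit across strongly
  heterogeneous pairs, which stepwise selection must evaluate) sit in
  ill-conditioned likelihood valleys where the batched Newton crawls;
  the quasi-Newton path handles them robustly.  In Laplace mode the
  single-node posterior score is not the gradient of the Laplace
  objective, so this path falls back to finite-difference gradients
  there.

Starting values: Poisson-IRLS coefficients for `beta`, the observed zero
excess over the Poisson fit for `pi`, and a method-of-moments
between-subject spread for `sigma_u`.  Standard errors come from the
observed information (central differences of the gradient at the
optimum; value-based second differences in single-fit Laplace mode).
Non-convergence and all-zero responses are recorded states
(`converged=False`, coefficients missing), never exceptions — the
permutation and stepwise-selection loops depend on that contract.

Validated reductions: with `pi=0, sigma_u=0` the fit reproduces a
statsmodels Poisson GLM (coefficients, SEs and log-likelihood to ~1e-5);
the quadrature marginal matches a 10^6-point trapezoid integral to 1e-6;
on data simulated from the model at n = 50 subjects × 4 trials the slope
bias is below 0.002 and 95% Wald coverage is ~93%.

## nbs-TFCE and max-statistic permutation inference

The per-pair fixed-effect coefficient of interest forms a signed
directed network.  For each sign direction (the negative direction
enhances the negated matrix), the enhanced score of cell `e` is

    score(e) = sum_{t=1..n_steps} extent(cluster_t(e))^E * h_t^H * dh

with `h_t = t*dh`, `dh = h_max/n_steps`, and `h_max` the largest
sign-adjusted coefficient of the network at hand; `dh` enters explicitly
so scores are comparable across permutations.  Defaults `E = 0.75`,
`H = 3.25`, `n_steps = 100`.  A cluster at height `h` is a connected set
of supra-threshold cells, where two cells connect when they share an
endpoint region — edge direction is ignored when forming clusters (the
natural reading of graph-component clustering on a directed network; the
component finder is isolated behind `supra_threshold_components` so a
direction-respecting variant could be swapped in).  Self-loops attach to
their region.  An isolated edge with coefficient `c` converges to
`c^(H+1)/(H+1)` as the grid refines; the implementation is verified cell
by cell (1e-10) against a brute-force loop over thresholds with
exhaustive union-find clustering, and computes identical output by
grouping grid steps between supra-threshold set changes.

Inference shuffles the subject-level covariate across subjects (each
subject's trials keep the shuffled value), refits every pair model per
shuffle in the Laplace fast mode, enhances each shuffled network
identically, and records the family-wise maximum enhanced score over
both sign directions and all cells.  The two-sided per-cell Monte-Carlo
p-value is the smoothed estimator `(1 + #{null max >= score}) /
(1 + n_perm)`, never zero with finite permutations.  Cells whose fits do
not converge are treated as coefficient 0 (they cannot contribute), and
the per-permutation non-convergence count is logged.

**Symmetry of the test statistic.**  The observed enhanced scores are
computed by running the *unshuffled* covariate ordering through exactly
the same batched pipeline as the shuffles — same fast-mode fits, same
per-item cold initialization, same enhancement — by prepending the
identity permutation to the shuffle list.  (Warm-starting the refits
from the observed-data fit was evaluated and rejected: because the
start point is derived from the unshuffled covariate, shuffled refits
converge slightly less completely than the observed one, which shrinks
null maxima and measurably inflates the family-wise error.)  Any systematic difference between fitting modes or
optimizer budgets would otherwise leak into the comparison of observed
scores against null maxima and bias the family-wise error; with one
shared code path, observed and null statistics are exchangeable under
the null by construction.  The coefficient table reported alongside the
p-values still comes from full-quadrature fits.

**Cell inclusion rule.** A pair enters the analysis only if its count
vector has at least `min_nonzero = 5` nonzero trials.  With very sparse
matrices, slopes for near-empty cells are unidentifiable and their wild
maximum-likelihood estimates would dominate every null maximum,
destroying power without helping error control.  Because the rule
depends only on the counts — never on the covariate — the same cells
enter the observed and every permuted analysis, and exchangeability
under the null is untouched; calibration is confirmed by simulation
(family-wise error within the binomial band around 5% over 200 null
datasets).

## Frontoparietal analysis

`build_model` reconstructs a buildmer-style stepwise procedure: starting
from the intercept + random-intercept model, candidate fixed-effect
terms are added one at a time, each step taking the eligible candidate
(hierarchy respected: interactions only after their sub-terms) with the
largest marginal log-likelihood gain; candidates whose fit fails to
converge are skipped.  Afterwards, terms are pruned backward, repeatedly
removing the least significant removable term with likelihood-ratio
p ≥ 0.05 until all remaining terms are significant.  The random
intercept is never pruned, and the full decision trace is recorded and
replayable.  The default maximal model is
`count ~ pair × visit × moca + age + sex + race + education_years +
lesion_hemisphere + (1|subject)` — the pair factor has 16 levels (the
4×4 ordered pairs), `moca` is the score at the row's visit, and the
confounder set follows the study design; the exact published maximal
formula is not available, so this reconstruction is user-overridable.

Group contrasts: subjects are grouped by their visit-1 MoCA against the
clinical cutoff of 26 (scores below 26 are "abnormal").  MoCA stays
continuous in the model; each group is represented by its median score
at the contrasted visit, and the contrast per ordered pair × visit is
the difference of linear predictors (log expected count) at those
representative scores, with a delta-method SE from the fixed-effect
covariance.  Adjustment is Holm or Bonferroni over the estimable
pair × visit family (32 comparisons by default); non-estimable rows are
flagged and excluded from the family.  Marginal predicted counts
(averaging over the random intercept) are
`(1 - pi) * exp(x'beta + sigma_u^2/2)` with delta-method SEs.

`visitwise_increase_test` fits `count ~ visit + (1|subject)` per ordered
4×4 pair and Bonferroni-adjusts the two-sided Wald p-values over the 16
pairs; a pair counts as a significant increase when the visit-2
coefficient is positive and adjusted p < 0.05.  Subjects lacking either
visit are excluded with a warning.

## Synthetic-data generator

The generator emulates the *output* of the upstream connectivity
detector, not the MEG signal chain: for every subject × visit × trial
and ordered region pair it draws a zero-inflated Poisson count with

    log lambda = baseline + u_subject + visit2_shift * [visit = 2]
                 + sum_k slope_k * (covariate_k - cohort mean)

in ipsilesional-aligned space, then assigns links uniformly to patch
pairs within the region pair and reflects right-lesion subjects' patch
ids into anatomical space (exactly undoing the downstream mirroring).
Zero inflation acts at the pair × trial level — an entire pair's count
in a trial is zeroed — matching the trial-level hit-rate interpretation.
Covariates are centred at the cohort mean so planted slopes do not move
the baseline.

Cohort marginals default to the study population: age ~ N(62.4, 13.9),
57% male, 39% Black, education ~ N(13.7, 2.4) years, 47% left-hemisphere
lesions.  Visit-1 MoCA is a discretised normal truncated to [0, 30] with
mean 24 and SD 3 — chosen so both sides of the clinical cutoff of 26 are
populated in a minor-stroke cohort; visit-2 MoCA adds a rounded
N(1.5, 2) improvement increment (positive mean: most patients improve).
Count-model defaults: `baseline_log_rate = -1.9` (≈ 0.15 links per
ordered pair and trial, ≈ 70 links per trial across 484 pairs — sparse
matrices with a visible zero excess), `subject_sd = 0.3`,
`zero_inflation = 0.2`, `visit2_log_increase = 0.5`, and two trials per
visit (one per 60-s segment; whether the upstream detector is run per
segment or pooled is unspecified upstream, so one link set per segment
is the default).

What the generator does *not* emulate: spatial correlation between
neighbouring pairs, covariate-dependent zero inflation, detector
false-positive structure, within-visit nonstationarity, or any
relationship between lesion volume and connectivity.  Passing tests
therefore demonstrate that the *statistical machinery* is correct and
calibrated under the stated model, not that the model captures every
property of real MEG link data.

## Problem sizes and profiles

Two profiles are exercised routinely.  The *study-scale* profile mirrors
the cohort design (49 subjects × 2 visits × 2 trials, 22 regions, 1000
permutations) and is the default of the command-line pipeline.  The
*desk-scale* profile used by the simulation studies in the test suite
and the acceptance script runs 6 pseudo-regions, 20 subjects,
`baseline_log_rate = 0` (≈ 1 link per pair and trial) and 49–99
permutations; calibration and power studies use 40–200 replicate
datasets.  The cluster-power comparison plants a slope of 0.2 per MoCA
point, chosen a priori so that single-edge detection power is interior
(neither floor nor ceiling) at this profile, which is what makes the
connected-versus-isolated comparison informative.

## Numerical and reproducibility notes

- All randomness flows through `numpy` `Generator`/`SeedSequence`;
  identical configuration and seed give byte-identical output files,
  including permutation p-values.
- TFCE uses `>=` at each threshold, so the maximal cell is counted at
  the top step; the brute-force oracle in the tests uses the same rule.
- Monte-Carlo p-values use the `(1+B)/(1+N)` estimator.
- Likelihood-ratio tests use the chi-square reference with df = the
  parameter-count difference; identical models give statistic 0, p = 1.
- Degenerate inputs: all-zero responses and constant covariates yield
  flagged non-converged fits, not errors; unknown patches, regions, or
  subjects raise keyed lookup errors naming the offender.

## Known limitations

- The published Monte-Carlo p-values and contrast estimates from the
  patient cohort are not reproducible here because the patient data are
  not deposited; the pipeline reproduces the *procedure* and validates
  it on synthetic data built to the same design.
- The atlas is a reconstruction (see above); analyses that depend on the
  exact patch-to-region assignment beyond FPC membership should supply
  their own table.
- Cluster adjacency ignores edge direction; a direction-respecting
  variant would require only replacing `supra_threshold_components`.
- The zero process is covariate-free by design; detectors whose hit rate
  varies with the covariate of interest would violate this assumption.
- Coefficient networks are enhanced on the raw coefficient scale (not
  z-scores), following the described procedure; cells with very
  different SEs therefore contribute on different scales, which the
  max-statistic null accounts for but which can cost power when count
  density is very heterogeneous.
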