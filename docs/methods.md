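# Methods

`alongtract` implements a statistical pipeline for studying how white-matter
tract microstructure matures along the length of a tract in a cross-sectional
developmental cohort, and how the maturation of a tract's superficial ends
relates to the cortical hierarchy of the regions it connects. This note
documents the models, the estimators, the synthetic data they are validated
on, and the numerical choices; it is the package's own account of its
science, not a results report — every empirical number mentioned here is
computed by the test suite or by `scripts/acceptance.py`.

## Data model

The unit of analysis is a **tract profile**: one scalar microstructure
metric (canonically mean diffusivity, in units of 1e-3 mm²/s) sampled at 100
equidistant nodes (ids 0–99) along a tract's core, per subject. Covariates
per subject are age (years), sex (coded 0/1), in-scanner head motion (mean
framewise displacement, mm) and optionally an acquisition site. The five
end-most nodes at each end are excluded before analysis to limit
partial-volume effects, so the retained ids are 5–94; node ids are never
renumbered, and trimming is keyed to original ids, which makes it
idempotent. "Superficial" refers to the retained nodes nearest the cortical
ends (5–9 and 90–94), "deep" to nodes around the tract midpoint (46–55 at
the default bin size) — not to U-fibers.

Tract-to-cortex assignment is consumed as a table of termination
probabilities per (tract, end, parcel); parcels with probability ≥ 30% form
the endpoint (a lower per-tract override, e.g. 5%, supports tracts that are
hard to segment). Each parcel carries a hierarchy rank on the
sensorimotor-association (S-A) axis and a unit-sphere centroid used by the
spatial null.

## Node-wise developmental models

Each node of each tract gets a generalized additive model

    metric ~ s(age) + sex + motion

where `s(age)` is an **unpenalized 1-D thin-plate regression spline** with
maximum basis dimension k = 3. The basis follows the standard eigen-truncated
construction: radial basis |a − a*|³ at knots placed at the unique observed
ages (quantile-subsampled above 200 knots), the k leading eigenvectors of
the radial matrix, and the constraint null space {1, age} absorbed, leaving
a centered linear-age column plus k − 2 wiggly columns. Because the smooth
is unpenalized, the fit is exactly ordinary least squares on the expanded
design, so adjusted R², partial-F tests and coefficient covariances are the
exact OLS quantities (verified in tests against a generic least-squares
oracle and against mgcv's `s(age, k=3, fx=TRUE)`).

Per node the pipeline reports:

* **ΔR²adj** — |R²adj(full) − R²adj(reduced)| where the reduced model drops
  both smooth-age columns and keeps intercept, sex and motion. This is the
  age-effect magnitude. Significance is the partial-F (ANOVA) comparison of
  the nested models; Benjamini–Hochberg FDR is applied per tract (the
  family is configurable).
* **Fitted trajectory** — fitted metric at 200 equally spaced ages between
  the sample minimum and maximum, with sex and motion at their sample means
  (population-averaged prediction; the reference values are configurable).
* **Derivative band** — the first derivative of the age smooth by central
  finite differences (step h = 1e-3 × age range; quadratic error far below
  band width at k = 3), with a simultaneous 95% confidence band: draw
  coefficients from N(β̂, V̂β) — exact for OLS — and use the 95% quantile of
  the grid-wise maximum standardized deviation as the critical multiplier.
  Within a tract all nodes share one design, so the standardized max-t
  multiplier is node-independent and is computed once per tract from shared
  draws; this is an exact batching, not an approximation.
* **Age of maturation** — the first grid age (on the same 200-point grid;
  resolution ≈ 0.075 y for an 8–23 y window) at which the simultaneous band
  contains zero. If the band excludes zero everywhere the node is still
  developing at the end of the window and the age is ceiling-set to the
  sample maximum with a `matured = False` flag. The scan is sign-agnostic,
  so increasing metrics (e.g. neurite density) need no special casing.
* **Coefficient of variation** — per-node sd/mean across subjects, with
  deep/superficial bin means, to check that larger superficial age effects
  are not an artifact of larger superficial variability.

## Enrichment testing (adapted NEST)

Whether age effects concentrate superficially is tested with a
network-enrichment-style statistic adapted to autocorrelated profiles.
Background nodes (superficial ∪ deep) are ranked by ΔR²adj descending, ties
broken by node id; a GSEA-type running sum adds `stat/Σ_set stat` on set
members and subtracts `1/|background∖set|` otherwise, and the enrichment
score (ES) is the signed maximum-magnitude excursion. The running sum is
evaluated at the boundaries of tied-statistic blocks, which makes the score
exactly invariant to relabeling equal-stat nodes. The weighted (exponent-1)
form is the default for deep-vs-superficial contrasts; the end-vs-end
contrast uses the unweighted (exponent-0) form, under which swapping end
labels flips the score sign exactly. The statistic is pluggable.

The null permutes **participant age only** — profiles, sex and motion stay
fixed — preserving the spatial structure of the data. Each permutation is a
full refit: permuting ages permutes the rows of the age-basis columns (the
knots depend only on the multiset of ages), and every background node is
re-estimated by OLS against the permuted design. One-sided
p = (1 + #{ES_null ≥ ES_obs})/(1 + n_perm), floored at 1/(n_perm + 1);
end-vs-end contrasts are two-sided. Numerical ties (scores equal in exact
arithmetic but separated by float rounding, e.g. saturated scores of 1) are
counted as exceedances — the conservative direction. Default n_perm is
10,000; permutations are drawn from one stream independent of the contrast
definition, so bin-size sensitivity rows at the default size reproduce the
default test exactly under the same seed. Deep/superficial bins recenter
with bin size b as 2b nodes symmetric about the midpoint and b nodes
abutting each trim boundary.

The permutation null is exact under age exchangeability (no age effect at
any node). When a global age effect is present but equally large at all
nodes, the test is conservative (measured empirically in the acceptance
battery); it does not inflate.

## Endpoint summaries and hierarchy alignment

Developmental measures at the five most superficial retained nodes per end
are averaged into endpoint summaries; an endpoint's S-A rank is the
unweighted mean of its parcels' ranks (termination-probability weighting is
available behind a flag). An endpoint is `matured` only if all five
constituent nodes matured within the window. Downstream quantities:

* Pearson correlation between endpoint maturation age and endpoint mean S-A
  rank, in both all-endpoints and matured-only variants;
* per-tract ΔAge and ΔS-A rank (absolute between-end differences), tracts
  split into large/small ΔS-A groups (default threshold 100 on a
  HCP-MMP-scale rank range; the pipeline uses half the atlas rank range so
  smaller synthetic atlases split sensibly), and a one-tailed Welch t-test
  of ΔAge (large > small). Welch rather than pooled t because group
  variances have no reason to match; the spin null makes the choice mostly
  immaterial;
* a parcel-level map assigning each endpoint parcel the across-tract mean
  of superficial maturation ages; parcels without a termination are flagged
  absent, never zero-filled, and a parcel serving both ends of a tract
  contributes both values.

## Spin-based spatial nulls

Significance of all hierarchy-alignment quantities uses spin tests: random
proper rotations of the parcel sphere (uniform on SO(3); the left
hemisphere uses the right rotation conjugated by the sagittal reflection),
with each original parcel re-assigned the value of the nearest rotated
centroid in its hemisphere (rotate-parcellation convention; many-to-one
assignment accepted). Spinning the rank map while holding the data-derived
map fixed yields nulls that preserve spatial autocorrelation. Endpoint-level
tests recompute each endpoint's mean spun rank per spin; the ΔAge contrast
spins the aggregated parcel-level age map and recomputes endpoint means,
ΔAge and the group t per spin, excluding (and counting) endpoints whose
parcels all lose their value under a spin. Correlations are two-sided;
t contrasts one-tailed where a direction is prespecified; the tail is always
recorded. All tests consuming one SpinSet share the same null draws, and a
fixed seed fixes the whole SpinSet.

## Multi-site harmonization

An optional ComBat-style mean/scale stage precedes modeling when data come
from multiple sites. Per node, a pooled OLS model with the same unpenalized
age smooth plus sex, motion and site indicators estimates site location
shifts (centered to the subject-weighted mean) and site scales (residual-SD
ratios); per-node parameters are shrunk toward their across-node mean with
moment-matched empirical-Bayes priors (normal on shifts, inverse-gamma on
squared scales). The correction subtracts shift and covariate prediction,
divides by scale, and adds the prediction back, preserving the nonlinear age
trend. A single-site cohort makes the stage a warned no-op. Harmonization is
fit per tract; covariance-stage batch correction is not implemented. The
model stores per-subject preserved predictions, so applying it is restricted
to the cohort it was fitted on.

## Synthetic cohorts and ground truth

The generator emulates the tables the pipeline consumes with a known
generative process:

    m(s, v) = asym_v + A_v exp(−(age_s − age_min)/τ_v)
              + b_sex sex_s + b_mot motion_s + site offset + ε,
    ε ~ N(0, (noise_sd × site scale)²)

* Ages uniform on the study window (default 8–23 y, the typical span of a
  developmental cohort); sex Bernoulli(½); motion truncated-lognormal in
  (0, 1] mm, matching the usual exclusion ceiling of 1 mm mean framewise
  displacement; sites assigned round-robin.
* The amplitude profile A_v is a smooth U-shape: `amplitude_deep` (default
  0.025) at the midpoint rising to `amplitude_superficial` (default 0.10)
  at the ends — a 4:1 superficial:deep gradient whose implied superficial
  ΔR²adj at the default noise (0.03) is in the 0.2–0.45 range reported for
  real cohorts.
* An exponential-decay trajectory was chosen over logistic decay: one
  interpretable timescale and an analytic derivative, with no testable
  benefit from extra parameters.
* Geometry: parcels on a Fibonacci lattice per unit hemisphere sphere (left
  = sagittal mirror of right). The hierarchy field is a weak principal axis
  plus several localized bumps of alternating sign; the bumps are essential,
  because a purely axial field is rotation-degenerate — every spin of a
  single-axis gradient carries the same low-to-high arrangement, so spun
  endpoint ranks reproduce observed contrasts and spin tests lose all
  power. The real S-A axis is likewise multi-peaked on the inflated sphere.
  Ranks 1..n_parcels are the rank order of this field.
* Each tract has two disjoint 3-parcel endpoint blocks chosen by rank
  position; tract ids carry `_homotopic` (ends at adjacent ranks) or
  `_heterotopic` (ends separated by more than half the rank range)
  suffixes, and the non-special tracts alternate between the two kinds so
  ΔS-A groups are always populated.
* The timescale τ_v is `tau_fast` at deep nodes and blends toward the value
  implied by the adjacent endpoint's normalized rank
  (`tau_fast → tau_slow`, defaults 2–6 y) at superficial nodes; two tracts
  sharing an endpoint get identical superficial timescales at that end.
* True maturation age is analytic: the age where the noiseless derivative
  magnitude A_v/τ_v · exp(−(a − age_min)/τ_v) falls below a detectability
  criterion c, clamped to the age window. The default c is **the slope the
  fitted simultaneous band is expected to resolve**: the median half-width
  of the 95% simultaneous derivative band computed analytically on an
  idealized design (uniform age quantiles, same k = 3 basis, the
  sqrt(χ²₂(0.95)) bound on the max-t multiplier), scaled by the configured
  noise and sample size. This makes "the band includes zero" a recoverable
  event in simulation; the criterion is exposed in the configuration for
  users who want a fixed slope instead.

What the generator does **not** emulate: image formation, streamline
geometry, heteroscedastic or spatially correlated noise within a profile
(noise is Gaussian and homoscedastic per site — the noise model of real
tract profiles is unknown, and this choice is an assumption), missing nodes
or failed segmentations (treated as I/O validation), and covariance-scale
site effects. Passing tests therefore establish correctness of the
statistics under the stated generative model, not robustness to real-data
pathologies.

## Validation battery and problem sizes

`alongtract.experiments` holds the self-contained studies that both the
test suite and `scripts/acceptance.py` run; sizes were chosen so the whole
battery completes in a few minutes on one CPU:

* gradient recovery: n = 250, 3 tracts; enrichment calibration: 300
  replicates at n_perm = 199 under the exchangeable (zero-amplitude,
  constant-τ) null, power: 100 replicates under the 4:1 gradient;
* maturation recovery: n = 400, noise 0.015, τ ∈ [0.8, 6] (true plateau
  ages span ≈ 12–22 y); band coverage: 500 replicates with a linear-in-age
  truth (inside the basis span, so the band targets the true derivative
  without smoothing bias);
* alignment recovery: 50 replicates, 10 tracts, 1,000 spins; alignment
  null: 200 replicates with constant τ; ΔAge contrast: 50 power and 200
  null replicates, 8 tracts, 500 spins; end-contrast dichotomy: 100
  replicates at n = 300 with end timescales 1 y vs 3 y — a 3:1 ratio chosen
  so a meaningful share of each end's change falls inside the sampled
  window, which is what the end contrast can detect (timescales ≫ the
  window leave nearly equal within-window variance at both ends and carry
  no end contrast).

## Known limitations

* **Maturation-age compression.** The k = 3 (2-df) smooth cannot represent
  fast exponential decay (τ ≲ 2 y over a 15-y window): the fitted
  derivative stays nonzero through mid-window, so estimated maturation ages
  compress toward the middle of the window even at low noise. Rank order is
  preserved (Spearman against analytic truth ≈ 0.95 in the recovery study)
  but absolute errors reach 2–3 y at the fast end; identical behavior is
  obtained with mgcv's `s(age, k=3, fx=TRUE)`, so this is a property of the
  estimator, not the implementation. Consumers should treat maturation ages
  ordinally across regions rather than as calibrated plateau times.
* The end-vs-end enrichment contrast detects differences in *within-window*
  explained variance; ends whose decay completes before the window or far
  after it are indistinguishable.
* The permutation null is exact only under age exchangeability; with a
  uniform global age effect the test is conservative.
* ΔR²adj is concave in amplitude and noisy at n in the low hundreds, so the
  per-node age-effect profile correlates with the generating amplitude
  profile imperfectly (r ≈ 0.86–0.95 per tract at n = 250).
* Spin tests assume endpoint/rank structure is not rotation-degenerate;
  with hierarchy maps that are a pure axis gradient the spin null is as
  wide as the signal (see the geometry discussion above).
* The harmonization stage corrects means and scales only, and its
  empirical-Bayes priors are moment-matched rather than estimated by the
  full iterative scheme.
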