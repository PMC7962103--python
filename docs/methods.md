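# Methods

This note documents the measurement model, its parameters and numerical
conventions, what the synthetic data emulate, and the design choices made
where the underlying scoring protocol leaves room.

## Cell classification

A detected cell is a centroid (µm, image convention: origin top-left,
y down), a nucleus area (µm²) and two stain intensities (unitless,
optical-density-like): the red chromogen marking nuclear BAP-1 and the
hematoxylin counterstain.  Classification is deliberately minimal,
mirroring routine chromogenic IHC review:

* **Per-slide calibration.**  One positive and one negative exemplar cell
  are designated per slide; the positivity threshold is the midpoint of
  their chromogen intensities.  The midpoint makes calibration symmetric
  and order-safe (a brighter positive exemplar can only raise the
  threshold).  A positive exemplar not strictly brighter than the
  negative raises a calibration error — the situation that in practice
  calls for re-picking exemplars, e.g. when melanin pigment is mistaken
  for chromogen.  When to re-calibrate is a pathologist's judgment; the
  package exposes re-calibration but does not model the trigger.
* **Binarization.**  A cell is positive iff its chromogen intensity is
  strictly above the threshold; intensity exactly at background is not
  "above" it, so ties are negative.  Staining intensity is never graded.
* **Filters.**  Nuclei below 30 µm² (lymphocyte-sized) or above 300 µm²
  are excluded, as is any cell whose centroid falls outside the tumor ROI
  or inside an exclusion polygon.  Membership is decided by the centroid
  alone and polygon boundaries count as inside.  The upstream detector's
  6 µm cytoplasm expansion is carried as provenance metadata only.

The three labels partition the cells; proportions are always computed
over positive + negative (classifiable) cells only.

## Window scan

The scored compartments are circular windows of fixed diameter 500 µm
(area 0.196 mm², one 400× high-power field).  Candidate centers form a
regular grid with 50 µm spacing anchored at the ROI bounding box and
clipped to the ROI — the reproducible surrogate for a pathologist
repeatedly placing a circle over a heatmap.  For each candidate the
classifiable cells within 250 µm (boundary inclusive) are counted with a
KD-tree; the hot (cold) spot is the candidate maximizing (minimizing)
the positive proportion among windows holding at least
`min_cells_per_spot` classifiable cells (default 100 — measured spots
contain on the order of 10³ cells, and the floor prevents a one-cell
window at the tumor edge from posing as an extreme).  Ties are broken
deterministically: larger classifiable count, then smaller y, then
smaller x, so the result is independent of cell ordering.

The scleral-margin spot is the same minimum restricted to candidates
whose **center** lies within 1 mm (point-to-segment Euclidean distance,
boundary inclusive) of the tumor-base polyline.  Whether the band should
constrain the circle's center or its entirety is genuinely open; the
center convention mirrors how a circle is dropped onto a heatmap near a
margin, and the window may likewise protrude past the ROI boundary —
only in-ROI classifiable cells are ever counted, and peri-scleral cold
spots are common, so edge windows are legitimate.

Heterogeneity is `hot − cold` in percentage points.  An exhaustive-grid
oracle reproduces the scan exactly on every tested instance; the
hot ≥ full-section ≥ cold and scleral ≥ cold orderings are asserted
property-style on every synthetic tumor.

## Heterogeneity statistics

Tumor volume uses the semi-ellipsoid estimate `V = π/6 · t · lbd²`
(apical thickness `t`, largest basal diameter `lbd`, mm).  The
heterogeneity-vs-volume screen fits eleven classic curve-estimation
families (linear, logarithmic, inverse, quadratic, cubic, compound,
power, S-shaped, growth, exponential, logistic); each intrinsically
linearizable family is fitted by least squares on its transformed scale
and R², the overall-regression F and its p-value are reported on that
same scale, matching the convention of the statistics packages that
popularized the procedure.  The logistic family's upper bound is not
identified by data and is fixed at `1.01 · max(y)`; this constant is a
package choice, documented rather than inferred.  Families requiring
`ln y` (or `ln x`, `1/x`) are marked unfittable when the data violate
their domain; the others are still returned.  A constant response has no
variance to explain: R² = 0, F = 0, p = 1 by convention.  Group
comparisons (equal-variance t, one-way ANOVA) are thin wrappers over
scipy.

## Prognostics

The prognostic score of a compartment is its percent of BAP-1
**negative** cells; higher means higher metastatic risk.

* **ROC.**  AUC is the tie-corrected ranking (Mann–Whitney) probability;
  its SE is Hanley–McNeil's nonparametric estimate, the 95% CI is
  asymptotic-normal (clipped to [0, 1]) and the p-value a Hanley–McNeil
  z-test of AUC = 0.5 — the exact null variant is a documented package
  choice.  "Equal emphasis on sensitivity and specificity" is
  operationalized as maximizing Youden's J over the unique observed
  scores with the rule `score ≥ cutoff ⇒ high risk`; J-ties prefer
  higher specificity, then the lower cutoff.
* **Dichotomization.**  `score ≥ cutoff` falls in the BAP-1-low
  (high-risk) group, so the ROC's attained operating point is reproduced
  exactly by the split.
* **Survival.**  Product-limit curves, log-rank tests and Cox partial
  likelihoods are delegated to lifelines.  Tie handling is Efron's (the
  backend's method); it coincides with the Breslow approximation
  whenever event times are untied, the generic case for continuous
  follow-up.  Univariate fits are polished by a Newton step on the
  hand-coded Efron score, because generic solvers stop on log-likelihood
  flatness, which in double precision leaves ~1e-7 of slack in the
  coefficient; the polish takes the estimate to the score root and the
  SE from the observed information there.  A monotone likelihood (e.g.
  an event-free group) has no finite maximizer; such fits are flagged
  unstable rather than quoted.
* **LRΔχ².**  `2(LL_full − LL_base)` for nested Cox models, df = number
  of added parameters, p from χ².  An added covariate with zero variance
  contributes 0 (p = 1) by construction; a covariate already in the base
  is rejected as non-nested.  The empty base uses the covariate-free
  partial log-likelihood under the same tie convention.
* **Compartment comparison.**  Per compartment: ROC against metastasis
  and against gene expression class 2, dichotomization at the metastasis
  cutoff, KM + log-rank, univariate Cox; then LRΔχ² cross-tables of
  region over region, region over AJCC T-category (ordinal 1–4) and
  region over gene-expression class 2 (patients with unknown class are
  dropped from that table only).  Cohorts without events produce the
  ROC-vs-class table and explicit "not estimable" notes instead of
  survival numbers.

Because each compartment's cutoff is chosen by maximizing J on the same
cohort, the LRΔχ² of an added dichotomized score is slightly
anticonservative under the null (optimal-cutpoint selection); at n ≈ 40
the null rejection rate at 0.05 is on the order of 10%.  This is a
property of the dichotomized design itself and is visible in the planted
simulations.

## Synthetic data

The generators define the study conditions for all tests:

* **Geometry** — a dome (half-ellipse) of basal width × apical height
  (default 6 × 3 mm) with a seeded low-frequency boundary waviness
  (±2%), sitting on a flat base whose edge is the scleral polyline.
* **Cell patterns** — homogeneous Poisson points clipped to the ROI at
  `cell_density` (default 2,500 / mm², so a default tumor holds ≈ 3.5 ×
  10⁴ cells; the CLI's `--paper-scale` raises the density toward the
  ~2 × 10⁵ cells of measured full sections).  True positivity is a logit
  background, optionally a smooth random plane-wave field, overridden
  inside planted discs (nearest-center precedence when discs overlap).
  Observable chromogen intensities are label-conditional Gaussians
  (negative mean 0.2, positive mean 0.2 + 0.6, SD 0.1, floored at 0) —
  separated enough that exemplar calibration is meaningful yet
  imperfect; counterstain is uninformative by design.  5% of nuclei are
  planted below the 30 µm² filter to exercise exclusion.  Exemplars are
  the median chromogen intensity of each true class (an absent class
  falls back to the nominal class mean, the analogue of a control
  slide).  Ground truth is returned on a separate table; the observable
  table never leaks labels.
* **Cohorts** — the hot−cold gap is drawn from a clipped normal (default
  mean 41 pp, SD 29 pp, the measured heterogeneity distribution), cold
  uniform below it, full uniform between cold and hot, scleral just
  above cold; demographics echo a typical enucleation cohort (age
  64 ± 14, slight female majority, mostly T3, thickness 8.8 mm, basal
  diameter 15.1 mm).  Metastasis times are exponential with hazard
  `baseline · exp(η + class2_log_hr · 1[class 2])` where η is either
  log-linear in the driving compartment's percent-negative score or a
  two-risk-group step at a score threshold (the high/low dichotomy of
  measured cohorts); censoring is administrative at 120 months.  With
  the defaults roughly 60–70% of patients event, matching the measured
  event fraction.

What the simulations do **not** model: pigment artifacts, necrosis,
stain gradients, the spatial correlation structure of real tumors beyond
planted discs/smooth fields, non-tumor cell types beyond the small-nucleus
fraction, competing risks, or loss to follow-up.  Passing tests therefore
demonstrate the correctness of the measurement and statistical machinery
under controlled conditions, not the biological claims on real cohorts.

## Numerical conventions and problem sizes

Distances and window membership are boundary-inclusive; all coordinates
are µm internally.  Measured extreme-window proportions carry a
selection bias of order one binomial SE (the maximum over many
overlapping windows), so recovered hot/cold values sit slightly outside
the planted ones on average; recovery tests use 99% binomial intervals
on ~500-cell windows.  Tests and the acceptance script run desk-scale
problems — tumors of ~0.7–3.5 × 10⁴ cells, cohorts of 40, 100–500
replicate simulations — chosen so the full suite completes in a few
minutes on one CPU while keeping every statistical check adequately
powered; all replicate counts and seeds are fixed in the tests.

## Known limitations

* The dialect mapping for detector exports is this package's
  abstraction; upstream tools vary and only tabular exports are read
  (no proprietary whole-slide formats).
* The candidate-grid scan is a surrogate for manual spot placement; at
  50 µm spacing the located extremum can differ from the continuous
  optimum by up to ~35 µm.
* Cutoffs are calibrated and evaluated on the same cohort, as in the
  original protocol; they are in-sample operating points, not validated
  classifiers.
* Breslow tie handling is unavailable in the survival backend; Efron's
  is used and documented (identical without ties).
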