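# Methods

This note documents the models, algorithmic choices and limitations of
the package in one place: what each stage assumes, which tunables matter,
what the synthetic data do and do not emulate, and where the design was
genuinely open.

## Imaging pipeline

### Input model

Digitised film mammograms are single-channel integer images at 8 or 16
bit. Because film digitiser settings vary and are often unknown, the
pipeline is depth-agnostic: nothing is rescaled to 8 bit, and the
threshold search operates on the native intensity scale. Colour inputs
are rejected outright. One breast per image, cranio-caudal view, is
assumed; the chest wall appears as the vertical image edge the breast
touches.

### Border detection and stripping

Scanner borders are bright frames along image edges. A side's width is
grown inward while the edge-adjacent row/column mean intensity is at or
above the `border_percentile` (default 99th) of the whole image, capped
at `max_border_frac` (default 10%) of that dimension. Detected border
pixels are zeroed; with no border the operation is an identity.

The percentile criterion assumes the border is among the very brightest
structures in the image. A mammogram whose breast occupies nearly the
whole frame at near-saturated intensity could defeat it; such images are
outside the pipeline's design envelope and would surface as area-bound
failures downstream.

### Background split, artefacts and failure rules

Background and tissue are split with Otsu's threshold on the
border-stripped image — a parameter-free, auditable choice. Connected
components use 4-connectivity throughout. The largest foreground
component is the breast candidate (ties broken in favour of a component
touching a vertical edge); its interior holes are filled, since local
noise below the background threshold inside the breast is not background.
Every other foreground component — laterality tags, nameplates, specks —
is an artefact and never enters the breast mask. A tag that overlaps the
breast merges with its component by construction; that geometry is meant
to surface as a failure, not to be repaired.

Edge contact is assessed at the *effective* edges, i.e. the first
row/column inside any stripped border. This folds the "breast overlaps
the scanner frame" failure mode into edge counting: a breast running
under the frame touches that effective edge. The candidate fails
(`FAIL_BREAST_SEGMENTATION`) when it

* touches both vertical effective edges, or
* touches three or more effective edges, or
* touches no vertical edge (a breast must sit on the chest wall), or
* occupies less than `min_breast_frac` (1%) or more than
  `max_breast_frac` (90%) of the image area.

Empty or constant images fail with `FAIL_EMPTY_IMAGE`. All failure
tunables are config-exposed; the rules are this package's own
characterisation of how automated breast outlining fails (typically on
breasts overlapping artefacts or the image border), not a claim about
any particular historical implementation. Failures are data: batch runs
record the reason code and keep going. No pectoral-muscle handling is
attempted (CC views do not normally show it).

The chest edge is the vertical edge the accepted component touches;
laterality tags are deliberately not consulted (they are artefacts).

### Preprocessing

Both operations touch only breast pixels and leave the rest of the image
bit-identical.

* **Median smoothing** (radius 1 by default): each breast pixel becomes
  the median of its (2r+1)² window *intersected with the breast mask* —
  no mirroring or zero padding, so dark background cannot bias boundary
  medians. With an even number of valid neighbours the lower median is
  taken; it is an actual pixel value, keeping the image integer. This
  convention is frozen by a brute-force oracle test.
* **Contrast stretching**: a linear map of breast intensities to the
  full scale, clipping at the nearest-rank 1st/99th percentiles of the
  breast multiset (`stretch_lo_pct`/`stretch_hi_pct`; 0/100 recovers a
  pure min–max stretch). Clipping makes the stretch robust to residual
  bright or dark specks. Values are rounded to nearest (ties to even, as
  IEEE rounding gives).

No intensity standardisation across images is performed anywhere; this
is a design principle, not an omission — each mammogram is thresholded
on its own scale.

### Dense/fatty threshold

The criterion *J(t)* is the between-class variance of the breast-pixel
histogram (Otsu restricted to the breast area), with the strictly
brighter class defined as dense. Candidates are the intensities actually
present in the breast — between two present values *J* is constant, so
this candidate set contains a global maximiser of the full-range scan;
the smallest maximiser is returned so plateaus resolve
deterministically. Dense = intensity **strictly greater** than *t\**;
this semantics is fixed once to avoid off-by-one drift between the
criterion and the mask.

Properties relied on elsewhere:

* **Exhaustive verifiability** — *J* is evaluated on a finite histogram,
  so an independent brute-force scan must agree exactly; this is tested
  on hundreds of random phantoms.
* **Affine equivariance** — an affine intensity remap `v ↦ a·v + b`
  (a > 0) rescales *J* by *a²* and preserves the maximising partition,
  so the dense-pixel *set* is unchanged. This is the correct invariance
  for this criterion; general monotone remappings need not preserve the
  partition because between-class variance uses intensity values, not
  ranks.
* **No hard failure** — a constant (degenerate) breast returns its
  maximum intensity, giving dense area 0, with the condition logged.
  The density stage never fails on a successfully segmented breast.

The criterion sits behind a single interface (`criterion=` config key)
so an alternative (e.g. entropy-based) could be A/B-tested without
touching the pipeline.

Percent density is computed from post-stretch pixel counts; under the
strict-threshold semantics the counts are invariant to the (monotone)
stretch applied before thresholding whenever the stretch does not merge
the levels the threshold separates, so this choice is immaterial at the
contrasts the generator produces.

## Phantoms

Phantoms emulate the *gross* structure of scanned film mammograms: a
half-elliptical breast attached to one vertical edge, dense discs, a
uniform fatty background inside the breast, additive Gaussian film grain
(clipped to the intensity range), an optional full border frame at
maximum intensity, and an optional detached bright tag. Defaults: 256²
8-bit images, fatty mean 90, dense mean 170 (high contrast; 130 for
medium), noise SD 8 — chosen as plausible film-digitisation values with
a dense/fatty separation of several noise SDs, the regime in which a
threshold method is meaningful.

Dense geometry is solved by random sequential placement of
non-overlapping discs fully inside the breast, the radius shrinking as
the remaining deficit falls; the realised fraction must land within ±2
percentage points of the target or (after 100 restart attempts) the
generator raises rather than silently missing. Generation is
deterministic given the spec (the seed is a spec field).

What phantoms do **not** emulate: real parenchymal texture, X-ray
physics, scatter, breast-thickness gradients, skin line and nipple
detail, or intensity calibration drift. Passing the recovery tests
therefore shows the pipeline is *correct under its stated model* —
bimodal tissue plus noise and artefacts — not that its accuracy
transfers to clinical film images; on real data only the validation
statistics (risk gradients, screening associations) can establish
usefulness.

A deliberately infeasible geometry (`failure_spec`) widens the breast to
span both vertical edges beneath a border frame, reproducing the
characterised segmentation-failure mode for failure-rate tests.

## Simulated cohorts

The cohort generator mimics a weighted case-control sample from a
biennial film-screening programme. For a simulated population of
`n_women`:

* screening round is first with probability 0.45; age group, hormone
  therapy use (22%), family history (3%) and minor symptoms (6%) are
  drawn independently (shares follow a screened population of women
  aged 40–79);
* each woman has a latent density percentile *u* ~ U(0, 100); the two
  dense-area measures are lognormal quantile transforms of *u* (medians
  21,293 and 18,400 px, log-SD 0.9) linked by a Gaussian copula
  (latent correlation 0.65), emulating two imperfectly agreeing
  measures of the same breast;
* the outcome is multinomial-logistic versus control with per-group
  log-odds offsets for each cancer type. Default highest-decile odds
  ratios are 2.2 (small screen-detected), 6.4 (large screen-detected)
  and 4.7 (interval), interpolated monotonically across groups; baseline
  (Q1) per-screen outcome probabilities put interval odds at 3/7 of
  screen-detected — i.e. a designed Q1 programme sensitivity of 70%;
* covariate effects act **equally** on all three cancer outcomes, so
  they shift cancer risk without touching the interval-vs-screen-
  detected odds; designed sensitivities are therefore exact at any
  covariate profile;
* all cases are retained; controls are kept with probability equal to
  their round's sampling fraction (1.55% first, 3.25% subsequent) and
  carry the inverse fraction as analysis weight, cases weight 1.

Setting both fractions to 1 returns the full population (weights 1),
which the law-of-large-numbers tests use. Tumour sizes are drawn
consistently with the outcome label (≤15 mm small, >15 mm large;
occasional microinvasive tumours are recorded as 0.1 mm).

## Validation statistics

* **Weighted percentiles** use the mid-rank estimator
  `pct(v) = 100·(W(<v) + ½·W(=v)) / W_total`: ties share a percentile,
  and a record of weight 2 is exactly two unit-weight copies. Group
  boundaries at population percentiles 20/40/60/80/90 are left-closed.
* **Odds-ratio models** are maximum-likelihood unconditional logistic
  regressions (statsmodels) with density group as a categorical exposure
  (Q1 reference) and categorical adjustment for age group, hormone
  therapy, family history, symptoms and screening round; Wald 95% CIs on
  the log-odds scale. A round×density interaction term is available.
  Complete separation on the exposure is detected before fitting and
  reported with the offending cell. Sampling weights enter the
  percentile computation only; the regressions are unweighted, as is
  standard for case-control sampling on outcome.
* **Programme sensitivity** comes from the case-only model of interval
  versus screen-detected cancers, sharing the same fitting core;
  sensitivity is the pure transform 100/(1 + odds) of the predicted
  odds at a covariate profile, with the CI obtained by transforming the
  Wald interval of the linear predictor (monotone decreasing, so the
  bounds swap). This CI choice is documented, not claimed to be the
  only reasonable one.
* **ROC/AUC**: AUC is the tie-halved Mann–Whitney probability; the curve
  has one point per distinct threshold. **Cuzick's trend test** is the
  Wilcoxon-type statistic *T = Σ lᵢRᵢ* standardised by its permutation
  moments with the usual tie correction (z = 0, p = 1 when the variance
  degenerates); Kruskal–Wallis comes from scipy with the all-ties case
  handled as H = 0.
* **Agreement**: Pearson correlation of weighted percentile scores
  (two-sided p via the Fisher z normal approximation), Bland–Altman
  mean difference and ±1.96 SD limits on log dense area (weighted
  moments), and a weighted 6×6 quintile–decile cross-classification
  with perfect (trace) and within-one-category (|row−col| ≤ 1)
  agreement percentages.

## Problem sizes and numerical notes

The shipped acceptance checks use 200 mixed-spec phantoms for
threshold-oracle equivalence, a 4-fraction × 10-seed high-contrast grid
for density recovery (mean |error| ≤ 5 points, Dice ≥ 0.95), 40-image
batches with 5% constructed failures for failure-mode fidelity, and 200
simulated cohorts per designed OR (population 50,000) for CI coverage
within 95% ± 4 points — sizes chosen to give exact or tight Monte-Carlo
checks on a single CPU in minutes. The acceptance script reports the
same quantities at moderately reduced replication. Logistic fits use
Newton iterations to statsmodels defaults; the 2×2 closed-form identity
(OR = ad/bc, Woolf CI) holds to at least six significant figures at
convergence.

## Known limitations

* The segmentation and threshold criteria are this package's documented
  choices for behaviour that published automated-density methods specify
  only loosely; other implementations' failure rules need not match.
* Between-class variance assumes an (approximately) bimodal breast
  histogram; breasts with genuinely unimodal histograms get a threshold
  in the histogram's interior and a dense area that should be read as a
  soft quantity, not anatomy.
* No BMI adjustment (screening programmes rarely record it), no
  conditional logistic models, no volumetric density, no raw digital
  mammography pipeline, and no DICOM/MLO-view support.
* Film-grain is modelled as additive Gaussian noise; correlated grain,
  blur and calibration artefacts of real digitisers are out of scope.
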