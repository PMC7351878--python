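# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic experiments can show.

## Biomarker quantification

**Binarization.** En-face angiograms are smoothed with a 3×3 median
filter, thresholded with Otsu's global method, opened with a one-pixel
disc, and cleaned of connected components under 50 px (8-connectivity
throughout; coordinates are 0-based row/column, origin top-left).  All
four stages are parameters of `BinarizeOptions`.  A constant image yields
an empty mask with a warning rather than an error, because a blank frame
is a data problem, not a programming error.  An `invert` flag flips the
image about the dtype maximum first, so inverted-contrast exports
binarize identically.

**Delineation.** The analysis assumes a single dominant lesion (eyes with
multiple lesions are outside the intended population).  The largest
8-connected component is kept together with any component intersecting its
20-px dilated envelope — satellite lobes of the same lesion — and the
analysis region is the convex hull of the retained flow.  The hull is the
vessel-density denominator; a bounding-box denominator can be swapped in
by using the mask extents instead.  SA counts flow pixels themselves, not
the hull.

**Box counting.** Box sizes follow powers of two, R = 2, 4, …, up to half
the smaller image side.  Each size is evaluated at four deterministic grid
origins — offsets (0,0), (R/2,0), (0,R/2), (R/2,R/2) — to reduce
grid-placement bias.  Grid shifts are applied periodically (the image is a
torus): a shifted grid over a clipped image would gain partial edge boxes
and systematically inflate counts at large R, which biases the fitted
dimension low (a filled square then measures ≈1.91 instead of 2).  With
toroidal shifts, axis-aligned sets keep their exact covering counts at
every origin.

**FD estimation.** Per origin, ordinary least squares of ln N on ln R
gives slope −FD; the reported FD is the mean of per-origin slopes (a
min-count aggregation — one fit to the origin-wise minimum counts, the
tightest covering — is available by flag).  The fit is restricted to the
scaling range R ≤ (bounding-box extent)/4, keeping at least the three
smallest sizes: boxes larger than the lesion hold O(1) counts and flatten
the log-log curve, biasing small lesions low.  FD is clipped to [0, 2]
with a flag.  Calibration on analytic shapes (rasterized at feature scales
of 1–3 px): straight line 1.000, filled square 2.000, Sierpinski order 7
→ 1.594 (target 1.585), Koch order 5 on a 512-px canvas → 1.222 (target
1.262).  Residual Koch bias is rasterization at its 2-px feature scale;
higher orders/larger canvases converge toward the analytic value.

One degenerate case is worth knowing: a thin structure lying exactly on a
box-grid boundary (e.g. a horizontal vessel at precisely half the field)
straddles two box rows at every aligned size and its measured FD drops by
≈0.05; the multi-origin average softens but does not remove this.

**Lacunarity.** Λ(R) = σ²(R)/µ(R)² per (size, origin), averaged over all
cells with µ > 0.  Two moment conventions are recorded in every
`BoxCountCurve`: over occupied boxes only (the default for the reported
LAC), and including empty boxes inside the lesion bounding box that lie
fully inside the image.  The occupied-only convention produces values
around 0.1–0.5 on skeletonized CNV networks — the magnitude reported for
real lesions — whereas the empty-box-inclusive variant is dominated by
sparsity at small R and runs an order of magnitude higher; it remains
available via `include_empty=True`.  Either way LAC = 0 exactly iff every
contributing box holds identical mass.

## Synthetic lesions

Vessel trees grow as a trunk chain (12 links) with recursively branching
side chains over at most 4 further generations; calibers 32/18/10/5.5/3 µm,
chain lengths tapering from 0.17 mm.  Each potential branch site owns a
private hash-derived random stream keyed by its tree position, and sprouts
iff its uniform draw falls below `BRANCH_PROB_SCALE[g] · complexity^0.7`.
Because draws are positional, the tree at a lower complexity is an exact
subtree of the tree at a higher complexity under the same seed — segment
counts, and in practice measured FD and SA, increase monotonically with
the knob.  Anti-VEGF pruning removes every segment thinner than a caliber
threshold (default 8 µm — the "tiny capillaries") together with its
subtree; the trunk always survives.

The rasterizer draws each segment as an anti-aliased capsule stroke of
width caliber/pitch on a 320-px, 4.5-mm field (≈14 µm/px, 8-bit), over a
12%-of-range background, with additive Gaussian speckle (σ = 8% of range
by default).  Calibers below ~1 px are drawn as faint sub-pixel strokes;
consequently binarized SA is grid-independent (<2% change on doubling
resolution) only when calibers are resolvable (≳2 px).

## Cohort simulation

Baseline morphology is drawn per patient: FD truncated-normal (mean 1.48,
SD 0.10 on [1.2, 1.6]) and SA log-normal (log-median ln 0.62, log-SD 1.1),
Gaussian-copula correlated at 0.4 — matching the distributions real
cohorts report at baseline.  A latent activity drive couples morphology to
burden on the log-odds scale:

    logit p(active) = −0.65 − 14·(FD − 1.48) − 0.55·(ln SA − ln 0.62)

Per-visit activity is an independent Bernoulli draw of this probability
(a serial-correlation carry-over coefficient exists but defaults to off).
The intercept and slopes were fixed once so that an always-quiet patient
receives exactly 7 injections under the default schedule, the median
burden is 7 and about 44% of patients need 8 or more, and the burden
groups separate in baseline FD and SA the way treated cohorts do.  The
drive is a statistical stand-in: there is no VEGF diffusion or fluid
geometry, and fluid is a per-visit flag.

The treat-and-extend schedule injects at weeks 0/4/8 (loading), sees the
patient again after an initial 8-week interval, then moves the interval by
±2 weeks (quiet/active) clamped to [4, 12], out to a 52-week horizon; all
five constants are configuration.  An always-quiet patient attends weeks
0, 4, 8, 16, 26, 38, 50; an always-active one peaks at 12 visits.  Because
an injection is given at every attended visit, the simulated minimum is 7
injections, whereas real cohorts report a minimum of 6 (patients miss
visits); missed visits are not modelled.

Clinical fields are generated to be internally consistent with the drawn
activity: an active visit shows subretinal fluid and a 30–80 µm rise in
central macular thickness (intraretinal fluid 40%, hemorrhage 8%), a quiet
visit is dry with thickness drifting down, so applying the activity
criteria to the generated flags recovers the Bernoulli draw exactly.
Visual acuity follows baseline (normal, mean 58 letters, clipped to
[20, 85]) plus a 12-month gain (normal, mean +8, SD 9 letters —
reproducing ≈60% five-letter gainers) interpolated across visits with
2-letter noise.  The loading-dose thickness change (normal, −110 µm mean,
SD 100) and a resolution probability produce ≈60% good anatomic
responders.  19% of patients drop out before month 12 (independent of
morphology); dropouts keep their simulated injection schedule but lack
the 12-month evaluation, so their functional response is undefined.

Imaging evaluations happen at weeks 0 (two consecutive acquisitions for
repeatability), 12 (the pruned tree — one month after loading) and 52
(the original tree again: regrowth back to baseline morphology, matching
the observation that 12-month biomarkers return to baseline levels).
These are separate from injection visits: under the default schedule there
is no injection visit at week 12, so evaluations are stored as their own
table.

**Fidelity of the imaging map.** The latent FD band maps steeply onto tree
complexity ((FD − 1.18)/0.40) and the SA target adjusts footprint and
caliber jointly with tight clips (length √scale in [0.75, 1.25], caliber
in [0.6, 1.4]).  These choices were calibrated once against the latent
draws: measured baseline FD correlates with the latent FD at r ≈ 0.86 and
measured SA ranks with latent SA at ρ ≈ 0.6.  Two costs are accepted and
documented rather than hidden: measured FD levels sit ≈0.15 below the
latent targets (rasterization and skeletonization compress the scale), and
measured SA medians run roughly twice the latent target because stroke
widths cannot shrink below the clip floor.  Group *differences* and
directions — what the acceptance checks assert — are preserved.

## Statistics

* ICC(A,k): two-way ANOVA mean squares, ICC = (MSR − MSE)/(MSR +
  (MSC − MSE)/n); CI from the single-rater F bounds (McGraw–Wong)
  stepped up by Spearman–Brown.  Cross-checked against an independent
  implementation to 1e-10.
* Paired tests: Wilcoxon signed-rank with exact enumeration up to 25
  non-zero pairs (normal approximation beyond), zeros dropped; sign test
  always exact binomial.  All-zero differences give p = 1 with a warning.
* Mann-Whitney: exact for tie-free groups of ≤12, else normal
  approximation with tie correction.
* Logistic GLM: maximum likelihood, Wald intervals; odds ratios reported
  per chosen predictor increment (FD per 0.01 units, SA per mm² —
  increments on which a per-unit odds ratio is readable for a predictor
  whose clinical range spans only a few hundredths).  Perfect separation is
  flagged and the CI reported unbounded instead of raising.  Smooth
  partial effects use a restricted cubic spline (default df 3, quantile
  knots) with pointwise Wald bands.
* ROC: AUC by the rank formulation (equals U/(n₁n₂) exactly in the
  tie-free case); CI by DeLong's structural components; qualitative bands
  at 0.7 and 0.8.
* Summaries: median and 25th–75th percentiles with linear interpolation.

## Problem sizes

The default experiments are sized for a single CPU: the shipped cohort is
64 patients at 320 px (the enrolment scale real studies use), null
calibration runs 200 statistics-only cohorts of 60, coverage runs 200
logistic cohorts of n = 200, and the box-count verification enumerates
100 random 32×32 masks.

## What passing tests do and do not show

The synthetic lesions reproduce the *geometry statistics* that matter for
the pipeline (branching networks with controllable FD/SA, speckle,
pruning) but not projection artifacts, segmentation errors of the
outer-retina slab, shadowing under pigment-epithelium detachments,
motion artifacts, or multi-lesion eyes.  Passing the direction-level
cohort checks shows the pipeline recovers programmed effects at realistic
sample sizes and noise — it does not validate the clinical effect sizes,
which only patient data can.
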