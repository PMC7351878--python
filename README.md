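# cnvquant

Quantitative OCT-angiography (OCT-A) biomarkers for choroidal
neovascularization (CNV) under a treat-and-extend (TAE) anti-VEGF regimen —
with a synthetic-data layer so the whole analysis is reproducible without
patient images.

## The problem

In neovascular age-related macular degeneration, abnormal choroidal vessels
grow under the retina and leak fluid.  Treatment is repeated intravitreal
anti-VEGF injections, dosed by a treat-and-extend schedule: inject at every
visit, lengthen the interval by two weeks while the lesion is quiet,
shorten it when it reactivates.  En-face OCT-A shows the lesion's vascular
network directly, and its morphology can be quantified:

* **FD** — box-counting (Kolmogorov capacity) fractal dimension of the
  skeletonized network, from the power law `N = N0 · R^(−FD)` where `N(R)`
  is the number of boxes of side `R` covering the skeleton.  Branching
  complexity; 0 ≤ FD ≤ 2.
* **LAC** — lacunarity, the normalized box-mass variance `σ²(R)/µ(R)²`
  averaged over box sizes and grid origins.  Gappiness/heterogeneity; 0
  for a translation-invariant pattern.
* **SA** — blood-flow surface area: flow pixels × pixel pitch², in mm².
* **VD** — vessel density: flow fraction of the delineated lesion region.

The scientific question is whether these baseline biomarkers predict the
first-year treatment burden (7 or fewer injections = *extended*, 8 or more
= *regular*), the anatomic response to the loading dose, and the 12-month
visual outcome.

## What the package provides

* `cnvquant.quantify` — binarization (median filter → Otsu → opening →
  despeckling), lesion delineation (dominant component + convex hull),
  skeletonization, multi-origin box counting, FD/LAC estimation, SA/VD.
* `cnvquant.vessels` / `cnvquant.imaging` — a seeded stochastic branching
  vessel-tree generator with a `complexity` knob, anti-VEGF pruning by
  caliber, and an anti-aliased rasterizer producing 8-bit en-face
  angiograms (4.5 × 4.5 mm field, 320 px, speckle noise).
* `cnvquant.protocol` / `cnvquant.cohort` — TAE schedule simulation
  (loading at weeks 0/4/8; ±2-week interval steps in [4, 12]) and a
  64-patient cohort whose per-visit activity is logistically coupled to
  baseline morphology (sparser, smaller lesions reactivate more).
* `cnvquant.outcomes` — activity criteria, good/bad anatomic response
  (fluid resolution or >100 µm thinning), ≥5-letter functional response,
  burden classes.
* `cnvquant.stats` — ICC(A,k) repeatability with McGraw–Wong intervals,
  exact Wilcoxon/sign/Mann-Whitney tests, logistic GLMs with odds ratios,
  restricted-cubic-spline partial effects, ROC AUC with DeLong intervals.
* `cnvquant.cli` — a `cnvquant` command with `simulate`, `quantify`,
  `analyze` and `report` subcommands over CSV/TIFF/YAML/JSON files.

## Worked example

```sh
cnvquant simulate --n 64 --seed 5 --out run/
cnvquant quantify --manifest run/manifest.csv --out run/metrics.csv
cnvquant analyze --metrics run/metrics.csv --cohort-dir run --out run/results.json
cnvquant report --results run/results.json
```

The report prints (seed 5, abridged):

```
patients: 64
injections: median 7 (IQR 7-9, range 7-12); regular share 0.42
baseline_vs_month12: fd: p=0.397, lac: p=0.867, sa_mm2: p=0.675, vd: p=0.575
baseline_vs_month3: fd: p=5.61e-11, lac: p=0.316, sa_mm2: p=4.49e-08, vd: p=1.31e-11
ICC fd: 0.990 [0.984, 0.994]
ICC lac: 0.917 [0.863, 0.949]
ICC sa_mm2: 1.000 [0.999, 1.000]
burden_regular ~ fd: OR 0.878/0.01, AUC 0.81 (very good)
burden_regular ~ sa_mm2: OR 0.00704/1.0, AUC 0.94 (very good)
functional_response ~ fd: OR 1/0.01, AUC 0.46 (none)
```

Reading: the median simulated patient receives 7 injections in year one
and 42% need 8 or more; FD and SA drop sharply one month after the
loading dose (the pruning effect — the finest capillaries disappear) while
lacunarity does not move, and by month 12 the regrown lesion is back at
baseline; two consecutive baseline acquisitions agree almost perfectly
(ICC ≥ 0.92 for all four biomarkers); each 0.01 of baseline FD lowers the
odds of a high injection burden by ~12% (OR 0.878, very good
discrimination at AUC 0.81), whereas baseline morphology says nothing
about the 12-month visual outcome.

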