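# Methods

## Segmentation model

A single axial CT slice in Hounsfield units is segmented by density alone:
a pixel is adipose tissue iff its HU lies in `[-190, -30]` and skeletal
muscle iff in `(-30, 150]`. The shared boundary value −30 HU appears in
both published windows; we assign it to adipose (closed) and open the
muscle interval at the left so that no pixel is ever double-counted and
adipose + muscle + rest always partitions an ROI. The inclusivity of each
bound is configurable per `TissueRange` for users who prefer another
convention.

Pixel membership in a polygon ROI follows one rule everywhere: a pixel
belongs iff its **center** lies inside or exactly on the boundary
(implemented with shapely's boundary-inclusive point test). The phantom
generator rasterizes its geometric compartments with the same rule, which
is what makes ground truth and measurement agree bit-exactly on noise-free
input — the property the test suite checks, alongside equivalence with an
independent brute-force ray-casting loop on small rasters.

Slice-thickness standardization to 1 mm is deliberately metadata-only: the
acquisition's 3 or 5 mm reconstruction scales the per-voxel volume, not the
in-plane geometry, so the correction divides the slab volume by 0.1 cm
rather than resampling pixels. Areas are
`count × row_spacing × col_spacing / 100` cm²; anisotropic spacing is
honoured via the product.

Field-of-view truncation is detected when the body-contour ROI touches or
exits the outermost image row/column (a tangent vertex counts as
truncated). Subcutaneous fat, being a difference of A and B, is then
reported as non-quantifiable instead of as a too-small number.

## Derived parameters

The seven areas, MA, SMI and the sarcopenia flags follow the definitions in
the README. Decisions worth making explicit:

* **MA is a pixel-pooled mean** over the union of ROIs C and D (an overlap
  is counted once), not a mean of per-compartment means; the source
  protocol does not say which it used, and pooling is the convention here.
  MA fails loudly when no muscle pixel exists — 0 HU is a valid density,
  not a sentinel.
* **Sarcopenia cutoffs** (men: SMI < 43 cm²/m² if BMI < 25, < 53 if
  BMI ≥ 25; women: < 41; MA < 41 HU if BMI < 25, < 33 if BMI ≥ 25;
  boundary 25 kg/m²) are stored in the configuration and swappable. All
  cutoffs are **strict** `<`: a patient exactly at a threshold is not
  sarcopenic, and a 3.0 mm duct is not "under 3 mm". The combined flag is
  the OR of the SMI and MA arms.
* **Unmeasurable ducts** stay a category of their own. They are excluded
  from continuous analyses and from the 2×2 stratification (forcing them
  into the wide row would bias it); an imputation-at-standard-width
  sensitivity mode exists for gauging that bias.

## Phantom generator

The phantom emulates what the quantification protocol sees, not CT physics:
concentric ellipses for body outline, subcutaneous fat ring and muscular
wall; a visceral interior whose pixels are independently visceral fat with
probability `visceral_fat_fraction` (default 0.55) and bowel gas otherwise;
a central vertebral body; a psoas pair flanking it; a paraspinal ellipse
behind it (vertebra carved out); optionally an anterior ascites blob at
10 ± 5 HU — inside the muscle window on purpose, to reproduce the
confounder that motivates excluding the ventral wall from MA. Default
tissue HU means/sds (fat ≈ −90 ± 12, muscle ≈ 44–52 ± 9–10, bone 600 ± 120,
bowel gas −650 ± 90) sit well inside their detection windows; the default
geometry yields a visceral fat area of ≈ 132 cm² and psoas area of
≈ 16 cm², near the reference cohort's medians. Noise is Gaussian per
tissue, truncated to the CT-representable range [−1024, 3071]. Not
emulated, and therefore not validated by a passing suite: partial-volume
mixtures at tissue borders, beam hardening, contrast-phase differences,
non-elliptic anatomy, and inter-operator ROI variability.

ROI polygons are 256-gons inscribed in the compartment ellipses with a
margin. Because an inscribed 256-gon's sagitta is below a micron, a margin
of 0.25 mm suffices for the muscle ROIs (C, D) to cover every own pixel
while staying clear of the neighbouring compartment even on 5.5 mm test
grids; A and B carry looser margins since their neighbours (air, muscular
wall) cannot contaminate the quantity each ROI is used for. Ground truth is
defined *through* these polygons: for each ROI it counts member pixels
whose noise-free tissue HU falls in each window, so truth and measurement
are two paths over one discretization.

## Cohort simulator

Covariates: sex Bernoulli (male fraction 84/139), height normal by sex
(1.78 ± 0.07 m men, 1.65 ± 0.065 m women), BMI normal 25.4 ± 3.5 kg/m².
Body composition (A_VAT, A_MTOT, MA, DPD, DPP) is multivariate normal with
means at the reference medians (127.5 cm², 134 cm², 39.5 HU, 2.9 mm,
17.7 mm), spreads and the two nonzero correlations (VAT–MA −0.40,
VAT–MTOT +0.20) chosen once as physiologically plausible — only medians and
ranges are published, so the spread is this package's own choice and the
simulated cohort is not claimed to reproduce the original one. Draws are
floored at physical minima. Total muscle is split into psoas / paraspinal /
ventral compartments by a Dirichlet around the reference proportions.

Sarcopenia is **computed** from the generated SMI/MA via the real
classifier, never sampled, keeping the classification rule on the tested
path. With the Martin cutoffs and this covariate model the sarcopenia
prevalence comes out near 0.7 — higher than a typical Western surgical
cohort, driven by the 53 cm²/m² cutoff for overweight men; the classifier,
not the prevalence, is the validated object.

Outcomes are Bernoulli with
`logit P = intercept + ln(4.30)·sarcopenic + ln(1.006)·A_VAT + ln(0.725)·DPD`
for severe POPF (major complications use the same slopes with their own
intercept). Intercepts −2.64 / −2.09 were calibrated once by bisection at
n = 20 000 so the marginal event rates match the reference prevalences
(26/139 and 18.7%, 37/139 and 26.6%). About 10% of ducts are set
unmeasurable, mirroring 14/139.

## Statistics

* **Mann-Whitney U** delegates to scipy: exact null distribution when
  n₁+n₂ ≤ 12 without ties, otherwise the normal approximation with mid-rank
  tie correction and continuity correction. Pooled-constant input returns
  p = 1 by definition. The null calibration study (50+50, 2000 replicates)
  lands at a rejection rate of ≈ 0.05 at α = 0.05.
* **Logistic regression** is an in-house IRLS/Newton solver with
  step-halving (the likelihood path is non-decreasing by construction and
  asserted in tests), convergence at score max-norm < 10⁻⁶, and explicit
  separation/non-convergence flags instead of unstable estimates; the fit
  agrees with statsmodels to 10⁻⁶ on the coefficients. Wald 95% intervals
  only; profile likelihood is out of scope. Coverage of the true log-ORs in
  the simulation study is ≈ 0.93–0.97 per coefficient.
* **ROC/AUC** is computed through the rank identity AUC = U/(n₁n₂) with
  tied pairs counted ½, and is asserted equal to an O(n²) pair-counting
  oracle and to the Mann-Whitney U cross-module on every tested input. The
  `lower_is_positive` orientation serves MA and DPD, which are risk factors
  when *low*.
* **2×2 tables** report row percentages through a one-decimal formatter and
  a cross-product odds ratio with the Haldane–Anscombe +0.5 correction when
  a cell is zero. The formatter's default is round-half-up; a truncation
  mode exists because printed clinical tables are not always consistent
  about which rule they used. No multiple-testing correction is applied
  anywhere, matching the workflow this package mirrors.
* p-values are computed at full precision; `format_p` reproduces the
  "p < x.xx" two-decimal presentation style separately from computation.

## Problem sizes and determinism

Defaults keep every study cheap: phantoms are 256×256 at 1.5 mm (a few
hundred ms each), the null-calibration study runs 2000 replicates of 50+50,
and the coverage study 100 cohorts of 2000 patients (≈ 10 s total). Every
random draw flows from one `numpy` Generator per call, seeded from the spec
(package default seed 20190427); identical spec ⇒ identical raster, cohort,
and byte-identical output files (DICOM UIDs are content-derived). The
acceptance script derives all sub-seeds from its `--seed` argument.

## Known limitations

Phantoms are piecewise-constant ellipse worlds; exact recovery there shows
the counting machinery is right, not that HU thresholds segment real
anatomy well. ROI placement is the operator's job (no atlas or learned
segmentation, no vertebral-level detection), pancreatic measurements are
manual caliper inputs, and gland density / remnant volume are out of scope.
The simulated cohort's dispersions and correlations are assumptions, so
downstream statistics validate calibration of the methods, not the clinical
effect sizes themselves.
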