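# ctbodycomp

CT body-composition quantification at the L3-L4 intervertebral level, with
the cohort statistics used to relate body composition to postoperative risk
after pancreaticoduodenectomy.

## The problem

Before a pancreatic head resection, a routine abdominal CT already contains
strong prognostic signal: visceral obesity, a narrow pancreatic duct and
muscle depletion (sarcopenia) all predispose to major complications and
symptomatic pancreatic fistula (POPF). This package implements the full
measurement chain a radiology workstation would run on the single axial
slice at L3-L4:

* **Density-threshold segmentation.** Tissue is identified purely by its
  Hounsfield-unit window — adipose `[-190, -30]` HU, skeletal muscle
  `(-30, 150]` HU — and counted pixel-wise inside four nested,
  manually-placed polygon ROIs: **A** total body contour, **B** inner border
  of the abdominal wall (visceral compartment), **C** the paired psoas
  muscles bridged across the anterior spinal canal, **D** the paravertebral
  muscle compartment. Slice thickness is standardized to 1 mm first, so the
  tool's volume bookkeeping and the reported cross-section coincide
  (45.63 cm³ at 0.1 cm thickness = 456.3 cm²).
* **Derived parameters.** A_TAT = fat(A); A_VAT = fat(B);
  A_SAT = A_TAT − A_VAT (not quantifiable if the body exceeds the scan
  field of view); A_MPSO = muscle(C); A_MSPI = muscle(D);
  A_MVEN = muscle(A) − muscle(C) − muscle(D); A_MTOT their sum;
  MA = mean HU of muscle-range pixels in C ∪ D (the ventral wall is
  deliberately excluded because ascites mimics muscle density);
  SMI = A_MTOT / height² in cm²/m²; sarcopenia by the Martin-convention
  sex- and BMI-specific SMI/MA cutoffs; pancreatic duct and parenchyma
  diameters (DPD, DPP) by caliper, stratified at 3 mm and 12 mm.
* **Cohort statistics.** Mann-Whitney U group comparisons (exact for tiny
  tie-free samples, tie- and continuity-corrected normal approximation
  otherwise), binary logistic regression by IRLS with odds ratios and 95%
  Wald intervals, ROC analysis through the identity AUC = U/(n₁n₂) with
  ties counted ½, and 2×2 stratification tables.

No patient data ships with the package. A synthetic phantom generator
(elliptical body with subcutaneous fat ring, muscular wall, visceral
fat/bowel mix, psoas pair, paraspinal compartment, vertebra, optional
ascites and field-of-view truncation) provides rasters with *exact* pixel
ground truth, and a cohort simulator draws patients whose outcomes follow a
known logistic model — so every stage is testable end to end.

## Worked example

```python
from ctbodycomp import (PhantomSpec, generate_phantom, standardize_slice,
                        quantify_tissue_area, adipose_range, muscle_range)
from ctbodycomp.phantom import DEFAULT_TISSUE_HU

hu0 = {k: (mu, 0.0) for k, (mu, sd) in DEFAULT_TISSUE_HU.items()}  # noise-free
ct, truth = generate_phantom(PhantomSpec(tissue_hu=hu0))
ct = standardize_slice(ct)
vat = quantify_tissue_area(ct, truth.roi_set.roi_b, adipose_range())
print(vat, truth.per_roi["B"].fat_area_cm2)
```

prints `132.0975 132.0975` — the measured visceral fat area (cm²) equals the
rasterized ground truth bit-exactly, because phantom rasterization and ROI
pixel membership share one rule (pixel center inside the boundary, boundary
counted as inside).

The analysis drivers run the same machinery at study scale:

```bash
python analysis/01_phantom_validation.py   # segmentation vs ground truth
python analysis/02_simulate_cohort.py      # 139-patient simulated cohort
python analysis/03_risk_statistics.py      # Mann-Whitney / logistic / ROC / 2x2
python analysis/04_method_calibration.py   # type-I error + CI coverage studies
```

`02` reports, for the default cohort, medians near the reference conditions
(A_VAT ≈ 122 cm², SMI ≈ 44 cm²/m², DPD ≈ 3.0 mm, 12 ducts unmeasurable) and
`03` prints the refitted odds ratios with their intervals and the AUCs of MA
and DPD for severe POPF. All tables land in `results/`.

There is also a CLI mirroring the three pipeline stages:

```bash
ctbodycomp phantom  --out bundle/
ctbodycomp quantify --dicom bundle/phantom.dcm --rois bundle/rois.json --out comp.csv
ctbodycomp report   --composition cohort.csv --out report/
```

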