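# cineqc

Reference-free quality control for automatic cardiac cine-MR segmentations.

Automatic deep-learning segmentation of short-axis cardiac MR — right
ventricular cavity (RVC), left ventricular myocardium (MYO) and left
ventricular cavity (LVC) — is good on average but fails silently on
individual slices, most often at the apex and base. In clinical or
large-cohort pipelines nobody re-checks thousands of masks by hand, so the
question this package answers is: **given only the image and a candidate
mask, how good is the segmentation?**

`cineqc` predicts the Dice similarity coefficient

```
DSC(X, Y) = 2 |X ∩ Y| / (|X| + |Y|)
```

of a candidate segmentation *X* against the (unavailable) reference *Y*
from radiomics features of the image region covered by *X*: shape,
first-order intensity statistics, and the five gray-level texture matrices
(GLCM, GLRLM, GLSZM, GLDM, NGTDM) — 102 features per 2D slice, 107 per 3D
structure. A gradient-boosted regressor estimates the DSC itself
(quantitative QC) and a random-forest classifier flags segmentations as
good or bad (DSC cutoff 0.7 at slice level, 0.85 at subject level). The
classifier is judged primarily by its negative detection rate,
NDR = TN / (TN + FN), the fraction of actually-bad segmentations it
catches. A two-stage filter then trusts the regressor's estimates only for
predicted-good masks.

Because real scanner data and trained segmentation networks cannot ship in
a package, training data come from a synthetic phantom cohort: stacks of
6–12 short-axis slices containing an LV-cavity disk, a myocardial annulus
and an RV-cavity crescent that taper base→apex, with disease presets (HCM,
DCM, HHD) that alter the geometry. A calibrated mask-perturbation engine
(erosion, dilation, boundary jitter, translation, slice dropping, false
blobs) degrades the ground-truth masks to any requested Dice level,
standing in for segmentation models of varying quality.

## Worked example

```python
import numpy as np
from cineqc.phantom import generate_cohort
from cineqc.pipeline import build_feature_table, run_qc_experiment

cohort = generate_cohort(8, seed=42)                      # 8 phantom subjects
table = build_feature_table(cohort, n_variants=8, seed=1, # 8 degraded variants each
                            structures=("LVC",), level="2D")
report = run_qc_experiment(table, "LVC", "2D", seed=0)
print(f"rows={len(table)}  held-out MAE={report['mae']:.3f}  "
      f"NDR={report['ndr']:.3f}  rank-corr={report['rank_correlation']:.3f}")
print(f"two-stage MAE improvement: {report['two_stage']['improvement']:.4f}")
```

prints (exact numbers from this seed):

```
rows=568  held-out MAE=0.051  NDR=0.989  rank-corr=0.964
two-stage MAE improvement: 0.0233
```

Meaning: on 568 slice-level records from unseen phantom subjects, predicted
Dice is off by 0.051 on average, 99% of actually-bad slices (true DSC < 0.7)
are caught by the classifier, and discarding predicted-bad slices lowers
the mean Dice-prediction error by 0.023.

The same workflow is available from the shell:

```bash
cineqc generate --n-subjects 10 --seed 0 --out runs/cohort
cineqc extract  --data runs/cohort --structures LVC --n-variants 8 --seed 1 --out runs/feat.csv
cineqc train    --table runs/feat.csv --structure LVC --seed 0 --out runs/models
```

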