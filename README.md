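# t1bh — quantitative T1 thresholding of MS black-hole lesions

Chronic T1-hypointense lesions ("black holes") in multiple sclerosis mark
axonal loss, but their visual definition is rater-dependent and their volume
correlates only weakly with disability. Quantitative T1 relaxation-time
(T1-RT) maps from MP2RAGE make an objective definition possible: sweep a
grid of T1-RT thresholds τ, keep at each τ only the lesion tissue with
T1-RT > τ, and ask at which τ the remaining lesion volume correlates best
with clinical disability (EDSS, MSFC). This package implements that
analysis end-to-end for neuroimaging researchers working with co-registered
NIfTI volumes — and ships a synthetic phantom cohort generator with planted
ground truth, so every stage is testable without patient data.

## What it computes

For each patient, given a T1-RT map (ms), two raters' black-hole (BH)
masks, a contrast-enhancing (CE) lesion mask, a total-FLAIR lesion mask and
cortical ROIs on one voxel grid:

- **Mask algebra** — two-rater consensus by binarized voxel-wise
  multiplication; pure-FLAIR = total-FLAIR minus (BH ∪ CE); inter-rater
  agreement by the Dice coefficient 2|A∩B|/(|A|+|B|).
- **Lesion statistics** — 26-connected component labeling; per lesion the
  voxel count, volume (mm³ from header spacing) and mean T1-RT; cortical
  mean ± SD per patient.
- **Threshold sweeps** over τ ∈ {700, 800, …, 1800} ms, two modes:
  *lesion-wise* keeps whole lesions with mean T1-RT > τ (a patient with no
  surviving lesion is excluded at that τ); *voxel-wise* keeps individual
  voxels with T1-RT > τ (no patient excluded). CE lesions are never
  thresholded.
- **Clinical scores** — EDSS validated on the 0–10 half-point grid; MSFC =
  (z_9HPT + z_T25FW + z_SDMT)/3 with z-scores against a configurable
  reference population (9-HPT scored on reciprocal time, T25-FW
  sign-flipped).
- **Correlation profiles** — tie-corrected Spearman rank correlation
  (average ranks, two-sided t-approximation p; exact permutation p for
  tiny n) between per-patient cumulative volume and each score at every τ;
  the optimal threshold is the significant τ maximizing |r|. Welch t-tests
  compare mean T1-RT between lesion classes and cortex.

The phantom module generates seeded cohorts of ellipsoidal lesions whose
counts, volumes and per-class T1-RT distributions follow published MS
cohort characteristics, with a planted threshold τ\* = 1500 ms: latent
disability is β·log(1 + V\*) + noise, where V\* is the volume of black
holes with true T1-RT above τ\*. Ground truth (lesion classes, drawn T1s,
V\*) is returned alongside, enabling parameter-recovery and type-I-error
calibration tests.

## Worked example

```python
from t1bh import phantom as ph
from t1bh.thresholding import DEFAULT_GRID, sweep_lesionwise
from t1bh.correlation import build_profile, optimal_threshold

cfg = ph.PhantomConfig(seed=7)                      # 40-patient synthetic cohort
records, summary, clinical = ph.generate_cohort_records(cfg)
bh = ph.bh_records(records)                          # black-hole lesion table
sweep = sweep_lesionwise(bh, DEFAULT_GRID,
                         patient_ids=list(summary["patient_id"]))
profile = build_profile(sweep, clinical, "edss", "lesion")
print(profile[["threshold_ms", "spearman_r", "p_value", "n_included"]]
      .round(3).to_string(index=False))
print("optimal threshold:", optimal_threshold(profile), "ms")
```

prints

```
 threshold_ms  spearman_r  p_value  n_included
        700.0       0.078    0.666          33
        800.0       0.078    0.666          33
        900.0       0.093    0.608          33
       1000.0       0.155    0.388          33
       1100.0       0.299    0.091          33
       1200.0       0.362    0.042          32
       1300.0       0.500    0.004          32
       1400.0       0.525    0.002          31
       1500.0       0.295    0.128          28
       1600.0       0.200    0.349          24
       1700.0       0.085    0.738          18
       1800.0       0.154    0.693           9
optimal threshold: 1400.0 ms
```

Unthresholded black-hole volume barely correlates with EDSS (r ≈ 0.08);
restricting to lesions with mean T1-RT above ~1300–1400 ms raises the
correlation to r ≈ 0.5 (p < 0.01), and the recovered optimum lands one grid
step below this cohort's planted τ\* of 1500 ms — within the resolution of
the threshold grid. `n_included` drops at high thresholds as patients run
out of surviving lesions, mirroring the exclusion rule of the lesion-wise
analysis.

The same analysis runs from the shell on written cohorts:

```
t1bh phantom --out cohort/ --seed 7
t1bh run --manifest cohort/manifest.json --out report/
```

`report/` then holds per-lesion tables, sweep tables, one correlation
profile CSV per mask family × score (each with lesion- and voxel-wise
rows), group comparisons, a Dice summary and a run log with the config
hash.

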