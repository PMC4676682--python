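# Methods

## Analysis model

The package quantifies how the correlation between lesion volume and
clinical disability in MS depends on a quantitative T1 relaxation-time
(T1-RT) cutoff. All per-patient volumes (T1-RT map, two raters' black-hole
masks, CE mask, total-FLAIR mask, cortical ROIs) must share one voxel grid;
registration is upstream and is checked, not corrected. Lesion classes are
nested: black holes (BH) and CE lesions are disjoint subsets of the
total-FLAIR lesions, and pure-FLAIR tissue is total-FLAIR minus (BH ∪ CE),
computed voxel-wise with clipping and a warning if the nesting is violated.

Discrete lesions are maximal connected components of a binary mask. The
default connectivity is 26 (faces + edges + corners), the common convention
for 3D lesion counting; 6 and 18 are available. Volumes are whole-voxel
counts times the voxel volume from the NIfTI header — no partial-volume
weighting. A lesion's T1-RT is the arithmetic mean over its member voxels.

Two thresholding modes are implemented over the grid 700…1800 ms in 100 ms
steps. Lesion-wise: a lesion survives at τ iff its mean T1-RT is strictly
greater than τ (a boundary-equal lesion drops); a patient with no surviving
lesion is *excluded* from that threshold's correlation. Voxel-wise: mask
voxels with T1-RT > τ are counted; every patient is retained, possibly with
volume 0. CE lesions are unaffected by thresholds and are excluded from the
thresholded volumes of both mask families; the thresholding functions
reject CE records outright.

Correlation is the Spearman rank correlation with average ranks (i.e. the
Pearson correlation of the rank vectors, the standard tie-corrected form —
EDSS is heavily tied, so this matters). Two-sided p-values use the t
approximation t = r√((n−2)/(1−r²)), adequate at n ≈ 30–40; an exact
permutation p is available below n = 10. A constant vector leaves r
undefined and is reported as such, not silently NaN-propagated. Profiles
are computed at α = 0.05 per threshold without multiplicity correction,
matching how such sweeps are conventionally reported; each profile
additionally flags how many thresholds would survive Bonferroni across the
grid, as an extension. The optimal threshold is the significant τ
maximizing |r|; ties resolve to the lowest τ (retaining the most volume);
no significant τ yields "none". Group contrasts on lesion-level mean T1-RT
(and per-patient cortical means) use Welch's unpaired t-test.

MSFC scoring follows the standard composite: the mean of three subtest
z-scores, with SDMT substituting PASAT. Orientations: SDMT z on the raw
correct-response count; T25-FW z sign-flipped (longer walk = worse); 9-HPT
z computed on the reciprocal of time. The reference population
(mean/SD per subtest) is a required configuration input — it is a property
of the normative dataset, not of this package — and the phantom supplies
its own (SDMT 55 ± 11 correct, T25-FW 4.8 ± 1.2 s, 9-HPT reciprocal
1/19 ± 0.006 s⁻¹, healthy-adult scale values). Any missing subtest removes
the composite and drops the patient from MSFC analyses only.

## The phantom

The generator produces seeded cohorts with known ground truth. Per patient:

- Lesion counts: black holes ~ round(N(22.3, 17.07)) clipped at 0,
  pure-FLAIR ~ round(N(19.95, 17.18)); 37.5% of patients carry 1–3 CE
  lesions. Lesions are axis-aligned ellipsoids with semi-axes uniform in
  1.5–4 mm, voxelized on a 128³, 1 mm isotropic grid by exact center-offset
  membership; volumes are therefore analytically checkable by brute-force
  enumeration.
- Lesion-level mean T1-RT per class: BH 1453.3 ± 213.4 ms, pure-FLAIR
  1331.2 ± 226.8 ms, CE 1350 ± 150 ms (CE is not reported separately in
  the cohort characteristics the defaults emulate; the value sits between
  the other classes). A patient-level severity component shares a fraction
  `t1_icc` = 0.6 of the class variance across all of a patient's lesions,
  preserving the marginal distribution. Without it, above- and
  below-threshold volumes are both proportional to the patient's lesion
  count and the planted threshold is not identifiable at n = 40; with it,
  T1 composition varies between patients, as the premise of the analysis
  assumes. Voxels scatter around their lesion's mean with SD 50 ms;
  background white matter is N(850, 50) ms; four spherical cortical ROIs
  carry a patient-level mean ~ N(1305.6, 35.8) ms.
- Every black hole sits inside a FLAIR footprint one voxel larger per
  semi-axis; the rim voxels draw their T1 from the pure-FLAIR distribution
  (the rim is less damaged tissue), which separates the class means the way
  real cohorts show. Lesions are placed largest-first by rejection sampling
  of axis-aligned exclusion boxes, guaranteeing ≥ 2 voxels between any two
  footprints — component labeling recovers the planted count exactly. If
  the grid cannot host the requested count, the generator warns and reports
  the count actually placed.
- Rater 2's BH mask re-voxelizes each lesion with semi-axes and center
  jittered by U(−0.6, +0.6) voxels (clipped into the FLAIR footprint).
  Whole-voxel dilation/erosion was rejected as a perturbation model: on
  2–4 mm lesions a single-voxel erosion already drops per-lesion Dice to
  ~0.4, far past the empirical two-rater agreement of ≈ 0.8; continuous
  jitter gives a smooth calibration knob. The default 0.6 was calibrated
  to a cohort-mean Dice of ≈ 0.80.
- Disability: latent η = β·log(1 + V\*) + N(0, 1), where V\* is the volume
  of black holes whose *true* lesion-level T1-RT exceeds the planted
  τ\* = 1500 ms. EDSS is η's cohort rank mapped through a N(2.2, 1.5)
  quantile function, clipped to [0, 6.5] and rounded to the half-point grid
  (ordinal and tie-heavy, median 2). MSFC subtest z-scores are
  0.98 − standardize(η) + N(0, 0.6) independently per subtest (higher
  disability → lower MSFC, composite centered near 1 with SD ≈ 1.1); raw
  subtest values are back-computed from the reference population so
  re-scoring the table reproduces them. 25% of patients lack MSFC. Disease
  duration is rank-mapped onto a truncated exponential (mean 6.8 y, max
  22 y) with a 0.45 latent correlation to total lesion volume. β = 0.45
  was fixed once so that the lesion-wise BH–EDSS profile peaks at
  |r| ≈ 0.5, the magnitude regime the analysis is designed for.
- Seeding: one master seed spawns per-patient sub-seeds through
  `numpy.random.SeedSequence` spawn keys, so any patient is reproducible in
  isolation and cohorts of different sizes share their common prefix.

Two generation paths share the identical lesion-attribute stream. The
volumetric path rasterizes T1 maps and masks (used by the mask-algebra,
Dice and labeling tests and by the pipeline). The record-level path skips
rasterization but still draws every lesion's individual voxel T1 values,
deriving observed lesion means and voxel-wise threshold counts from the
same draws; it powers the replicate-heavy simulations (threshold recovery,
null calibration) at ~0.4 s per 40-patient cohort. Simulation sizes in the
test suite — 100 recovery replicates, 500 null replicates, 100 oracle
masks of 20³ — were chosen as the smallest runs whose pass/fail decisions
are stable across reruns.

### What the phantom does not emulate

No bias fields, no partial-volume effects beyond voxelized ellipsoids, no
registration error, no spatially structured noise, and no lesion-location
effects. Lesion shapes are ellipsoids, not the confluent irregular shapes
of real MS lesions; in particular the phantom plants one FLAIR lesion per
black hole and cannot reproduce cohorts where one large FLAIR lesion
fragments into several visually marked black holes (there, the BH count
exceeds the FLAIR count). Passing tests therefore demonstrate the
correctness and calibration of the *analysis machinery* under known truth,
not the clinical validity of any particular threshold on real data.

## Numerical and design notes

- Strict ">" inclusion everywhere a threshold is applied, so two
  consecutive thresholds with no lesion mean between them give identical
  volumes.
- Dice of two empty masks is defined as 1.0 (logged); the cohort summary
  reports both the mean of per-patient Dice values and the pooled
  (voxel-sum) Dice.
- Mean cumulative volumes per threshold are reported under both averaging
  conventions — over all patients and over included patients — since
  either reading is defensible for a cohort table.
- Masks are binarized at > 0 on load; non-binary values are reported, as
  are BH voxels outside the FLAIR mask (count included) and BH∩CE overlap.
- The sweep filters a per-lesion table computed once rather than
  re-scanning volumes per threshold; equivalence to per-threshold
  recomputation is covered by a dedicated test.
- Lesion-wise exclusion is applied per threshold and every exclusion
  (patient, threshold, reason) is logged in the report bundle. Note a
  structural consequence verified in simulation: excluding zero-lesion
  patients truncates the low-severity end of the cohort and biases the
  lesion-wise argmax of |r| below the planted τ\*, while the voxel-wise
  profile (no exclusions) localizes τ\* reliably — one more reason the two
  modes are reported side by side.
- Pipeline outputs are deterministic given inputs: rerunning produces
  byte-identical CSVs; every output carries a SHA-256 config hash prefix.
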