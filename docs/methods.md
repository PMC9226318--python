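# Methods

`taoscope` re-creates, without trained network weights, a three-stage
photographic screening pipeline for thyroid-associated ophthalmopathy
(TAO): locate the eyes on a face photograph, segment cornea and sclera in
each eye crop, and turn per-gaze segmentations into clinical sign calls —
most importantly an ocular-motility (duction) assessment over the nine
cardinal gaze positions. Because the clinical photograph corpus such a
system is normally trained and evaluated on is not publicly available, the
package ships a parametric synthetic eye/face simulator that generates
images, pixel-perfect ground truth and cohort manifests with the
statistical structure the pipeline assumes. This note records the models,
conventions, parameters and limitations.

## Coordinate and raster conventions

All geometry lives in image coordinates: `x` along columns (rightward),
`y` along rows (downward), 0-based. A mask pixel `(r, c)` covers the
half-open cell `[c, c+1) x [r, r+1)`; its center is `(c + 0.5, r + 0.5)`.
Polygon rasterization includes a pixel iff its center is inside or on the
polygon boundary (shapely `covers`), which matches a brute-force
point-in-polygon test exactly and makes rasterized areas deterministic.

Canthus landmarks are reported as integer pixel coordinates (the raw
horizontal extremes of the fissure mask, vertical-median tie-break). Two
sub-pixel compensations follow from the half-open convention:

* the lateral rule line is placed on the **outer edge** of the canthus
  pixel (`x = c + 1` for the right canthus, `x = c` for the left), so a
  cornea rendered exactly tangent to the true canthus vertex reads as
  tangent, not separated, after rasterization;
* the intercanthal line runs through the two canthus **pixel centers**.

## The gaze rule engine

For each eccentric gaze the engine fits a circle to the corneal boundary
and classifies its relation to a rule line with signed clearance
`d(center, line) − radius`:

* **Lateral gaze** (nonzero horizontal component only): rule line is the
  vertical line through the gaze-side canthus. *Impaired iff separated*;
  tangent or intersecting is normal duction (the cornea reached the
  canthus).
* **Vertical gaze**: rule line is the infinite line through inner and
  outer canthus. *Impaired iff intersecting*; tangent or separated is
  normal (the cornea cleared the line).
* **Oblique gaze**: both component rules are evaluated and impairments
  combined by OR — the conservative screening choice, since the clinical
  rules are stated only for pure lateral and vertical gaze. The verdict
  records both component clearances.

The tangency band is `max(1.0, 0.02 × radius)` pixels: it absorbs
rasterization error on small corneas and scales with corneal size on
large ones; it is exposed in the pipeline configuration
(`tolerance_px`). Patient-level aggregation is OR over all determinate
verdicts (two eyes × eight eccentric gazes): any restricted duction is a
motility disorder. Verdicts with no visible cornea are *indeterminate*:
excluded from the OR but counted, so a closed eye never silently reads as
normal; a patient with only indeterminate verdicts is an error, not a
negative.

### Circle fitting

The corneal boundary is the 0.5-level contour of the cornea mask
(sub-pixel, via marching squares). Contour points lying on the fissure
outline — where the visible cornea is clipped by an eyelid and the
boundary no longer follows the corneal circle — are excluded using the
fissure's Euclidean distance transform (points within 1.5 px of
background are dropped; if fewer than 8 points survive, the full contour
is used). The fit is algebraic least squares (Kåsa): closed form,
deterministic, and exact on noiseless circles at any radius.

One failure mode matters: in extreme lateral gaze the cornea's leading
edge hides under the canthus corner and the visible boundary is a short
*trailing* arc (~100°). On such arcs the free fit trades radius against
center along the arc axis, and the clearance — an extrapolation across
the full diameter — absorbs both errors (up to ~1.5 px at tangency).
Since the cornea is rigid, the patient-level engine fixes this by pooling
a per-eye radius (median of the free fits across that eye's gazes) and
refitting only the circle center per gaze with the radius held fixed,
which restores tangency clearance to ~0.1 px. Single-gaze calls
(`assess_gaze` without a `radius` argument) use the free fit.

### Brute-force oracle

`pixel_oracle_verdict` re-derives verdicts with no circle fit: signed
distances of cornea pixel centers to the rule lines, minimum as
clearance, same tolerance and rule tables. Half a pixel is subtracted
from the minimum because pixel centers sit on average half a cell inside
the continuous region boundary; without the inset the pixel estimate of
clearance is systematically ~0.5 px too large. When validating against
the generator, the oracle can be given the rasterized *unclipped*
corneal disk: in extreme adducted/elevated gaze the visible (lid-clipped)
pixels cannot reach the canthus even though the cornea does — which is
precisely why the method fits a circle rather than counting pixels.

## The synthetic simulator

Each eye tile contains:

* a palpebral fissure drawn as two parabolic arcs between the two canthi,
  with height = `aperture_ratio` × intercanthal width. Default canthi sit
  at 8% and 92% of the tile width on a pixel-center-aligned row; default
  `aperture_ratio` 0.36 (roughly a 30 × 10 mm adult fissure),
  retraction phenotype ~0.50;
* a sclera filling the fissure, white (242/255) with a red-channel-
  preserving tint proportional to `redness` (conjunctival congestion);
* a corneal disk of radius ~17% of the intercanthal width (≈ the 11.5 mm
  corneal diameter against a 30 mm fissure), clipped by the fissure
  polygon — only the visible cornea is labeled, matching what an
  annotator can trace;
* a skin surround with a reddened lid band proportional to `lid_redness`
  (eyelid congestion) and additive Gaussian noise, σ = 5/255 by default.

**Gaze displacement.** The corneal center moves from the fissure center
along the gaze components by `motility × maximal excursion` per axis,
where the maximal excursion is *defined* as the displacement that makes
the circle exactly tangent to the corresponding rule line (the gaze-side
canthus line horizontally; the intercanthal line vertically). Full
motility therefore *is* tangency by construction, which is exactly the
rule's definition of normal duction.

**Label coupling.** The movement-disorder label is tied to the
continuous parameter by *impaired iff motility < 0.7 in at least one
gaze*. Simulated impaired patients receive 1–4 impaired (eye, gaze)
slots with motility ~ U(0.2, 0.65) — the band below 0.65 keeps label
noise away from the rule boundary, per the threshold's rationale —
and all other gazes at full excursion; unimpaired patients render every
gaze at motility 1.0, the clinical meaning of normal duction. Other sign
labels map to phenotypes monotonically (retraction → aperture,
conjunctival congestion → scleral redness, eyelid congestion → lid-band
redness); chemosis, corneal ulcer and eyelid edema get manifest labels
but no renderable phenotype (faking a texture would manufacture unearned
scorer accuracy), so those scorers are near chance on synthetic data by
design.

**Cohort.** Signs are sampled independently per patient at the published
cohort prevalences (e.g. movement disorders 1209/1560 = 77.50%,
conjunctival congestion 62.63%); age-band and sex frequencies follow the
same cohort table. The view plan (1 anteroposterior + 9 nine-gaze + 2
lateral images per patient) is configuration, not hard-coded. All
randomness flows from one integer seed through per-patient `SeedSequence`
substreams; the same seed reproduces byte-identical manifests and images.
Lateral (profile) views are rendered as single-eye stand-ins — a true
90° profile is outside the renderer's scope; the rows exist so the
manifest and harness see the full plan.

What the simulator does **not** model: photometric variation (lighting,
white balance, skin-tone diversity), head tilt, eyelashes and shadows,
specular reflections, partial blinks, and any correlation between signs.
Passing tests on this test bed demonstrate the pipeline's internal
consistency and the rule engine's geometric correctness — not clinical
performance on photographs.

## Detection and segmentation baselines

Both baselines operate on a skin-contrast field: the Euclidean distance
of each pixel's color from the border-median skin estimate. The field has
three populations (skin ≈ 0; tinted tissue — congested sclera or lids —
mid; dark cornea and white sclera high), so the **lowest of the 3-class
multi-Otsu thresholds** separates skin from non-skin (a 2-class Otsu
drops a congested sclera). An opening (disk 1) removes noise speckles
before a closing (disk 3) consolidates regions, so speckles cannot bridge
into components.

* **Detector**: the two largest components become eye candidates; boxes
  are component extents padded by 8% of the component diagonal per side,
  sorted left-to-right (image-left = anatomical right eye). Fewer than
  two candidates is a detection-failure *value* (empty list), so batch
  runs log-and-skip. The 8% padding keeps lid/canthus context while
  holding the padded box above 0.5 IoU against a tight fissure-extent
  box at realistic eye aspect ratios (a 25%-of-diagonal pad gives
  IoU ≈ 0.26 and can never match the ground truth). Known limitation: a
  heavily reddened lid band joins the component, and those patients'
  boxes fall below 0.5 IoU against tight ground truth even though the
  eye is correctly localized.
* **Crops**: half-open box crop, bilinear resize to 224 × 224,
  intensities scaled to [0, 1].
* **Segmenter**: fissure = largest non-skin component; cornea = largest
  dark blob inside it (Otsu over within-fissure brightness), accepted
  only if circularity `4πA/P² ≥ 0.6` (rejects eyelash/shadow blobs while
  tolerating lid-clipped corneas); sclera = remainder. A crop flat
  against its border skin tone yields all-background plus a warning.
  Empty-vs-empty IoU is defined as 1.0 (nothing to find, nothing found).

Because the square resize distorts the box aspect ratio (circle →
ellipse), the pipeline maps predicted crop masks back to the box's native
resolution (nearest-neighbour) before the rule engine runs; tangency is
not affine-invariant for a *circle* fit, so the rules always run in
undistorted coordinates.

## Sign scorers

One scorer per sign behind a uniform registry contract
(`(crop, segmentation) → probability`, deterministic, mirror-symmetric
features): scleral red-excess for conjunctival congestion, lid-band
red-excess for eyelid congestion, aspect-corrected fissure
height/width for eyelid retraction, lid-band brightness variance for
edema, and the rule engine's impairment margin (logistic with a 2 px
scale) for movement disorders. Feature scorers pass through a 1-D
logistic calibration fitted once on a seeded synthetic calibration set
(seed 20220610, 160 crops per sign, balanced labels) and shipped as
package data (`taoscope/data/calibration.json`); `fit_calibration`
regenerates it. Chemosis and corneal ulcer are registered as flagged
constant-prior (0.5) scorers — chemosis is essentially undetectable from
frontal images and ulcers have no renderable phenotype — and flagged
scorers are excluded from mean-row aggregation unless explicitly
included.

## Evaluation harness

* AUROC by the rank (Mann–Whitney) statistic, ties ½; cross-checked in
  the tests against exhaustive pair counting.
* 95% CIs by stratified percentile bootstrap (resampling within class;
  default 2000 resamples, 200 in the pipeline for runtime); undefined
  resamples are redrawn and counted.
* Sensitivity/specificity/F1 from the 2 × 2 table at an operating
  threshold chosen by the Youden index on the validation split (midpoint
  candidates between consecutive unique scores), frozen before test
  evaluation; if the validation split is single-class the threshold
  widens to train+validation, then falls back to 0.5.
* Splits are patient-level (70/10/20 by default — 20% test, with 10% of
  the total held inside the training side for validation), seeded, with
  largest-remainder sizing; all of a patient's images share a split.
* Prevalence percentages are exact rational arithmetic rounded half-up
  to two decimals only at the formatting layer.
* Per-patient sign score = max over that patient's eligible images (a
  sign in either eye is a positive patient); the movement probability
  comes from the patient's pooled impairment margin.

## Pipeline reproducibility

Stages communicate through files (PNG/CSV/JSON); each stage is
independently runnable from the CLI and replaceable by a learned
component. `report.json` contains no timestamps or absolute paths and is
a pure function of (config, seed): two runs with the same configuration
are byte-identical. The effective config and tool version are echoed
into every run directory.

## Problem sizes

Default experiment scales, chosen to exercise the statistics they feed:
200 patients (× 2 eyes × 8 gazes) for motility parameter recovery, 100
rasterized eyes for the rule-engine/oracle comparison, 200 crops for
scorer recovery, 50 zero-noise faces for detector accuracy, 50-patient
cohorts (600 images) for end-to-end pipeline runs.

## Known limitations

* The canthus "vertex" construction (horizontal extremes) assumes a
  near-horizontal palpebral axis; head tilt is not corrected.
* Ellipse fitting for oblique corneal projections is out of scope; the
  cornea is modeled as a circle in the image plane.
* The intercanthal chord of the renderer is drawn between the canthus
  points; strongly tilted chords (> a few degrees) thin the fissure tips
  below one pixel and canthus localization degrades by 1–2 px.
* Rule verdicts for gazes whose cornea is fully hidden are indeterminate
  rather than imputed.
* Baseline scorers are calibrated on, and only meaningful for, the
  synthetic phenotype distributions; they make no clinical claim.
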