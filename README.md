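# taoscope

Weight-free facial-image screening pipeline for thyroid-associated
ophthalmopathy (TAO).

TAO is an autoimmune orbital disease whose signs — eyelid retraction,
congestion, edema, and above all restricted eye movements — are visible on
ordinary photographs, yet few clinicians outside specialist centers can
read them reliably. A photographic screening system works in three stages:
locate the eyes on a face image, segment cornea and sclera in each eye
crop, and turn the segmentations into per-sign calls. The motility stage
is purely geometric: photograph the patient in the nine cardinal gaze
positions and, per eccentric gaze, test the corneal circle against a rule
line.

**The gaze rules.** Fit a circle (center **c**, radius *r*) to the
corneal boundary and compute the signed clearance to a line *L*,

&nbsp;&nbsp;&nbsp;&nbsp;δ = d(**c**, L) − r,

with a tangency band |δ| ≤ τ, τ = max(1, 0.02 r) px. For *lateral* gaze,
*L* is the vertical line through the gaze-side canthus: the eye is
**impaired iff separated** (δ > τ — the cornea never reached the
canthus). For *vertical* gaze, *L* is the intercanthal line: **impaired
iff intersecting** (δ < −τ — the cornea failed to clear it). Oblique
gazes evaluate both rules and OR the impairments; a patient is impaired
iff any determinate per-eye, per-gaze verdict is. Detection and
segmentation quality are measured by IoU (area of overlap over area of
union), sign calls by AUROC, sensitivity, specificity and F1 with
stratified-bootstrap 95% CIs.

No trained weights or clinical images ship with the package. Classical
baselines (multi-Otsu thresholding + morphology) stand behind the same
interfaces a learned detector/segmenter/classifier would implement, and a
parametric synthetic eye/face simulator provides images, pixel-perfect
ground truth and cohort manifests for end-to-end validation. See
`docs/methods.md` for the models, conventions and limitations.

## Worked example

Render a healthy and a motility-restricted eye in left gaze and apply the
rule engine:

```python
from dataclasses import replace
from taoscope import EyePhenotype, gaze, render_eye, assess_gaze, diagnose_patient
from taoscope.synthetic import ECCENTRIC_GAZES

phen = EyePhenotype.default(160)                  # healthy right eye
weak = replace(phen, motility={"left": 0.45})     # restricted adduction

for name, p in [("healthy", phen), ("restricted", weak)]:
    eye = render_eye(p, gaze("left"), image_size=160, seed=0)
    v = assess_gaze(eye.segmentation, gaze("left"), eye_side="right")
    print(f"{name:10s} gaze=left relation={v.relation.relation:12s} "
          f"clearance={v.relation.signed_clearance:+.1f} px impaired={v.impaired}")

exams = [("right", g, render_eye(weak, g, 160, seed=0, with_image=False).segmentation)
         for g in ECCENTRIC_GAZES]
report = diagnose_patient(exams)
print(f"patient impaired: {report.patient_impaired} "
      f"({sum(bool(v.impaired) for v in report.verdicts)}/8 gazes flagged)")
```

```
healthy    gaze=left relation=intersecting clearance=-1.5 px impaired=False
restricted gaze=left relation=separated    clearance=+24.3 px impaired=True
patient impaired: True (1/8 gazes flagged)
```

The healthy eye at full excursion reaches the canthus (the fitted circle
just crosses the canthus line — normal duction); the restricted eye stops
24 px short of it, so that gaze is flagged and the patient-level OR turns
positive.

The full pipeline — simulate a cohort, detect, crop, segment, assess
motility, score signs, evaluate — runs from the command line:

```bash
taoscope run --seed 7 --out runs/demo     # writes runs/demo/report.json
```

`report.json` holds per-sign AUROC/sensitivity/specificity/F1 rows with
bootstrap CIs, a mean row, cohort prevalences and detection accuracy, and
is byte-identical across reruns with the same config and seed. Individual
stages (`taoscope simulate|detect|segment|motility|signs|evaluate`)
operate on the same run directory through files, so any stage can be
re-run or replaced independently.

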