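# glaucoscreen

Interpretable, hierarchical glaucoma screening from colour fundus
photographs — with a built-in synthetic optic-nerve-head simulator so the
whole pipeline can be trained, evaluated and reproduced without any
clinical data.

## Who this is for

Researchers and engineers working on explainable retinal-image screening:
the package implements a full screening hierarchy in which every stage
after the first is transparent, and the final call is made from two
clinically meaningful numbers plus one anatomical flag rather than from a
black-box score.

## The method

Glaucomatous optic neuropathy (GON) shows in a fundus photograph as an
enlarged optic cup relative to the optic disc, loss of the normal
neuroretinal-rim shape, and wedge-shaped retinal nerve fiber layer defects
(RNFLD). The pipeline mirrors how a specialist reads these signs:

1. **Pre-diagnosis.** A classifier produces a glaucoma probability from
   the whole image; the label threshold is 0.8, with ties called glaucoma.
2. **Diagnosis-conditioned segmentation.** Disc, cup and RNFLD are
   segmented per pixel. The *cup* segmenter is selected by the
   pre-diagnosis: a glaucoma-specific model (trained on referable eyes
   only) when the pre-diagnosis says glaucoma, a general model otherwise.
   Only the cup can change with the pre-diagnosis — disc and RNFLD never do.
3. **Rim features.** From the masks, a 360-dimensional cup-to-disc-ratio
   profile CDR(θ) is measured radially from the disc centroid (0° =
   superior, clockwise; left eyes mirrored into the right-eye frame). Its
   mean is the MCDR. The **ISNT score** is

       s = (1/360) · ⟨ z(CDR), b ⟩,

   where z(·) standardizes a profile to mean 0 / SD 1 and b is the
   standardized average profile of a cohort of normal eyes. Normal rims
   follow the ISNT rule (inferior ≥ superior ≥ nasal ≥ temporal rim
   width), giving the profile a characteristic bimodal shape; s ∈ [−1, 1]
   measures conformity with it.
4. **Decision layer.** A linear SVM in the (MCDR, s) plane gives a
   classification line; Platt calibration maps its signed margin to a
   probability p₁. The final label follows a decision tree: RNFLD present
   → glaucoma; otherwise points on or above the line (the high-ISNT side)
   are normal, points below are glaucoma. The fused probability is
   p = (1 + p₁)/2 with RNFLD and p = p₁ without, and p is thresholded into
   confidence regions: reliable glaucoma (p ≥ 0.8), reliable normal
   (p ≤ 0.2), suspicious in between.

The simulator (`glaucoscreen.simulate`) draws parametric eyes — elliptical
disc, analytic rim profile, notches, rim thinning, RNFLD wedges,
hemorrhage/atrophy distractors — renders 512×512 images with exact
ground-truth masks, and grades each eye by the clinical rules
(unlikely / probable / definite GON; referable = probable or definite).

## Worked example

```python
import numpy as np
import glaucoscreen as gs
from glaucoscreen.decision import compute_training_features, fit_decision_line, diagnose
from glaucoscreen.geometry import build_baseline, compute_cdr_profile
from glaucoscreen import metrics

mix = {"unlikely": 0.5, "probable": 0.25, "definite": 0.25}
train = gs.generate_dataset(300, mix, seed=1000)
test = gs.generate_dataset(200, mix, seed=2000)

bundle = gs.train_bundle(train, gs.TrainConfig(epochs=30, seed=0))
baseline = build_baseline([compute_cdr_profile(e.masks) for e in train.eyes
                           if e.truth.grade.category == "unlikely"])
feats = compute_training_features(train, bundle, baseline)
boundary = fit_decision_line(feats, train.referable_labels)

diags = [diagnose(e.image, bundle, boundary, baseline,
                  laterality=e.truth.laterality, eye_id=e.id) for e in test.eyes]
auc = metrics.roc_auc([d.p for d in diags], test.referable_labels)
table = metrics.region_table(diags, test.referable_labels)
print(round(auc, 3))
print(table[["region", "sensitivity", "specificity"]].round(3))
```

Output from this exact run:

```
0.991
       region  sensitivity  specificity
0     overall        0.820          1.0
1    reliable        0.944          1.0
2  suspicious        0.517          1.0
```

The AUC (0.991) is computed from the fused probability p. The region table
mirrors how screening confidence behaves: most eyes land in the reliable
region, where sensitivity is much higher than in the yellow "suspicious"
band that collects the cases a clinician should re-read. The missed
positives are mostly probable-GON eyes whose only sign (for example a
hemorrhage) is invisible to the interpretable feature layer by design —
see `docs/methods.md`. Numbers vary a little with the seed; the test
suite checks the stable properties.

The same pipeline is scriptable from the shell:

```bash
glaucoscreen simulate --n 100 --seed 1 --out data/cohort
glaucoscreen baseline --cohort data/cohort --out data/baseline.csv
glaucoscreen train --cohort data/cohort --baseline data/baseline.csv --out models/
glaucoscreen diagnose --cohort data/cohort --models models/ \
    --baseline data/baseline.csv --boundary models/boundary.json --out diag.jsonl
glaucoscreen evaluate --diagnoses diag.jsonl --cohort data/cohort --out-prefix eval
glaucoscreen report --cohort data/cohort --diagnoses diag.jsonl \
    --boundary models/boundary.json --eye-id eye_0000 --out reports/
```

`report` writes the transparency figures: the segmentation overlay and the
(MCDR, ISNT) plane shaded red / green / yellow by confidence region with
the evaluated eye marked on it.

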