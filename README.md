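# tiradscope

Explainable automated ACR TI-RADS evaluation of thyroid-nodule ultrasound
images.

Thyroid nodules found on neck ultrasound are risk-stratified with the
American College of Radiology Thyroid Imaging Reporting and Data System
(ACR TI-RADS, 2017): five feature axes — composition, echogenicity, shape,
margin and echogenic foci — are scored additively, the total maps to a risk
level TR1–TR5, and the level plus the nodule's maximum diameter decides
between no action, follow-up ultrasound and fine-needle aspiration (FNA).
Scoring is standardised but reader-dependent; `tiradscope` automates it and
keeps the decision process inspectable for the radiologist.

The package is aimed at medical-imaging researchers who want an end-to-end,
reproducible TI-RADS pipeline they can train, probe and extend on a single
CPU. It contains:

* **`tirads_rules`** — the deterministic ACR TI-RADS 2017 scorer
  (points → TR level → suspicion % → size-gated recommendation);
* **`preprocess`** — nodule crop with a 5 % per-side margin, resize to
  512×512, 3×3 stride-1 max-pool sharpening, and assembly of the
  three-plane network input (raw, sharpened, segmentation mask); nodule
  shape and size are measured from the mask in millimetres, never learned;
* **`net`** — a multi-output CNN (compact NumPy implementation with
  explicit forward/backward passes and Adam) with one head per feature
  axis plus malignancy, trained with the unweighted eight-term loss
  `L_all = L_m + L_p + L_a + L_b + L_c + L_d + L_e + L_f`.  Two head
  designs: `v1` (softmax classifiers throughout) and the refactored `v2`
  (independent cystic/solid/spongiform sigmoids with a programmatic
  "mixed" rule, a linear echogenicity regression with integer codes 0–3,
  and a margin head that merges ill-defined with smooth);
* **`explain`** — per-head Grad-CAM maps, multiplied by the head's
  predicted probability (`map_modified = p_o × map`), rendered as
  pseudo-colour overlays;
* **`synthgen`** — a seeded generator of speckled ultrasound-like nodule
  images with exact ground-truth labels, including a bundled study
  profile (1328 training and 149 test cases; 673 benign / 804 malignant);
* **`cli`** — the `tiradscope` command with `score`, `synth`,
  `preprocess`, `train`, `eval`, `explain`, `report` and `run`
  subcommands, driven by one YAML config and one root seed.

## Worked example

Score the two canonical patterns with the rule engine:

```python
from tiradscope import NoduleFeatures, assess, score_features

benign = NoduleFeatures("mixed", "hyperechoic", "wider_than_tall",
                        "smooth", frozenset(), max_diameter_mm=12.0)
print(score_features(benign).total_pts, assess(benign))
# 2 TiradsAssessment(tr_level=2, suspicion_pct=1.5, recommendation='no_action')

malignant = NoduleFeatures("solid", "hypoechoic", "taller_than_wide",
                           "lobulated_irregular", {"punctate_micro"},
                           max_diameter_mm=20.0)
print(score_features(malignant).total_pts, assess(malignant))
# 12 TiradsAssessment(tr_level=5, suspicion_pct=35.0, recommendation='fna')
```

The benign mixed solid–cystic pattern scores 1+1 = 2 points → TR2, a
low-suspicion (1.5 %) nodule needing no intervention at 12 mm.  The solid,
hypoechoic, taller-than-wide, lobulated nodule with punctate
microcalcifications scores 2+2+3+2+3 = 12 points → TR5 (35 % suspicion),
and at 20 mm crosses the 10 mm TR5 gate for FNA.

The same from the shell:

```sh
echo '{"composition":"solid","echogenicity":"hypoechoic","shape":"taller_than_wide",
       "margin":"lobulated_irregular","foci":["punctate_micro"]}' > features.json
tiradscope score --features features.json --size-mm 20
```

A full synthetic pipeline run (generate → train → evaluate → per-nodule
reports with heatmaps):

```sh
tiradscope run --config my_config.yaml   # or no --config for the demo run
```

which logs a per-head accuracy table in the usual
classification-type × accuracy layout and writes, per test nodule, a
`report.json` (per-head probabilities, points breakdown, TR level,
suspicion %, recommendation) plus eight Grad-CAM overlay PNGs.

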