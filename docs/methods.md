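# Methods

## Rule engine

The scorer implements the ACR TI-RADS 2017 point chart: composition
(cystic 0, spongiform 0, mixed 1, solid 2), echogenicity (anechoic 0,
hyperechoic 1, hypoechoic 2, very hypoechoic 3; isoechoic nodules belong
to the 1-point class), shape (wider-than-tall 0, taller-than-wide 3),
margin (smooth 0, ill-defined 0, lobulated/irregular 2, extrathyroidal
extension 3) and additive echogenic-foci points (comet-tail 0, macro 1,
peripheral 2, punctate micro 3).  Totals map to levels as 0–1 → TR1,
2 → TR2, 3 → TR3, 4–6 → TR4, ≥ 7 → TR5; a 1-point total (possible, e.g.
mixed + anechoic) is treated as TR1, which keeps the mapping monotone and
matches common calculator behaviour.  Size gates are inclusive: TR3
follow-up ≥ 15 mm / FNA ≥ 25 mm, TR4 ≥ 10 / ≥ 15 mm, TR5 ≥ 5 / ≥ 10 mm;
TR1–TR2 never trigger action.  The ACR "benign" shortcut (spongiform or
pure cyst ⇒ no FNA regardless of points) is deliberately not applied;
scoring stays plainly additive.  Suspicion percentages are a
per-level lookup (defaults 0.3, 1.5, 4.8, 9.1, 35 % for TR1–TR5, from the
validation literature behind the chart) and are overridable per call.

## Preprocessing

Crops use the tight mask bounding box expanded by 5 % of the box extent
per side (margin is relative to the nodule, not the frame), in 0-based
half-open row-major coordinates, then a bilinear resize of the intensity
plane and nearest-neighbour resize of the mask to 512×512 (configurable).
Pixel spacing is rescaled per axis so physical measurements survive the
resize.  Sharpening is a 3×3 max-pool with stride 1 — grayscale dilation
with a flat 3×3 element — with replicate edge padding, which guarantees
the sharpened plane dominates the raw plane pointwise everywhere.  Shape
is decided in millimetres from the mask bounding box (strictly taller ⇒
taller-than-wide; squares and circles are not "taller"), so it is
invariant to intensity and, because spacing is rescaled, to the resize;
anisotropic spacing is honoured.

## Network

The classifier is a shared convolutional backbone, global average
pooling, and one linear head per output surface.  It is implemented
directly in NumPy — im2col convolutions, explicit layer-by-layer backward
passes, He initialisation, Adam — which keeps the whole training and
explanation path inspectable and dependency-light, and exposes exactly
the activation gradients Grad-CAM needs.  Backbones:

* `tiny_resnet` (default): a stride-4 7×7 stem plus four residual blocks
  (3×3 convs with 1×1 strided shortcuts), 64 final channels.  One
  forward+backward pass on a 3×512×512 input takes well under a second
  on one CPU core.
* `tiny_densenet`: stem plus two 3-layer dense blocks (growth 8) with
  1×1 transition convs and 2×2 average pooling.
* `micro`: two convolutions; used for finite-difference gradient checks.
* `resnet50` / `densenet201`: full-depth variants of the same block
  families, constructible for completeness but impractical to train on
  CPU; no pretrained weights are bundled, and requesting them raises.

Heads and losses (`L_all` is the unweighted sum of eight terms —
malignancy, composition, four foci, echogenicity, margin):

* v1: 4-class softmax composition/echogenicity/margin with
  cross-entropy; logistic malignancy and four independent logistic focus
  detectors with binary cross-entropy.
* v2: composition becomes three independent sigmoids (cystic, solid,
  spongiform); its loss term is the sum of the three per-component
  binary cross-entropies, and "mixed" is decided programmatically when
  both cystic and solid strictly exceed the threshold (default 0.5 — the
  rule uses strict `>`).  Echogenicity becomes a single linear output
  with integer targets 0–3 coding hyperechoic, hypoechoic, very
  hypoechoic, anechoic, trained with squared error and decided by
  nearest integer (ties round half away from zero, then clamp to
  [0, 3]).  The margin head drops the ill-defined unit and merges it
  with smooth — score-neutral because both classes carry 0 points.

Training defaults (the source material specifies none): Adam at
lr 3e-3, batch size 16, per-epoch reshuffling from a seeded generator.
All loss terms are batch means, so `L_all` is exactly the sum of the
eight per-head terms in evaluation order.  Per-head accuracies are
reported in a classification-type × accuracy table; v2 margin accuracy is
judged on the merged 3-class axis.

## Grad-CAM

The target layer is the last spatial feature map before the fully
connected heads (configurable in principle; all bundled backbones end in
a spatial map).  Channel weights are the spatial mean of the gradient of
the chosen class logit — gradients are taken on logits, not softmax
outputs, so maps are not claimed invariant under probability rescaling —
and the ReLU-rectified weighted sum is bilinearly upsampled to the input
size and max-normalised to [0, 1] (identically zero maps stay zero).
Normalisation happens *before* probability modulation, so after
`modulate(map, p_o)` the overlay's intensity ceiling reads directly as
p_o; modulations compose multiplicatively.  `explain_all` emits one map
per decision surface (malignancy, composition, echogenicity, margin, four
foci = 8 maps in both versions), using each head's predicted class and
probability; binary heads use the positive-class probability so an absent
feature gives a blank map, and the v2 echogenicity regression, having no
class probability, uses p_o = 1.  Overlays blend a colormap into the
grayscale frame with the map value as the per-pixel alpha, so a zero map
reproduces the input and a saturated pixel shows the palette's top
colour.

## Synthetic data

The generator emulates the private clinical dataset the pipeline is
designed for: single-nodule grayscale frames with exact labels.
Background tissue is a constant mean (default 0.45) under multiplicative
Rayleigh speckle smoothed with a σ=1.2 px Gaussian — the standard
first-order B-mode approximation.  The nodule is an ellipse whose
boundary radius encodes the margin class (harmonic perturbation for
lobulated/irregular, an added focal bump for extrathyroidal extension, a
Gaussian-blurred rim for ill-defined); echogenicity scales the interior
to 0.10/0.35/0.65/1.45 × background; composition sets the interior
structure (cystic ≈ 4 % of background, mixed split half fluid / half
solid, spongiform densely pocked with small dark microcysts — pocket
count scales with nodule area so the texture survives downscaled
rendering).  Foci are painted after the speckle, as calcifications are
strong specular reflectors: micro dots ≤ 3 px diameter at 512 px scale,
macro discs ≥ 7 px with an acoustic shadow, peripheral rim arcs,
comet-tail dots with a decaying vertical reverberation; separate foci are
rejection-placed with a minimum separation so they stay resolvable, and
micro vs macro differ *only* in rendered diameter.  Pixel spacing is
0.08 mm/px at 512 px and rescales with resolution, giving nodule
diameters of roughly 9–26 mm.

The bundled study profile writes exactly 603 benign + 725 malignant
training and 70 + 79 test cases; benign cases sample from TR1–TR2 feature
combinations (including the benign-typical comet-tail and spongiform
patterns), malignant cases from TR4–TR5 combinations, and the test
verifies both strata against the rule engine.

What the generator does **not** model: acoustic physics (attenuation,
refraction, beam geometry), vendor post-processing, neighbouring anatomy,
multiple nodules, inter-observer label noise, and the correlation
structure of real feature co-occurrence.  Passing the synthetic recovery
checks therefore demonstrates that the pipeline's mechanics — rendering,
preprocessing, optimisation, decision rules, scoring — are correct and
connected, not that the network reaches clinical accuracy on real
ultrasound.

## Problem sizes and numerical choices

The feature-recovery check trains `tiny_resnet` for 5 epochs on 400
balanced composition-contrast images (cystic/anechoic vs. solid, mixed
and spongiform on bright tissue) rendered at 128×128, and requires > 90 %
composition accuracy on 100 held-out images; at these sizes the run takes
about 20 s on one CPU and reaches 100 % across the seeds we exercised.
Probabilities are clipped at 1e-7 inside log losses; simplex sums are
asserted to 1e-6; the Grad-CAM analytic/finite-difference comparison uses
central differences (ε = 1e-5) and tolerates 1e-3 relative error, though
the float64 implementation agrees to ~1e-9.  Argmax ties break to the
lowest class index.  All randomness (weights, shuffling, rendering,
sampling) flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds reproduce images
byte-for-byte and training runs exactly.

## Known limitations

* The full-scale backbones are unoptimised NumPy and are not realistic
  to train; they exist so the configuration surface covers the intended
  architecture family.
* The malignancy head learns whatever separates the benign and malignant
  sampling pools, which in synthetic data is a proxy correlation — no
  clinical claim attaches to it.
* Grad-CAM maps at the tiny backbones' 8×8–32×32 feature resolution are
  coarse; localisation statements about individual microcalcifications
  require finer target layers than global pooling on these backbones
  provides.
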