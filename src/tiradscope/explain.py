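"""Grad-CAM relevance maps per output head, with probability modulation.

For a chosen head and class, the gradient of the class logit with respect
to the last spatial feature map (the backbone output, just before global
average pooling) is averaged over space to give one weight per channel;
the weighted channel sum is ReLU-rectified, bilinearly upsampled to the
input size, and max-normalised to [0,1].  The normalised map is then
multiplied by the head's predicted probability p_o, so that an uncertain
prediction produces a correspondingly faint map — the map maximum never
exceeds p_o.

Gradients are taken on logits (standard Grad-CAM), not on softmax
outputs, so maps are not invariant to per-class probability rescaling;
normalisation happens before modulation so p_o is readable off the
overlay's intensity ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np
from skimage.transform import resize as _sk_resize

from .net import (
    FOCI_ORDER,
    HeadOutputs,
    MultiHeadModel,
    decide_composition,
    decide_margin,
    forward,
    outputs_from_logits,
    V1_COMPOSITION_CLASSES,
    V2_COMPOSITION_COMPONENTS,
    ECHOGENICITY_CODE_ORDER,
    V1_MARGIN_CLASSES,
    V2_MARGIN_CLASSES,
)

__all__ = ["GradCamMap", "gradcam", "modulate", "overlay", "explain_all"]


@dataclass
class GradCamMap:
    """One relevance map: raw (feature resolution) and upsampled (input).

    ``upsampled`` is max-normalised to [0,1] at construction; after
    :func:`modulate` its maximum is bounded by the stored ``p_o``.
    """

    raw: np.ndarray
    upsampled: np.ndarray
    head: str
    class_index: int
    p_o: float = 1.0


def _stack_array(stack) -> np.ndarray:
    from .preprocess import InputStack

    if isinstance(stack, InputStack):
        return stack.planes
    return np.asarray(stack, dtype=np.float64)


def gradcam(
    model: MultiHeadModel, stack, head: str, class_index: int
) -> GradCamMap:
    """Grad-CAM map for one head/class on a single input stack."""
    planes = _stack_array(stack)
    if planes.ndim == 3:
        planes = planes[None]
    feats = model.forward_features(planes)
    model.logits_from_features(feats)  # caches pooled input in the head
    grad = model.feature_gradient(feats, head, class_index)
    weights = grad.mean(axis=(2, 3))                       # (1, C)
    raw = np.maximum(
        (weights[:, :, None, None] * feats).sum(axis=1), 0.0
    )[0]
    up = _sk_resize(
        raw, planes.shape[2:], order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    peak = up.max()
    if peak > 0:
        up = up / peak
    return GradCamMap(raw=raw, upsampled=up, head=head, class_index=class_index)


def modulate(cam: GradCamMap, p_o: float) -> GradCamMap:
    """Scale the normalised map by the class probability p_o.

    Modulations compose multiplicatively:
    ``modulate(modulate(m, a), b) == modulate(m, a * b)``.
    """
    if not 0.0 <= p_o <= 1.0:
        raise ValueError(f"p_o must lie in [0, 1], got {p_o}")
    return replace(
        cam, upsampled=cam.upsampled * p_o, p_o=cam.p_o * p_o
    )


def overlay(
    image: np.ndarray,
    cam_map: np.ndarray,
    palette: str = "jet",
    out_path: Optional[str] = None,
) -> np.ndarray:
    """Alpha-blend a pseudo-colour heatmap onto a grayscale image.

    The blend weight at each pixel is the map value itself: a zero map
    reproduces the grayscale image in RGB, a saturated pixel shows the
    palette's top colour.  Returns a uint8 H x W x 3 array; optionally
    writes it as PNG.
    """
    import matplotlib

    image = np.asarray(image, dtype=np.float64)
    cam_map = np.asarray(cam_map, dtype=np.float64)
    if image.shape != cam_map.shape:
        raise ValueError(
            f"image shape {image.shape} != map shape {cam_map.shape}"
        )
    cmap = matplotlib.colormaps[palette]
    colour = cmap(cam_map)[..., :3]                        # H,W,3 in [0,1]
    gray = np.repeat(image[..., None], 3, axis=-1)
    blended = (1.0 - cam_map[..., None]) * gray + cam_map[..., None] * colour
    rgb = np.clip(np.round(blended * 255.0), 0, 255).astype(np.uint8)
    if out_path is not None:
        import imageio.v3 as iio

        iio.imwrite(out_path, rgb)
    return rgb


def _predicted_class_and_prob(
    out: HeadOutputs, head: str, cfg
) -> Dict[str, object]:
    """Predicted class index, name and probability p_o for one head."""
    if head == "malignancy":
        p = float(out.p_malignant[0])
        # binary head: one logit; p_o is the positive-class probability, so
        # a confidently benign case yields a correspondingly blank map
        return {"index": 0, "name": "malignant" if p > 0.5 else "benign",
                "p_o": p}
    if head == "composition":
        name = decide_composition(out, cfg)[0]
        if cfg.version == "v1":
            idx = V1_COMPOSITION_CLASSES.index(name)
            return {"index": idx, "name": name,
                    "p_o": float(out.composition[0, idx])}
        # v2: the map targets the dominant component; for "mixed" that is
        # the stronger of cystic/solid, with p_o their product.
        probs = out.composition[0]
        if name == "mixed":
            idx = int(np.argmax(probs[:2]))
            p_o = float(probs[0] * probs[1])
        else:
            idx = V2_COMPOSITION_COMPONENTS.index(name)
            p_o = float(probs[idx])
        return {"index": idx, "name": name, "p_o": p_o}
    if head == "echogenicity":
        if cfg.version == "v1":
            idx = int(out.echogenicity.argmax(axis=1)[0])
            return {"index": idx, "name": ECHOGENICITY_CODE_ORDER[idx],
                    "p_o": float(out.echogenicity[0, idx])}
        from .net import decide_echogenicity

        # regression output: no class probability, map left unattenuated
        return {"index": 0,
                "name": decide_echogenicity(float(out.echogenicity[0])),
                "p_o": 1.0}
    if head == "margin":
        classes = V1_MARGIN_CLASSES if cfg.version == "v1" else V2_MARGIN_CLASSES
        name = decide_margin(out)[0]
        idx = classes.index(name)
        return {"index": idx, "name": name, "p_o": float(out.margin[0, idx])}
    raise ValueError(f"unknown head {head!r}")


def explain_all(model: MultiHeadModel, stack) -> Dict[str, GradCamMap]:
    """One modulated Grad-CAM map per decision surface.

    Emits eight maps regardless of head version: malignancy, composition,
    echogenicity, margin, and one per echogenic-focus detector, each for
    the head's predicted class with the predicted probability as p_o.
    Binary heads (malignancy and each focus) use the positive-class
    probability, so an absent feature yields a blank map; the v2
    echogenicity regression has no class probability and uses p_o = 1.
    """
    planes = _stack_array(stack)
    out = forward(planes, model)
    cfg = model.cfg
    maps: Dict[str, GradCamMap] = {}
    for head in ("malignancy", "composition", "echogenicity", "margin"):
        info = _predicted_class_and_prob(out, head, cfg)
        cam = gradcam(model, planes, head, int(info["index"]))
        maps[head] = modulate(cam, float(info["p_o"]))
    for j, focus in enumerate(FOCI_ORDER):
        cam = gradcam(model, planes, "foci", j)
        maps[focus] = modulate(cam, float(out.foci[0, j]))
    return maps
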