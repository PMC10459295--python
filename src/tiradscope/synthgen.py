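"""Seeded synthetic ultrasound-like nodule images with exact ground truth.

Renders grayscale B-mode-like frames containing a single thyroid-nodule
phantom whose TI-RADS features — composition, echogenicity, margin
regularity, aspect ratio (shape), and echogenic foci — are controlled by
the request and therefore known exactly.  The background carries
multiplicative Rayleigh speckle smoothed with a small Gaussian, the
standard first-order approximation of fully developed B-mode speckle.

Feature rendering:

* echogenicity scales the nodule interior relative to the background
  (anechoic almost black ... hyperechoic brighter than background);
* composition controls interior structure: cystic is near-zero (fluid),
  mixed is half fluid / half solid, spongiform is solid tissue pocked
  with many small dark microcysts;
* margins: smooth is a clean ellipse, ill-defined blurs the rim,
  lobulated/irregular perturbs the boundary radius with low-order
  harmonics, extrathyroidal extension adds a focal protrusion;
* foci: punctate microcalcifications are bright dots of diameter <= 3 px
  (at 512 px scale), macrocalcifications are larger discs (>= 7 px) with
  an acoustic shadow below, peripheral calcification is a bright rim
  arc, comet-tail is a dot with a bright vertical reverberation tail.
  Micro and macro are distinguished purely by rendered diameter.

Everything is deterministic per (parameters, seed): the same request
yields byte-identical images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .net import LabelSet
from .preprocess import NoduleImage, InputStack, assemble_input, crop_with_margin

__all__ = [
    "SynthParams",
    "DatasetProfile",
    "STUDY_PROFILE",
    "render_nodule",
    "render_stack",
    "generate_dataset",
    "composition_recovery_sets",
    "BENIGN_POOL",
    "MALIGNANT_POOL",
]

#: reference pixel spacing at 512 px rendering scale (mm per pixel)
BASE_SPACING = 0.08
BASE_SIDE = 512

# interior intensity as a multiple of the background mean
_ECHO_FACTOR = {
    "anechoic": 0.10,
    "very_hypoechoic": 0.35,
    "hypoechoic": 0.65,
    "hyperechoic": 1.45,
}


@dataclass(frozen=True)
class SynthParams:
    """Request for one synthetic nodule image.

    ``nodule_axes_px`` are the (row, col) semi-axes in pixels at the
    requested ``image_side``; if omitted they default to a mid-sized
    nodule consistent with the requested shape class.
    """

    composition: str = "solid"
    echogenicity: str = "hypoechoic"
    margin: str = "smooth"
    shape: str = "wider_than_tall"
    foci: FrozenSet[str] = field(default_factory=frozenset)
    malignant: bool = False
    background_mean: float = 0.45
    speckle_scale: float = 0.8
    image_side: int = 512
    nodule_axes_px: Optional[Tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.background_mean < 1.0:
            raise ValueError("background_mean must lie in (0, 1)")
        if self.speckle_scale <= 0:
            raise ValueError("speckle_scale must be positive")
        object.__setattr__(self, "foci", frozenset(self.foci))

    @property
    def spacing(self) -> Tuple[float, float]:
        s = BASE_SPACING * BASE_SIDE / self.image_side
        return (s, s)


@dataclass(frozen=True)
class DatasetProfile:
    """Per-split benign/malignant case counts."""

    train_benign: int
    train_malignant: int
    test_benign: int
    test_malignant: int


#: the bundled study profile: 1328 training (603 benign + 725 malignant)
#: and 149 test (70 + 79) cases, 673 benign / 804 malignant in total
STUDY_PROFILE = DatasetProfile(603, 725, 70, 79)

# Low-point (TR1-TR2) feature combinations; benign-typical patterns such as
# comet-tail artifacts and spongiform composition appear only here.
BENIGN_POOL: Tuple[dict, ...] = (
    dict(composition="cystic", echogenicity="anechoic", margin="smooth",
         shape="wider_than_tall", foci=frozenset()),
    dict(composition="cystic", echogenicity="anechoic", margin="smooth",
         shape="wider_than_tall", foci=frozenset({"comet_tail"})),
    dict(composition="spongiform", echogenicity="hyperechoic", margin="smooth",
         shape="wider_than_tall", foci=frozenset()),
    dict(composition="spongiform", echogenicity="hyperechoic", margin="smooth",
         shape="wider_than_tall", foci=frozenset({"comet_tail"})),
    dict(composition="mixed", echogenicity="hyperechoic", margin="smooth",
         shape="wider_than_tall", foci=frozenset()),
)

# High-point (TR4-TR5) combinations for the malignant class.
MALIGNANT_POOL: Tuple[dict, ...] = (
    dict(composition="solid", echogenicity="hypoechoic", margin="smooth",
         shape="wider_than_tall", foci=frozenset()),
    dict(composition="solid", echogenicity="hypoechoic", margin="smooth",
         shape="wider_than_tall", foci=frozenset({"macrocalcification"})),
    dict(composition="solid", echogenicity="hypoechoic",
         margin="lobulated_irregular", shape="wider_than_tall",
         foci=frozenset({"punctate_micro"})),
    dict(composition="solid", echogenicity="very_hypoechoic",
         margin="lobulated_irregular", shape="taller_than_wide",
         foci=frozenset({"punctate_micro"})),
    dict(composition="solid", echogenicity="hypoechoic",
         margin="lobulated_irregular", shape="taller_than_wide",
         foci=frozenset()),
    dict(composition="mixed", echogenicity="hypoechoic",
         margin="lobulated_irregular", shape="wider_than_tall",
         foci=frozenset({"punctate_micro"})),
    dict(composition="solid", echogenicity="very_hypoechoic",
         margin="extrathyroidal_extension", shape="taller_than_wide",
         foci=frozenset({"punctate_micro", "macrocalcification"})),
    dict(composition="solid", echogenicity="hypoechoic", margin="smooth",
         shape="wider_than_tall", foci=frozenset({"peripheral_calcification"})),
)


def _scale(params: SynthParams) -> float:
    return params.image_side / BASE_SIDE


def _default_axes(params: SynthParams, rng: np.random.Generator) -> Tuple[float, float]:
    s = _scale(params)
    a = rng.uniform(55, 130) * s
    b = rng.uniform(55, 130) * s
    lo, hi = min(a, b), max(a, b)
    if hi / lo < 1.15:  # keep the shape class unambiguous
        hi = lo * 1.25
    if params.shape == "taller_than_wide":
        return hi, lo
    return lo, hi


def _disc(image: np.ndarray, r: float, c: float, radius: float, value: float) -> None:
    rr, cc = np.ogrid[: image.shape[0], : image.shape[1]]
    image[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] = value


def render_nodule(params: SynthParams) -> Tuple[np.ndarray, np.ndarray, LabelSet]:
    """Render one (image, mask, label) triple, deterministic per seed."""
    side = params.image_side
    rng = np.random.default_rng(params.seed)
    axes = params.nodule_axes_px or _default_axes(params, rng)
    ar, ac = axes
    if params.shape == "taller_than_wide" and not ar > ac:
        ar, ac = max(axes), min(axes)
    if params.shape == "wider_than_tall" and not ac >= ar:
        ar, ac = min(axes), max(axes)
    if 2 * ar >= side or 2 * ac >= side:
        raise ValueError(f"nodule axes {axes} do not fit in a {side}px image")

    jitter = 0.04 * side
    cr = side / 2 + rng.uniform(-jitter, jitter)
    cc_ = side / 2 + rng.uniform(-jitter, jitter)

    rows, cols = np.mgrid[0:side, 0:side]
    dy = (rows - cr) / ar
    dx = (cols - cc_) / ac
    rad = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    # boundary radius as a function of angle encodes the margin class
    boundary = np.ones_like(theta)
    if params.margin in ("lobulated_irregular", "extrathyroidal_extension"):
        for k in (3, 4, 5, 6):
            amp = rng.uniform(0.03, 0.07)
            boundary += amp * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    if params.margin == "extrathyroidal_extension":
        theta0 = rng.uniform(-np.pi, np.pi)
        dtheta = np.angle(np.exp(1j * (theta - theta0)))
        boundary += 0.38 * np.exp(-((dtheta / 0.30) ** 2))
    mask = rad <= boundary

    bg = params.background_mean
    interior = _ECHO_FACTOR[params.echogenicity] * bg
    structure = np.full((side, side), bg)
    if params.composition == "cystic":
        structure[mask] = 0.04 * bg
    elif params.composition == "mixed":
        fluid = mask & (cols < cc_)
        structure[mask] = interior
        structure[fluid] = 0.04 * bg
    elif params.composition == "spongiform":
        structure[mask] = interior
        inner = np.argwhere(rad <= 0.85 * boundary)
        # pocket count scales with nodule area so the microcystic texture
        # stays visible at any rendering resolution
        n_pockets = max(25, len(inner) // 50)
        pocket_r = max(2.2, 3.0 * _scale(params))
        for idx in rng.choice(len(inner), size=min(n_pockets, len(inner)),
                              replace=False):
            r0, c0 = inner[idx]
            _disc(structure, r0, c0, pocket_r * rng.uniform(0.8, 1.3), 0.10 * bg)
    else:  # solid
        structure[mask] = interior

    if params.margin == "ill_defined":
        structure = ndimage.gaussian_filter(structure, sigma=3.5 * _scale(params) + 1.0)

    # multiplicative Rayleigh speckle, lightly smoothed
    field_ = rng.rayleigh(scale=1.0, size=(side, side))
    field_ = ndimage.gaussian_filter(field_, sigma=1.2)
    field_ /= field_.mean()
    image = structure * (1.0 + params.speckle_scale * (field_ - 1.0))

    # calcifications and artifacts are strong specular reflectors: painted
    # after the speckle so their intensity is exact
    s = _scale(params)
    inner_pts = np.argwhere(rad <= 0.7 * boundary)
    placed: List[Tuple[int, int]] = []

    def _pick(min_sep: float = 0.0) -> Tuple[int, int]:
        # rejection-sample so separate foci stay separate in the render
        for _ in range(50):
            r0, c0 = inner_pts[rng.integers(len(inner_pts))]
            if all(np.hypot(r0 - r1, c0 - c1) >= min_sep for r1, c1 in placed):
                break
        placed.append((int(r0), int(c0)))
        return int(r0), int(c0)

    if "punctate_micro" in params.foci:
        for _ in range(int(rng.integers(2, 5))):
            r0, c0 = _pick(min_sep=10.0 * s + 4.0)
            _disc(image, r0, c0, max(1.0, 1.4 * s), 0.98)
    if "macrocalcification" in params.foci:
        for _ in range(int(rng.integers(1, 3))):
            r0, c0 = _pick(min_sep=12.0 * s + 4.0)
            radius = max(2.5, 4.5 * s)
            _disc(image, r0, c0, radius, 0.95)
            shade = slice(int(r0 + radius), min(side, int(r0 + radius + 40 * s)))
            image[shade, max(0, int(c0 - radius)):int(c0 + radius)] *= 0.35
    if "peripheral_calcification" in params.foci:
        theta0 = rng.uniform(-np.pi, np.pi)
        dtheta = np.abs(np.angle(np.exp(1j * (theta - theta0))))
        rim = (rad >= 0.90 * boundary) & (rad <= 1.02 * boundary) & (dtheta < 1.1)
        image[rim] = 0.92
    if "comet_tail" in params.foci:
        r0, c0 = _pick()
        _disc(image, r0, c0, max(1.0, 1.6 * s), 0.97)
        tail_len = int(14 * s) + 4
        for t in range(tail_len):
            rr_ = int(r0 + 2 + t)
            if rr_ >= side:
                break
            image[rr_, max(0, c0 - 1):c0 + 2] = 0.97 * (1.0 - 0.6 * t / tail_len)

    image = np.clip(image, 0.0, 1.0)
    label = LabelSet(
        malignant=params.malignant,
        composition=params.composition,
        echogenicity=params.echogenicity,
        margin=params.margin,
        foci=params.foci,
    )
    return image, mask, label


def render_stack(
    params: SynthParams, out_side: Optional[int] = None
) -> Tuple[InputStack, LabelSet, NoduleImage]:
    """Render, crop with the standard 5% margin, and assemble the 3-plane input."""
    image, mask, label = render_nodule(params)
    nod = NoduleImage(image, mask, params.spacing)
    cropped = crop_with_margin(nod, out_side=out_side or params.image_side)
    return assemble_input(cropped), label, cropped


def _sample_params(
    pool: Sequence[dict], malignant: bool, rng: np.random.Generator,
    image_side: int, background_mean: float, speckle_scale: float,
) -> SynthParams:
    combo = pool[rng.integers(len(pool))]
    return SynthParams(
        malignant=malignant,
        image_side=image_side,
        background_mean=background_mean,
        speckle_scale=speckle_scale,
        seed=int(rng.integers(0, 2**31 - 1)),
        **combo,
    )


def generate_dataset(
    profile: DatasetProfile,
    seed: int,
    out_dir: str,
    image_side: int = 512,
    background_mean: float = 0.45,
    speckle_scale: float = 0.8,
) -> pd.DataFrame:
    """Write an image/mask/manifest dataset matching the profile exactly.

    Benign cases are sampled from low-point (TR1-TR2) feature
    combinations, malignant cases from high-point (TR4-TR5) ones.  Files
    land under ``out_dir/<split>/`` as 8-bit PNGs; the manifest CSV
    records paths, pixel spacing, the full label set, malignancy and
    split, and is returned as a DataFrame.
    """
    import imageio.v3 as iio

    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    rows: List[dict] = []
    plan = [
        ("train", False, profile.train_benign),
        ("train", True, profile.train_malignant),
        ("test", False, profile.test_benign),
        ("test", True, profile.test_malignant),
    ]
    for split, malignant, count in plan:
        split_dir = os.path.join(out_dir, split)
        os.makedirs(split_dir, exist_ok=True)
        pool = MALIGNANT_POOL if malignant else BENIGN_POOL
        for i in range(count):
            params = _sample_params(
                pool, malignant, rng, image_side, background_mean, speckle_scale
            )
            image, mask, label = render_nodule(params)
            stem = f"{split}_{'mal' if malignant else 'ben'}_{i:04d}"
            img_path = os.path.join(split_dir, stem + ".png")
            mask_path = os.path.join(split_dir, stem + "_mask.png")
            iio.imwrite(img_path, np.round(image * 255).astype(np.uint8))
            iio.imwrite(mask_path, (mask * 255).astype(np.uint8))
            sr, sc = params.spacing
            rows.append({
                "image_path": img_path,
                "mask_path": mask_path,
                "spacing_row_mm": sr,
                "spacing_col_mm": sc,
                "composition": label.composition,
                "echogenicity": label.echogenicity,
                "margin": label.margin,
                "shape": params.shape,
                "comet_tail": int("comet_tail" in label.foci),
                "punctate_micro": int("punctate_micro" in label.foci),
                "macrocalcification": int("macrocalcification" in label.foci),
                "peripheral_calcification": int(
                    "peripheral_calcification" in label.foci),
                "malignant": int(label.malignant),
                "split": split,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def composition_recovery_sets(
    n_train: int = 400,
    n_test: int = 100,
    seed: int = 0,
    image_side: int = 128,
) -> Tuple[Tuple[np.ndarray, List[LabelSet]], Tuple[np.ndarray, List[LabelSet]]]:
    """Balanced composition-contrast sets for the feature-recovery check.

    The four composition classes are rendered at maximal mutual contrast
    (cystic/anechoic vs. solid, mixed and spongiform on bright tissue),
    with smooth margins and no foci, then preprocessed into input stacks.
    Returns ``(train, test)`` where each is ``(stacks, labels)``.
    """
    recipes = {
        "cystic": dict(composition="cystic", echogenicity="anechoic"),
        "solid": dict(composition="solid", echogenicity="hyperechoic"),
        "mixed": dict(composition="mixed", echogenicity="hyperechoic"),
        "spongiform": dict(composition="spongiform", echogenicity="hyperechoic"),
    }
    comps = list(recipes)
    rng = np.random.default_rng(seed)

    def make(n: int) -> Tuple[np.ndarray, List[LabelSet]]:
        if n == 0:
            return np.zeros((0, 3, image_side, image_side)), []
        stacks, labels = [], []
        for i in range(n):
            comp = comps[i % 4]
            params = SynthParams(
                margin="smooth",
                shape="wider_than_tall",
                image_side=image_side,
                seed=int(rng.integers(0, 2**31 - 1)),
                **recipes[comp],
            )
            stack, label, _ = render_stack(params, out_side=image_side)
            stacks.append(stack.planes)
            labels.append(label)
        return np.stack(stacks), labels

    return make(n_train), make(n_test)
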