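"""Ultrasound frame + nodule mask -> network input and shape measurements.

A raw grayscale frame with a binary segmentation mask is cropped to the
nodule's bounding box with a 5% per-side margin, resized to a square
(512x512 by default), and assembled into a three-plane stack: the raw
image, a max-pool sharpened copy (to accentuate bright punctate reflectors
such as microcalcifications), and the binary mask.  Shape and size are
measured directly from the mask in physical units, so they never pass
through the network.

Conventions: 0-based row-major coordinates, half-open boxes, bilinear
interpolation for intensity planes and nearest-neighbour for masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "NoduleImage",
    "InputStack",
    "crop_with_margin",
    "sharpen",
    "assemble_input",
    "measure_shape",
    "load_nodule_image",
]


@dataclass
class NoduleImage:
    """A grayscale frame in [0,1], its binary nodule mask, and pixel spacing.

    ``spacing_mm_per_px`` is (row, col) in millimetres per pixel and may be
    anisotropic.
    """

    pixels: np.ndarray
    mask: np.ndarray
    spacing_mm_per_px: Tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if self.pixels.shape != self.mask.shape:
            raise ValueError(
                f"pixels shape {self.pixels.shape} != mask shape {self.mask.shape}"
            )
        if not self.mask.any():
            raise ValueError("mask has no foreground pixels")
        sr, sc = self.spacing_mm_per_px
        if not (sr > 0 and sc > 0):
            raise ValueError("pixel spacing must be positive")


@dataclass
class InputStack:
    """3 x H x W network input: (raw, sharpened, mask) planes."""

    planes: np.ndarray

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float64)
        if self.planes.ndim != 3 or self.planes.shape[0] != 3:
            raise ValueError(f"expected 3 x H x W planes, got {self.planes.shape}")


def _mask_bbox(mask: np.ndarray) -> Tuple[int, int, int, int]:
    """Tight half-open bounding box (r0, r1, c0, c1) of the foreground."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def crop_with_margin(
    img: NoduleImage, margin_frac: float = 0.05, out_side: int = 512
) -> NoduleImage:
    """Crop to the mask bounding box + margin and resize to a square.

    The tight box is expanded on each side by ``margin_frac`` times the box
    extent along that axis (rounded to whole pixels, clipped to the frame),
    then the crop is resized to ``out_side`` x ``out_side``.  Pixel spacing
    is rescaled so physical extents are preserved per axis.
    """
    if margin_frac < 0:
        raise ValueError("margin_frac must be >= 0")
    r0, r1, c0, c1 = _mask_bbox(img.mask)
    mr = int(round(margin_frac * (r1 - r0)))
    mc = int(round(margin_frac * (c1 - c0)))
    r0, r1 = max(0, r0 - mr), min(img.mask.shape[0], r1 + mr)
    c0, c1 = max(0, c0 - mc), min(img.mask.shape[1], c1 + mc)
    pix = img.pixels[r0:r1, c0:c1]
    msk = img.mask[r0:r1, c0:c1]
    out_pix = _sk_resize(pix, (out_side, out_side), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    out_msk = _sk_resize(msk.astype(np.float64), (out_side, out_side), order=0,
                         mode="edge", anti_aliasing=False, preserve_range=True) > 0.5
    sr, sc = img.spacing_mm_per_px
    new_spacing = (sr * (r1 - r0) / out_side, sc * (c1 - c0) / out_side)
    return NoduleImage(np.clip(out_pix, 0.0, 1.0), out_msk, new_spacing)


def crop_box(img: NoduleImage, margin_frac: float = 0.05) -> Tuple[int, int, int, int]:
    """The half-open (r0, r1, c0, c1) crop window before resizing."""
    r0, r1, c0, c1 = _mask_bbox(img.mask)
    mr = int(round(margin_frac * (r1 - r0)))
    mc = int(round(margin_frac * (c1 - c0)))
    return (
        max(0, r0 - mr),
        min(img.mask.shape[0], r1 + mr),
        max(0, c0 - mc),
        min(img.mask.shape[1], c1 + mc),
    )


def sharpen(pixels: np.ndarray) -> np.ndarray:
    """3x3 max-pool with stride 1 (grayscale dilation, flat 3x3 element).

    Edge handling replicates the border pixel, so the output dominates the
    input pointwise everywhere, including at the frame edge.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("sharpen expects a 2-D array")
    return ndimage.maximum_filter(pixels, size=3, mode="nearest")


def assemble_input(img: NoduleImage) -> InputStack:
    """Stack (raw, sharpened raw, mask) into the 3-plane network input."""
    planes = np.stack(
        [img.pixels, sharpen(img.pixels), img.mask.astype(np.float64)], axis=0
    )
    return InputStack(planes)


def measure_shape(img: NoduleImage) -> Tuple[bool, float]:
    """(taller_than_wide, max_diameter_mm) from the mask and pixel spacing.

    Measured on the mask bounding box in physical mm, so the result is
    independent of image intensities and, because spacing is rescaled by
    :func:`crop_with_margin`, of the resize step.  Exact squares are not
    "taller"; the comparison is strict.
    """
    r0, r1, c0, c1 = _mask_bbox(img.mask)
    sr, sc = img.spacing_mm_per_px
    height_mm = (r1 - r0) * sr
    width_mm = (c1 - c0) * sc
    return height_mm > width_mm, float(max(height_mm, width_mm))


def load_nodule_image(
    image_path: str, mask_path: str, spacing_mm_per_px: Tuple[float, float]
) -> NoduleImage:
    """Read a PNG/TIFF frame and PNG mask from disk into a NoduleImage.

    8- or 16-bit integer images are rescaled to [0,1] by their dtype range;
    float images are assumed to already be in [0,1].
    """
    import imageio.v3 as iio

    pix = np.asarray(iio.imread(image_path))
    if pix.ndim == 3:  # collapse RGB(A) to luminance
        pix = pix[..., :3].mean(axis=-1)
    if np.issubdtype(pix.dtype, np.integer):
        pix = pix.astype(np.float64) / np.iinfo(pix.dtype).max
    msk = np.asarray(iio.imread(mask_path))
    if msk.ndim == 3:
        msk = msk[..., 0]
    return NoduleImage(np.clip(pix, 0.0, 1.0), msk > 0, spacing_mm_per_px)
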