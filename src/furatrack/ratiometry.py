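"""Ratio-image computation, masking, and pseudocolor rendering.

The ratio image is the pixel-by-pixel quotient of the 340-nm image over
the 380-nm image; because Fura-2's excitation optimum shifts from
~380 nm (Ca2+-free) to ~340 nm (Ca2+-bound), the ratio rises
monotonically with intracellular free Ca2+ and is invariant to common
multiplicative factors (illumination, dye load, bleaching that affects
both channels equally).

Pixels where the 380-nm denominator falls below a floor, or that lie
outside the embryo mask, are flagged invalid rather than producing
unstable quotients.
"""
from __future__ import annotations

from importlib import resources
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DegenerateInputError, ShapeError, ValidationError
from .stacks import ImagePairStack, Mask, RatioStack

#: default denominator floor: this fraction of the 99th percentile of F380
DEFAULT_EPS_FRACTION = 0.01


def _load_lut() -> np.ndarray:
    with resources.files("furatrack.data").joinpath("pseudocolor_lut.csv").open() as fh:
        lut = np.loadtxt(fh, delimiter=",", skiprows=1, dtype=np.uint8)
    if lut.shape != (256, 3):
        raise ValidationError(f"pseudocolor LUT must be 256x3; got {lut.shape}")
    return lut


_LUT: Optional[np.ndarray] = None


def pseudocolor_lut() -> np.ndarray:
    """The fixed 256x3 blue->green->yellow->red lookup table (uint8)."""
    global _LUT
    if _LUT is None:
        _LUT = _load_lut()
    return _LUT


def compute_embryo_mask(
    stack: ImagePairStack,
    quantile_q: float = 0.1,
    min_fill: float = 0.05,
) -> Mask:
    """Segment the embryo from dark background on the time-mean 380-nm image.

    A pixel belongs to the embryo when its time-mean F380 is positive and
    at least the ``quantile_q`` quantile of the time-mean image; holes are
    filled.  The positivity guard makes the rule well behaved when the
    background is exactly zero (the quantile itself may then be zero).
    Raises :class:`DegenerateInputError` when coverage falls below
    ``min_fill`` (likely an empty field of view).
    """
    if not (0 < quantile_q < 1):
        raise ValidationError(f"quantile_q must be in (0, 1); got {quantile_q}")
    mean380 = np.asarray(stack.f380, dtype=np.float64).mean(axis=0)
    threshold = np.quantile(mean380, quantile_q)
    pixels = (mean380 >= threshold) & (mean380 > 0)
    pixels = ndimage.binary_fill_holes(pixels)
    if pixels.sum() < min_fill * pixels.size:
        raise DegenerateInputError(
            f"embryo mask covers {pixels.sum()}/{pixels.size} pixels, below "
            f"min_fill={min_fill} (empty field of view?)"
        )
    return Mask(pixels=pixels, kind="embryo")


def compute_ratio(
    stack: ImagePairStack,
    mask: Optional[Mask] = None,
    eps: Optional[float] = None,
) -> RatioStack:
    """Compute the masked per-frame F340/F380 ratio stack.

    ``eps`` is the denominator floor; by default it is 1% of the 99th
    percentile of F380, a relative rule robust to bit depth.  A pixel is
    valid in a frame when it is inside the mask, F380 >= eps and
    F340 > 0; invalid entries are stored as 0.
    """
    f340 = np.asarray(stack.f340, dtype=np.float64)
    f380 = np.asarray(stack.f380, dtype=np.float64)
    if eps is None:
        eps = DEFAULT_EPS_FRACTION * np.percentile(f380, 99)
    if not (eps > 0):
        raise ValidationError(f"eps must be > 0; got {eps}")
    if mask is None:
        mask_px = np.ones(stack.frame_shape, dtype=bool)
    else:
        if mask.pixels.shape != stack.frame_shape:
            raise ShapeError(
                f"mask shape {mask.pixels.shape} != frame shape {stack.frame_shape}"
            )
        mask_px = mask.pixels
    valid = mask_px[None, :, :] & (f380 >= eps) & (f340 > 0)
    ratio = np.zeros_like(f340)
    np.divide(f340, f380, out=ratio, where=valid)
    ratio[~valid] = 0.0
    return RatioStack(ratio=ratio, valid=valid, dt_s=stack.dt_s, t0_s=stack.t0_s)


def display_range(ratios: RatioStack, lo_pct: float = 1.0, hi_pct: float = 99.0) -> tuple[float, float]:
    """Session display range: percentiles of the valid ratio values."""
    vals = ratios.ratio[ratios.valid]
    if vals.size == 0:
        raise DegenerateInputError("no valid ratio pixels in session")
    lo, hi = np.percentile(vals, [lo_pct, hi_pct])
    if lo >= hi:
        lo, hi = float(vals.min()), float(vals.max() + 1e-9)
    return float(lo), float(hi)


def encode_pseudocolor(
    ratio_frame: np.ndarray,
    valid: np.ndarray,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Map one ratio frame to an 8-bit pseudocolor image.

    The ratio is clamped to [lo, hi], scaled to s in [0, 1] and encoded
    as level floor(255 s) (s = 1 maps to 255), then sent through the
    fixed blue->green->yellow->red lookup table: low ratio (low Ca2+)
    renders blue, high ratio (high Ca2+) renders yellow/red.  Invalid
    pixels render black.
    """
    if not (lo < hi):
        raise ValidationError(f"need lo < hi; got lo={lo}, hi={hi}")
    ratio_frame = np.asarray(ratio_frame, dtype=np.float64)
    valid = np.asarray(valid, dtype=bool)
    if ratio_frame.shape != valid.shape or ratio_frame.ndim != 2:
        raise ShapeError("ratio_frame and valid must be matching 2-D images")
    s = np.clip((ratio_frame - lo) / (hi - lo), 0.0, 1.0)
    levels = np.minimum(np.floor(255.0 * s), 255).astype(np.uint8)
    rgb = pseudocolor_lut()[levels]
    rgb[~valid] = 0
    return rgb


def roi_from_reference(reference: np.ndarray, frac_of_max: float = 0.5) -> Mask:
    """Segment the lineage-tracer ROI from the 540-nm reference image.

    Pixels at or above ``frac_of_max`` of the image maximum are kept and
    reduced to the largest 8-connected component — the injected-cell
    (TxR-positive) region.
    """
    if not (0 < frac_of_max < 1):
        raise ValidationError(f"frac_of_max must be in (0, 1); got {frac_of_max}")
    reference = np.asarray(reference, dtype=np.float64)
    if reference.ndim != 2:
        raise ShapeError("reference must be a single 2-D image")
    peak = reference.max()
    if peak <= 0:
        raise DegenerateInputError("reference image has no positive signal")
    candidate = reference >= frac_of_max * peak
    labels = measure.label(candidate, connectivity=2)
    if labels.max() == 0:
        raise DegenerateInputError("no suprathreshold region in reference image")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return Mask(pixels=labels == sizes.argmax(), kind="roi")
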