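"""Session-level composite activity maps and ROI contrasts.

The composite map accumulates, per pixel, how many transient events
covered that pixel over a session — the topographic "peaks" view of
where Ca2+ release happened.  The ROI contrast compares event rates and
mean ratio levels inside versus outside a region of interest (the
lineage-tracer-positive region in a localized-suppression assay).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, ShapeError, ValidationError
from .events import EventTable
from .ratiometry import pseudocolor_lut
from .stacks import Mask, RatioStack


@dataclass
class CompositeMap:
    """Per-pixel count of transient events covering each pixel.

    Each event increments each pixel of its union footprint exactly
    once, so ``counts.sum()`` equals the summed footprint sizes and
    ``counts.max() <= n_events``.
    """

    counts: np.ndarray
    n_events: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ShapeError("counts must be 2-D")
        if self.counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_events < 0 or (self.counts.size and self.counts.max() > self.n_events):
            raise ValidationError("max(counts) cannot exceed n_events")


@dataclass
class RoiContrast:
    """Event rates and mean ratios inside vs outside an ROI.

    ``suppression`` is rate_in / rate_out, or None when no events fell
    outside the ROI (undefined).
    """

    rate_in: float
    rate_out: float
    mean_ratio_in: float
    mean_ratio_out: float
    suppression: Optional[float]
    n_in: int
    n_out: int


def accumulate_composite(
    table: EventTable,
    shape: tuple[int, int],
    include_sustained: bool = False,
) -> CompositeMap:
    """Accumulate event footprints into a composite count map.

    By default only ``transient``-labelled events are counted (the unit
    of the frequency analysis); ``include_sustained`` adds the rest.
    Events must carry footprint data (fresh from the detector, not a
    round-tripped CSV).
    """
    h, w = shape
    counts = np.zeros((h, w), dtype=np.int64)
    selected = table.events if include_sustained else table.transients
    for event in selected:
        fp = event.union_footprint()
        if fp.size and fp.max() >= h * w:
            raise ValidationError(
                f"event {event.id} footprint exceeds shape {shape}"
            )
        counts.ravel()[fp] += 1
    return CompositeMap(counts=counts, n_events=len(selected))


def render_composite(cmap: CompositeMap) -> np.ndarray:
    """Pseudocolor render of a composite map (low count purple/blue,
    high count yellow/red), matching the published color convention."""
    peak = max(int(cmap.counts.max()), 1)
    levels = np.minimum(np.floor(255.0 * cmap.counts / peak), 255).astype(np.uint8)
    return pseudocolor_lut()[levels]


def roi_contrast(
    table: EventTable,
    ratios: RatioStack,
    roi: Mask,
    session_hours: float,
) -> RoiContrast:
    """Contrast transient activity inside vs outside an ROI.

    Events are assigned by centroid membership (rounded to the nearest
    pixel); rates are events per hour; ratio means are taken over valid
    pixels in each region across all frames.  The two rates partition
    the total exactly: rate_in*hours + rate_out*hours = transient count.
    """
    if not (session_hours > 0):
        raise ValidationError(f"session_hours must be > 0; got {session_hours}")
    if roi.pixels.shape != ratios.frame_shape:
        raise ShapeError(
            f"roi shape {roi.pixels.shape} != frame shape {ratios.frame_shape}"
        )
    if not roi.pixels.any():
        raise DegenerateInputError("ROI is empty")

    h, w = ratios.frame_shape
    n_in = n_out = 0
    for event in table.transients:
        r = min(max(int(round(event.centroid[0])), 0), h - 1)
        c = min(max(int(round(event.centroid[1])), 0), w - 1)
        if roi.pixels[r, c]:
            n_in += 1
        else:
            n_out += 1

    region_in = ratios.valid & roi.pixels[None, :, :]
    region_out = ratios.valid & ~roi.pixels[None, :, :]
    mean_in = float(ratios.ratio[region_in].mean()) if region_in.any() else float("nan")
    mean_out = float(ratios.ratio[region_out].mean()) if region_out.any() else float("nan")

    rate_in = n_in / session_hours
    rate_out = n_out / session_hours
    return RoiContrast(
        rate_in=rate_in,
        rate_out=rate_out,
        mean_ratio_in=mean_in,
        mean_ratio_out=mean_out,
        suppression=(rate_in / rate_out) if rate_out > 0 else None,
        n_in=n_in,
        n_out=n_out,
    )
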