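"""Core in-memory containers for dual-wavelength Fura-2 acquisitions.

An acquisition session is a pair of aligned fluorescence stacks: the
340-nm excitation image reports the Ca2+-bound indicator, the 380-nm
image the Ca2+-free form.  All downstream analysis operates on the
pixel-wise 340/380 ratio, which increases monotonically with
intracellular free Ca2+.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ShapeError, ValidationError


@dataclass
class ImagePairStack:
    """Aligned 340-nm and 380-nm intensity stacks plus acquisition metadata.

    Parameters
    ----------
    f340, f380
        Intensity stacks of shape ``(frames, height, width)``, arbitrary
        fluorescence units, non-negative.  Shapes must match and there
        must be at least two frames (a single frame supports no temporal
        analysis).
    dt_s
        Inter-frame interval in seconds (the acquisitions this pipeline
        models used 15 s).
    t0_s
        Acquisition start time in seconds.
    reference_540
        Optional single image of the Texas Red lineage-tracer channel
        (540-nm excitation), used to derive the injected-cell ROI.
    meta
        Free-form string metadata (stage annotations, embryo id, ...).
    """

    f340: np.ndarray
    f380: np.ndarray
    dt_s: float
    t0_s: float = 0.0
    reference_540: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.f340 = np.asarray(self.f340)
        self.f380 = np.asarray(self.f380)
        if self.f340.ndim != 3 or self.f380.ndim != 3:
            raise ShapeError(
                f"stacks must be 3-D (frames, height, width); got "
                f"f340 ndim={self.f340.ndim}, f380 ndim={self.f380.ndim}"
            )
        if self.f340.shape != self.f380.shape:
            raise ShapeError(
                f"f340 shape {self.f340.shape} != f380 shape {self.f380.shape}"
            )
        if self.f340.shape[0] < 2:
            raise ValidationError(
                f"need >=2 frames for temporal analysis; got {self.f340.shape[0]}"
            )
        if not (self.dt_s > 0):
            raise ValidationError(f"dt_s must be > 0; got {self.dt_s}")
        for name, arr in (("f340", self.f340), ("f380", self.f380)):
            a = np.asarray(arr, dtype=np.float64)
            if not np.all(np.isfinite(a)):
                raise ValidationError(f"{name} contains non-finite values")
            if a.min() < 0:
                raise ValidationError(f"{name} contains negative intensities")
        if self.reference_540 is not None:
            ref = np.asarray(self.reference_540)
            if ref.shape != self.f340.shape[1:]:
                raise ShapeError(
                    f"reference_540 shape {ref.shape} does not match frame "
                    f"shape {self.f340.shape[1:]}"
                )
            self.reference_540 = ref

    @property
    def n_frames(self) -> int:
        return self.f340.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.f340.shape[1:]

    def frame_time_s(self, index: int) -> float:
        """Acquisition time of frame ``index`` (0-based) in seconds."""
        return self.t0_s + index * self.dt_s

    @property
    def duration_hours(self) -> float:
        """Session length in hours, counting the full frame grid span."""
        return self.n_frames * self.dt_s / 3600.0


@dataclass
class RatioStack:
    """Per-frame pixel-wise 340/380 ratio with a validity mask.

    ``ratio`` is finite and strictly positive wherever ``valid`` is
    true; invalid entries (denominator under the floor, outside the
    embryo mask) are stored as 0 and must never be interpreted.
    """

    ratio: np.ndarray
    valid: np.ndarray
    dt_s: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.ratio.ndim != 3:
            raise ShapeError("ratio must be 3-D (frames, height, width)")
        if self.ratio.shape != self.valid.shape:
            raise ShapeError(
                f"ratio shape {self.ratio.shape} != valid shape {self.valid.shape}"
            )
        if not (self.dt_s > 0):
            raise ValidationError(f"dt_s must be > 0; got {self.dt_s}")
        sel = self.ratio[self.valid]
        if sel.size and (not np.all(np.isfinite(sel)) or sel.min() <= 0):
            raise ValidationError("ratio must be finite and > 0 on the valid region")

    @property
    def n_frames(self) -> int:
        return self.ratio.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.ratio.shape[1:]


@dataclass
class Mask:
    """A boolean image labelling either the embryo or an ROI."""

    pixels: np.ndarray
    kind: str = "embryo"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ShapeError("mask must be 2-D (height, width)")
        if self.kind not in ("embryo", "roi"):
            raise ValidationError(f"mask kind must be 'embryo' or 'roi'; got {self.kind!r}")

    @property
    def n_true(self) -> int:
        return int(self.pixels.sum())
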