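"""Transient events and the tabular carrier used to persist them.

A :class:`TransientEvent` is a localized, time-limited increase in the
340/380 ratio.  Events whose elevation persists no longer than the
transient bound (default 30 s, i.e. two frames at 15-s sampling) are
labelled ``transient``; longer elevations are ``sustained``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

LABEL_TRANSIENT = "transient"
LABEL_SUSTAINED = "sustained"


@dataclass
class TransientEvent:
    """One detected Ca2+ release event.

    ``onset_frame``/``offset_frame`` are inclusive 0-based frame indices;
    an onset needs a predecessor frame so ``onset_frame >= 1``.
    ``centroid`` is the (row, col) centroid of the footprint at the peak
    frame, in 0-based pixel units.  ``area_px`` is the maximum per-frame
    footprint size over the event, ``peak_delta_ratio`` the maximum
    elevation of the ratio above the per-pixel pre-onset baseline.

    ``footprints`` (optional, not serialized) maps frame index to the
    flat pixel indices active in that frame; it feeds the composite map.
    """

    id: int
    onset_frame: int
    offset_frame: int
    duration_s: float
    centroid: tuple[float, float]
    area_px: int
    peak_delta_ratio: float
    label: str
    footprints: Optional[dict[int, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.onset_frame < 1:
            raise ValidationError("onset_frame must be >= 1 (a difference needs a predecessor)")
        if self.offset_frame < self.onset_frame:
            raise ValidationError("offset_frame must be >= onset_frame")
        if self.area_px < 1:
            raise ValidationError("area_px must be >= 1")
        if not (self.peak_delta_ratio > 0):
            raise ValidationError("peak_delta_ratio must be > 0")
        if self.label not in (LABEL_TRANSIENT, LABEL_SUSTAINED):
            raise ValidationError(f"unknown label {self.label!r}")

    @property
    def is_transient(self) -> bool:
        return self.label == LABEL_TRANSIENT

    def union_footprint(self) -> np.ndarray:
        """Flat pixel indices covered by the event in any frame."""
        if self.footprints is None:
            raise ValidationError(f"event {self.id} carries no footprint data")
        if not self.footprints:
            return np.empty(0, dtype=np.intp)
        return np.unique(np.concatenate(list(self.footprints.values())))


@dataclass
class EventTable:
    """Ordered collection of events plus the session metadata needed to
    timestamp them (dt_s, t0_s, stack geometry)."""

    events: list[TransientEvent]
    dt_s: float
    n_frames: int
    height: int
    width: int
    t0_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.dt_s > 0):
            raise ValidationError(f"dt_s must be > 0; got {self.dt_s}")
        ids = [e.id for e in self.events]
        if len(set(ids)) != len(ids):
            raise ValidationError("event ids must be unique")
        onsets = [e.onset_frame for e in self.events]
        if onsets != sorted(onsets):
            raise ValidationError("events must be sorted by onset frame")
        for e in self.events:
            if e.offset_frame >= self.n_frames:
                raise ValidationError(
                    f"event {e.id} offset frame {e.offset_frame} outside stack "
                    f"of {self.n_frames} frames"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def transients(self) -> list[TransientEvent]:
        return [e for e in self.events if e.is_transient]

    def onset_times_s(self) -> np.ndarray:
        """Onset time of every event in seconds (t0 + frame * dt)."""
        return np.array([self.t0_s + e.onset_frame * self.dt_s for e in self.events])
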