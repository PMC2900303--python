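"""Subtractive detection of localized Ca2+ release events.

Sequential ratio images are differenced; pixels whose frame-to-frame
increase exceeds a robust noise threshold seed detections, detections
are grouped into 8-connected components per frame, linked through time
by footprint overlap, and each linked event is then kept alive while
its pixels remain elevated above their pre-onset baseline — so event
duration measures how long Ca2+ stays up, not only how fast it rose.
Events are labelled ``transient`` when their elevation persists no
longer than ``d_max_s`` (default 30 s, an inclusive 2-frame bound at
15-s sampling) and ``sustained`` otherwise.

Only positive-going deflections are considered: the analysis counts
Ca2+ release, not clearance.  Footprint size is recorded (``area_px``)
but never disqualifies an event — enlarged release domains are a real
phenotype and must stay countable; an optional ``max_area_px`` exists
for sensitivity analyses.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import measure

from .errors import ValidationError
from .events import LABEL_SUSTAINED, LABEL_TRANSIENT, EventTable, TransientEvent
from .stacks import RatioStack


@dataclass
class DetectionParams:
    """Tunables of the subtractive detector.

    k_sigma
        Threshold multiplier in robust SDs of the pooled frame-difference
        noise (MAD-based).
    min_area_px
        Minimum 8-connected footprint, in pixels, for a detection.
    max_gap_frames
        Dropout frames tolerated inside one event before it is closed.
    d_max_s
        Maximum persistence, in seconds, for the ``transient`` label
        (inclusive bound: exactly d_max_s is still transient).
    link_min_overlap
        Minimum footprint overlap, as a fraction of the smaller
        footprint, to link detections in consecutive frames.
    max_area_px
        Optional footprint cap for sensitivity analyses; None (default)
        never excludes an event by size.
    noise_mode
        ``"pooled"`` (default): one robust SD of the frame-difference
        noise pooled over all valid pixels.  ``"per_pixel"``: a robust
        SD per pixel from its own difference trace — appropriate when
        the scene mixes ratio levels, because shot noise on a ratio
        scales with the ratio, so bright sustained domains are noisier
        than baseline tissue and a single pooled scale under-thresholds
        them.
    """

    k_sigma: float = 4.0
    min_area_px: int = 4
    max_gap_frames: int = 0
    d_max_s: float = 30.0
    link_min_overlap: float = 0.25
    max_area_px: Optional[int] = None
    noise_mode: str = "pooled"

    def __post_init__(self) -> None:
        if not (self.k_sigma > 0):
            raise ValidationError(f"k_sigma must be > 0; got {self.k_sigma}")
        if self.min_area_px < 1:
            raise ValidationError(f"min_area_px must be >= 1; got {self.min_area_px}")
        if self.max_gap_frames < 0:
            raise ValidationError(f"max_gap_frames must be >= 0; got {self.max_gap_frames}")
        if not (self.d_max_s > 0):
            raise ValidationError(f"d_max_s must be > 0; got {self.d_max_s}")
        if not (0 < self.link_min_overlap <= 1):
            raise ValidationError(
                f"link_min_overlap must be in (0, 1]; got {self.link_min_overlap}"
            )
        if self.max_area_px is not None and self.max_area_px < 1:
            raise ValidationError(f"max_area_px must be >= 1; got {self.max_area_px}")
        if self.noise_mode not in ("pooled", "per_pixel"):
            raise ValidationError(
                f"noise_mode must be 'pooled' or 'per_pixel'; got {self.noise_mode!r}"
            )


def classify_duration(duration_s: float, d_max_s: float = 30.0) -> str:
    """Label an event by elevation persistence.

    ``transient`` iff ``duration_s <= d_max_s`` — the bound is inclusive
    ("persists no longer than" the cap), so a 2-frame event at 15-s
    sampling (30 s) is a transient; 3 frames (45 s) is sustained.
    """
    if not (duration_s > 0) or not (d_max_s > 0):
        raise ValidationError(
            f"durations must be positive; got duration_s={duration_s}, d_max_s={d_max_s}"
        )
    return LABEL_TRANSIENT if duration_s <= d_max_s else LABEL_SUSTAINED


def difference_noise_sigma(ratios: RatioStack) -> float:
    """Robust SD of pooled frame-to-frame ratio differences.

    1.4826 x median absolute deviation about the median, over all pixels
    valid in both frames of each consecutive pair.  Zero on noise-free
    piecewise-constant stacks (most differences vanish), which makes the
    detection threshold 'any strictly positive jump'.
    """
    diffs = ratios.ratio[1:] - ratios.ratio[:-1]
    valid_pair = ratios.valid[1:] & ratios.valid[:-1]
    pooled = diffs[valid_pair]
    if pooled.size == 0:
        return 0.0
    med = np.median(pooled)
    return float(1.4826 * np.median(np.abs(pooled - med)))


def difference_noise_sigma_map(ratios: RatioStack) -> np.ndarray:
    """Per-pixel robust SD of the frame-difference trace.

    1.4826 x MAD over time of each pixel's consecutive-frame ratio
    differences, with invalid frame pairs excluded.  Pixels with no
    valid pair get sigma 0.
    """
    diffs = ratios.ratio[1:] - ratios.ratio[:-1]
    valid_pair = ratios.valid[1:] & ratios.valid[:-1]
    masked = np.where(valid_pair, diffs, np.nan)
    with warnings.catch_warnings():
        # all-NaN traces (never-valid pixels) legitimately yield sigma 0
        warnings.simplefilter("ignore", category=RuntimeWarning)
        med = np.nanmedian(masked, axis=0)
        mad = np.nanmedian(np.abs(masked - med[None]), axis=0)
    return 1.4826 * np.nan_to_num(mad)


class _Track:
    """Mutable per-event state during linking."""

    __slots__ = ("seq", "onset", "last_active", "last_rise", "gap", "frames", "baseline")

    def __init__(self, seq: int, onset: int, n_pixels: int):
        self.seq = seq
        self.onset = onset
        self.last_active = onset
        self.last_rise = onset
        self.gap = 0
        self.frames: dict[int, np.ndarray] = {}
        self.baseline = np.full(n_pixels, np.nan)

    def recruit(self, pixels: np.ndarray, prev_ratio_flat: np.ndarray) -> None:
        """Set pre-onset baselines for pixels joining the event now."""
        new = pixels[np.isnan(self.baseline[pixels])]
        self.baseline[new] = prev_ratio_flat[new]


def detect_events(ratios: RatioStack, params: Optional[DetectionParams] = None) -> EventTable:
    """Run the subtractive algorithm on a ratio stack.

    Returns every detected event, both labels, sorted by onset frame.
    A stack with fewer than 2 frames is a validation error; an
    all-invalid stack yields an empty table.
    """
    if params is None:
        params = DetectionParams()
    R = ratios.ratio
    V = ratios.valid
    T = R.shape[0]
    if T < 2:
        raise ValidationError(f"need >= 2 frames to difference; got {T}")
    h, w = R.shape[1:]
    n_px = h * w
    Rf = R.reshape(T, n_px)
    Vf = V.reshape(T, n_px)

    if params.noise_mode == "per_pixel":
        sigma = difference_noise_sigma_map(ratios)
    else:
        sigma = np.full((h, w), difference_noise_sigma(ratios))
    threshold = params.k_sigma * sigma
    threshold_flat = threshold.ravel()

    open_tracks: list[_Track] = []
    closed: list[_Track] = []
    seq = 0

    for t in range(1, T):
        valid_pair = V[t] & V[t - 1]
        rise = np.zeros((h, w), dtype=bool)
        rise[valid_pair] = (R[t] - R[t - 1])[valid_pair] > threshold[valid_pair]

        comps: list[np.ndarray] = []
        if rise.any():
            labels = measure.label(rise, connectivity=2).ravel()
            order = np.argsort(labels, kind="stable")
            sorted_labels = labels[order]
            boundaries = np.searchsorted(sorted_labels, np.arange(1, labels.max() + 1))
            boundaries = np.append(boundaries, labels.size)
            for i in range(len(boundaries) - 1):
                idx = order[boundaries[i]:boundaries[i + 1]]
                if idx.size >= params.min_area_px:
                    comps.append(np.sort(idx))

        # elevation persistence: pixels of an ongoing event stay in it
        # while the ratio holds above pre-onset baseline + threshold
        continuations: dict[int, np.ndarray] = {}
        for tr in open_tracks:
            prev_fp = tr.frames[tr.last_active]
            keep = Vf[t, prev_fp] & (
                Rf[t, prev_fp] > tr.baseline[prev_fp] + threshold_flat[prev_fp]
            )
            continuations[tr.seq] = prev_fp[keep]

        # link rising components to candidate tracks by footprint overlap
        links: dict[int, list[int]] = {tr.seq: [] for tr in open_tracks}
        unlinked: list[np.ndarray] = []
        track_by_seq = {tr.seq: tr for tr in open_tracks}
        # a fresh detection joins a track only if that track itself rose
        # recently or is dormant within the gap allowance.  A detection
        # overlapping a long-elevated plateau (e.g. a transient firing on
        # top of a sustained domain) starts its own event, measured
        # against the elevated pre-onset level.
        for comp in comps:
            hits = []
            for tr in open_tracks:
                rose_recently = t - tr.last_rise - 1 <= params.max_gap_frames
                dormant = 0 < tr.gap <= params.max_gap_frames
                if not (rose_recently or dormant):
                    continue
                fp = tr.frames[tr.last_active]
                inter = np.intersect1d(comp, fp, assume_unique=True).size
                if inter and inter / min(comp.size, fp.size) >= params.link_min_overlap:
                    hits.append(tr.seq)
            if hits:
                links[hits[0]].append(len(unlinked))
                unlinked.append(comp)
                # one component touching several tracks merges them
                for other_seq in hits[1:]:
                    a, b = track_by_seq[hits[0]], track_by_seq[other_seq]
                    if a is b:
                        continue
                    keep_tr, drop = (a, b) if a.seq < b.seq else (b, a)
                    for fr, px in drop.frames.items():
                        if fr in keep_tr.frames:
                            keep_tr.frames[fr] = np.union1d(keep_tr.frames[fr], px)
                        else:
                            keep_tr.frames[fr] = px
                    fill = np.isnan(keep_tr.baseline) & ~np.isnan(drop.baseline)
                    keep_tr.baseline[fill] = drop.baseline[fill]
                    keep_tr.onset = min(keep_tr.onset, drop.onset)
                    keep_tr.last_active = max(keep_tr.last_active, drop.last_active)
                    keep_tr.last_rise = max(keep_tr.last_rise, drop.last_rise)
                    links[keep_tr.seq].extend(links.pop(drop.seq, []))
                    open_tracks.remove(drop)
                    track_by_seq = {tr.seq: tr for tr in open_tracks}
                    continuations[keep_tr.seq] = np.union1d(
                        continuations.get(keep_tr.seq, np.empty(0, np.intp)),
                        continuations.pop(drop.seq, np.empty(0, np.intp)),
                    )
                    if hits[0] == drop.seq:
                        hits[0] = keep_tr.seq
            else:
                unlinked.append(comp)

        linked_comp_ids = {i for ids in links.values() for i in ids}

        still_open: list[_Track] = []
        for tr in open_tracks:
            parts = [continuations.get(tr.seq, np.empty(0, np.intp))]
            parts += [unlinked[i] for i in links.get(tr.seq, [])]
            fp = np.unique(np.concatenate(parts)) if parts else np.empty(0, np.intp)
            if fp.size:
                tr.recruit(fp, Rf[t - 1])
                tr.frames[t] = fp
                tr.last_active = t
                if links.get(tr.seq):
                    tr.last_rise = t
                tr.gap = 0
                still_open.append(tr)
            else:
                tr.gap += 1
                if tr.gap > params.max_gap_frames:
                    closed.append(tr)
                else:
                    still_open.append(tr)
        open_tracks = still_open

        # fresh detections start new events
        for i, comp in enumerate(unlinked):
            if i in linked_comp_ids:
                continue
            tr = _Track(seq, onset=t, n_pixels=n_px)
            tr.recruit(comp, Rf[t - 1])
            tr.frames[t] = comp
            seq += 1
            open_tracks.append(tr)

    closed.extend(open_tracks)

    raw_events = []
    for tr in closed:
        onset = min(tr.frames)
        offset = tr.last_active
        duration_s = (offset - onset + 1) * ratios.dt_s
        area = max(px.size for px in tr.frames.values())
        if params.max_area_px is not None and area > params.max_area_px:
            continue
        peak_delta = -np.inf
        peak_frame = onset
        for fr, px in sorted(tr.frames.items()):
            d = np.max(Rf[fr, px] - tr.baseline[px])
            if d > peak_delta:
                peak_delta = d
                peak_frame = fr
        rows, cols = np.unravel_index(tr.frames[peak_frame], (h, w))
        raw_events.append(
            (onset, tr.seq, offset, duration_s, float(rows.mean()), float(cols.mean()),
             area, float(peak_delta), dict(tr.frames))
        )

    raw_events.sort(key=lambda r: (r[0], r[1]))
    event_list = [
        TransientEvent(
            id=i,
            onset_frame=onset,
            offset_frame=offset,
            duration_s=duration_s,
            centroid=(crow, ccol),
            area_px=area,
            peak_delta_ratio=peak,
            label=classify_duration(duration_s, params.d_max_s),
            footprints=frames,
        )
        for i, (onset, _, offset, duration_s, crow, ccol, area, peak, frames)
        in enumerate(raw_events)
    ]
    return EventTable(
        events=event_list,
        dt_s=ratios.dt_s,
        t0_s=ratios.t0_s,
        n_frames=T,
        height=h,
        width=w,
    )
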