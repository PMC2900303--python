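"""Synthetic dual-wavelength Fura-2 embryo movies with ground truth.

The generator emulates what the analysis pipeline sees in a live
zebrafish imaging session: a spatially structured baseline Ca2+ field
inside an elliptical embryo, sustained high-Ca2+ domains (two lateral
presomitic stripes; intersomitic boundary bands appearing sequentially
as somites form), stochastic localized transients arriving as a Poisson
process, a two-state linear Fura-2 forward model producing the 340- and
380-nm channels, photobleaching drift, and per-pixel Poisson shot
noise.  Every simulated transient is logged, so detection and rate
estimates can be scored against exact ground truth.

The normalized Ca2+ level c(x, t) lives in [0, 1]; channel intensities
are ``bleach(t) * (g_free * (1 - c) + g_bound * c) + offset`` with the
Fura-2 constraint g340_bound > g340_free and g380_bound < g380_free, so
the noise-free ratio increases strictly with c.  Transient kinetics are
rectangular (a disc elevated for a whole number of frames): at 15-s
sampling the threshold/duration analysis cannot resolve sub-frame
kinetics, and an exponential-decay tail is available for robustness
checks.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .events import EventTable
from .stacks import ImagePairStack

DEFAULT_DT_S = 15.0
#: default session: 480 frames at 15 s = 2 h, the length of the
#: somitogenesis time-lapse acquisitions this generator emulates
DEFAULT_FRAMES = 480


@dataclass
class OpticsParams:
    """Channel gains of the two-state Fura-2 model plus camera offset.

    Intensities are in arbitrary units; ``photon_scale`` (in
    :class:`NoiseParams`) converts them to expected photon counts.
    """

    g340_free: float = 0.5
    g340_bound: float = 3.0
    g380_free: float = 3.0
    g380_bound: float = 0.5
    offset: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.g340_free, self.g340_bound, self.g380_free, self.g380_bound, self.offset)
        if any(v < 0 for v in vals):
            raise ValidationError("optics gains and offset must be >= 0")
        if not (self.g340_bound > self.g340_free):
            raise ValidationError("need g340_bound > g340_free (Ca-bound brighter at 340 nm)")
        if not (self.g380_bound < self.g380_free):
            raise ValidationError("need g380_bound < g380_free (Ca-free brighter at 380 nm)")


@dataclass
class NoiseParams:
    """Shot noise and photobleaching.

    photon_scale
        Expected photons per intensity unit; observed counts are Poisson
        with this mean (0 disables noise).
    tau_bleach_s
        Photobleaching time constant; intensity decays as
        exp(-t / tau); ``inf`` disables bleaching.  Both channels bleach
        by the same factor, so the ratio itself is bleach-invariant.
    """

    photon_scale: float = 2000.0
    tau_bleach_s: float = 28800.0

    def __post_init__(self) -> None:
        if self.photon_scale < 0:
            raise ValidationError("photon_scale must be >= 0")
        if not (self.tau_bleach_s > 0):
            raise ValidationError("tau_bleach_s must be > 0")


@dataclass
class SustainedDomain:
    """A geometric region with persistently elevated Ca2+.

    ``kind`` is ``"stripe"`` (a vertical band, columns
    [position - width/2, position + width/2)) or ``"disc"``; the
    elevation applies during frames [on_frame, off_frame).
    """

    kind: str
    elevation_c: float
    on_frame: int = 0
    off_frame: Optional[int] = None
    center: Optional[tuple[float, float]] = None
    radius_px: float = 0.0
    position_col: float = 0.0
    width_px: float = 0.0
    horizontal: bool = False

    def footprint(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        rr, cc = np.mgrid[0:h, 0:w]
        if self.kind == "disc":
            if self.center is None or self.radius_px <= 0:
                raise ValidationError("disc domain needs center and positive radius")
            return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius_px**2
        if self.kind == "stripe":
            axis = rr if self.horizontal else cc
            return np.abs(axis - self.position_col) <= self.width_px / 2.0
        raise ValidationError(f"unknown domain kind {self.kind!r}")


@dataclass
class RoiSuppression:
    """Localized suppression: inside a disc ROI the transient rate is
    multiplied by ``rate_multiplier`` and the baseline + sustained
    elevation by ``level_multiplier`` (the injected-suppressor region of
    a lineage-tracer assay)."""

    center: tuple[float, float]
    radius_px: float
    rate_multiplier: float = 0.1
    level_multiplier: float = 0.6

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValidationError("ROI radius must be > 0")
        if not (0 <= self.rate_multiplier <= 1) or not (0 < self.level_multiplier <= 1):
            raise ValidationError("ROI multipliers must lie in [0, 1]")


@dataclass
class SceneParams:
    """Full specification of one simulated embryo movie.

    Transients arrive as a homogeneous Poisson process at
    ``transient_rate_per_hour``; each is a disc of radius drawn from
    ``transient_radius_px`` elevated by ``transient_amplitude_c`` for a
    duration drawn from ``transient_duration_frames`` (uniform over the
    stated support).  ``morphant_mode`` models enlarged release domains:
    radius doubled, amplitude x1.5, duration pinned to the top of the
    support.  Contributions add and clamp at c = 1.
    """

    frames: int = DEFAULT_FRAMES
    height: int = 128
    width: int = 128
    dt_s: float = DEFAULT_DT_S
    baseline_c: float = 0.15
    sustained_domains: list[SustainedDomain] = field(default_factory=list)
    transient_rate_per_hour: float = 5.3
    transient_duration_frames: tuple[int, ...] = (1, 2)
    transient_radius_px: tuple[int, ...] = (2, 3)
    transient_amplitude_c: tuple[float, float] = (0.2, 0.3)
    exponential_tail: bool = False
    morphant_mode: bool = False
    roi_suppression: Optional[RoiSuppression] = None
    optics: OpticsParams = field(default_factory=OpticsParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames < 2 or self.height < 4 or self.width < 4:
            raise ValidationError("scene needs >= 2 frames and >= 4x4 pixels")
        if not (self.dt_s > 0):
            raise ValidationError("dt_s must be > 0")
        if not (0 <= self.baseline_c <= 1):
            raise ValidationError("baseline_c must be in [0, 1]")
        if self.transient_rate_per_hour < 0:
            raise ValidationError("transient rate must be >= 0")
        if not self.transient_duration_frames or min(self.transient_duration_frames) < 1:
            raise ValidationError("duration support must be positive integers")
        if not self.transient_radius_px or min(self.transient_radius_px) < 1:
            raise ValidationError("radius support must be positive")
        lo, hi = self.transient_amplitude_c
        if not (0 < lo <= hi <= 1):
            raise ValidationError("amplitude range must satisfy 0 < lo <= hi <= 1")

    @property
    def session_hours(self) -> float:
        return self.frames * self.dt_s / 3600.0


@dataclass
class TrueEvent:
    onset_frame: int
    duration_frames: int
    center: tuple[float, float]
    radius_px: float
    amplitude_c: float


@dataclass
class GroundTruthEvents:
    """The realized transient log of one simulated session."""

    events: list[TrueEvent]

    @property
    def count(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


def fura2_forward(
    c_frame: np.ndarray, optics: OpticsParams
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free two-state forward model for one frame.

    F340 = g340_free (1 - c) + g340_bound c + offset, likewise F380;
    the resulting ratio is strictly increasing in c.
    """
    c = np.asarray(c_frame, dtype=np.float64)
    if c.size and (c.min() < 0 or c.max() > 1):
        raise ValidationError("c must lie in [0, 1]")
    f340 = optics.g340_free * (1.0 - c) + optics.g340_bound * c + optics.offset
    f380 = optics.g380_free * (1.0 - c) + optics.g380_bound * c + optics.offset
    return f340, f380


def embryo_ellipse(shape: tuple[int, int], margin: float = 0.06) -> np.ndarray:
    """Boolean ellipse covering most of the frame — the embryo tissue."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = cy * (1 - margin) + 0.5, cx * (1 - margin) + 0.5
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def default_wildtype_domains(shape: tuple[int, int], frames: int) -> list[SustainedDomain]:
    """Two lateral presomitic stripes plus intersomitic boundary bands
    switching on sequentially through the session."""
    h, w = shape
    domains = [
        SustainedDomain(kind="stripe", elevation_c=0.25, position_col=0.2 * w, width_px=0.08 * w),
        SustainedDomain(kind="stripe", elevation_c=0.25, position_col=0.8 * w, width_px=0.08 * w),
    ]
    n_boundaries = 4
    for i in range(n_boundaries):
        on = int(frames * (0.1 + 0.7 * i / max(n_boundaries - 1, 1)))
        domains.append(
            SustainedDomain(
                kind="stripe",
                horizontal=True,
                elevation_c=0.2,
                position_col=h * (0.25 + 0.5 * i / max(n_boundaries - 1, 1)),
                width_px=max(2.0, 0.03 * h),
                on_frame=on,
            )
        )
    return domains


def _sample_transients(params: SceneParams, rng: np.random.Generator) -> list[TrueEvent]:
    h, w = params.height, params.width
    tissue = embryo_ellipse((h, w))
    rows, cols = np.nonzero(tissue)

    dur_support = tuple(params.transient_duration_frames)
    radius_support = tuple(params.transient_radius_px)
    amp_lo, amp_hi = params.transient_amplitude_c
    if params.morphant_mode:
        dur_support = (max(dur_support),)
        radius_support = tuple(2 * r for r in radius_support)
        amp_lo, amp_hi = min(1.5 * amp_lo, 1.0), min(1.5 * amp_hi, 1.0)

    max_dur = max(dur_support)
    latest_onset = params.frames - 1 - max_dur
    if latest_onset < 1:
        raise ValidationError("session too short for the transient durations requested")

    n = rng.poisson(params.transient_rate_per_hour * params.session_hours)
    events: list[TrueEvent] = []
    for _ in range(n):
        # onsets uniform over frames that leave both the rise and the
        # return to baseline observable
        onset = int(rng.integers(1, latest_onset + 1))
        duration = int(rng.choice(dur_support))
        radius = float(rng.choice(radius_support))
        amplitude = float(rng.uniform(amp_lo, amp_hi))
        idx = rng.integers(0, rows.size)
        center = (float(rows[idx]), float(cols[idx]))
        if params.roi_suppression is not None:
            sup = params.roi_suppression
            d2 = (center[0] - sup.center[0]) ** 2 + (center[1] - sup.center[1]) ** 2
            if d2 <= sup.radius_px**2 and rng.random() > sup.rate_multiplier:
                continue
        events.append(TrueEvent(onset, duration, center, radius, amplitude))
    events.sort(key=lambda e: e.onset_frame)
    return events


def _build_c_stack(params: SceneParams, truth: Sequence[TrueEvent]) -> np.ndarray:
    T, h, w = params.frames, params.height, params.width
    tissue = embryo_ellipse((h, w))
    c = np.zeros((T, h, w), dtype=np.float64)
    c[:, tissue] = params.baseline_c

    for dom in params.sustained_domains:
        fp = dom.footprint((h, w)) & tissue
        off = dom.off_frame if dom.off_frame is not None else T
        c[dom.on_frame:off, fp] += dom.elevation_c

    rr, cc = np.mgrid[0:h, 0:w]
    for ev in truth:
        fp = (rr - ev.center[0]) ** 2 + (cc - ev.center[1]) ** 2 <= ev.radius_px**2
        fp &= tissue
        t1 = min(ev.onset_frame + ev.duration_frames, T)
        c[ev.onset_frame:t1, fp] += ev.amplitude_c
        if params.exponential_tail:
            for k, t in enumerate(range(t1, min(t1 + 3, T))):
                c[t, fp] += ev.amplitude_c * np.exp(-(k + 1))

    if params.roi_suppression is not None:
        sup = params.roi_suppression
        roi = (rr - sup.center[0]) ** 2 + (cc - sup.center[1]) ** 2 <= sup.radius_px**2
        roi &= tissue
        c[:, roi] *= sup.level_multiplier

    np.clip(c, 0.0, 1.0, out=c)
    return c


def _roi_reference_image(params: SceneParams) -> Optional[np.ndarray]:
    if params.roi_suppression is None:
        return None
    sup = params.roi_suppression
    h, w = params.height, params.width
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr - sup.center[0]) ** 2 + (cc - sup.center[1]) ** 2
    # smooth-edged tracer distribution, bright in the injected clone
    ref = 1000.0 * np.exp(-d2 / (2.0 * (sup.radius_px / 1.5) ** 2))
    ref[d2 <= sup.radius_px**2] = 1000.0
    return ref.astype(np.float64)


def simulate_scene(params: SceneParams) -> tuple[ImagePairStack, GroundTruthEvents]:
    """Simulate one session; identical params (incl. seed) give
    byte-identical stacks and truth logs.

    Returns the noisy dual-channel stack (uint16 photon counts) and the
    exact transient log.
    """
    rng = np.random.default_rng(params.seed)
    truth = _sample_transients(params, rng)
    c = _build_c_stack(params, truth)

    f340, f380 = fura2_forward(c, params.optics)
    tissue = embryo_ellipse((params.height, params.width))
    # no indicator outside the embryo: camera offset only
    f340[:, ~tissue] = params.optics.offset
    f380[:, ~tissue] = params.optics.offset

    t = np.arange(params.frames, dtype=np.float64) * params.dt_s
    bleach = np.exp(-t / params.noise.tau_bleach_s)[:, None, None]
    f340 = bleach * f340
    f380 = bleach * f380

    scale = params.noise.photon_scale
    if scale > 0:
        f340 = rng.poisson(f340 * scale).astype(np.float64)
        f380 = rng.poisson(f380 * scale).astype(np.float64)
        if f340.max() < np.iinfo(np.uint16).max and f380.max() < np.iinfo(np.uint16).max:
            f340 = f340.astype(np.uint16)
            f380 = f380.astype(np.uint16)

    stack = ImagePairStack(
        f340=f340,
        f380=f380,
        dt_s=params.dt_s,
        reference_540=_roi_reference_image(params),
        meta={"seed": str(params.seed)},
    )
    return stack, GroundTruthEvents(events=truth)


# ---------------------------------------------------------------------------
# presets spanning the experimental groups

def preset(name: str, seed: int = 0, **overrides) -> SceneParams:
    """Named scene presets for the experimental groups.

    ``wildtype`` (5.3 transients/h), ``rgs3_morphant`` (21.7/h, enlarged
    events), ``wnt5b_morphant`` (1.3/h), ``double_morphant`` (1.8/h) and
    ``roi_suppression`` (a 75-min blastula-style session with elevated
    release globally and a suppressed tracer-positive clone).
    """
    shape = (overrides.get("height", 128), overrides.get("width", 128))
    frames = overrides.get("frames", DEFAULT_FRAMES)
    base = dict(
        frames=frames,
        sustained_domains=default_wildtype_domains(shape, frames),
        seed=seed,
    )
    presets = {
        "wildtype": dict(transient_rate_per_hour=5.3),
        "rgs3_morphant": dict(transient_rate_per_hour=21.7, morphant_mode=True),
        "wnt5b_morphant": dict(transient_rate_per_hour=1.3),
        "double_morphant": dict(transient_rate_per_hour=1.8),
        "roi_suppression": dict(
            frames=overrides.get("frames", 300),
            sustained_domains=[],
            baseline_c=0.3,
            transient_rate_per_hour=12.0,
            roi_suppression=RoiSuppression(
                center=(shape[0] * 0.5, shape[1] * 0.3),
                radius_px=0.18 * min(shape),
            ),
        ),
    }
    if name not in presets:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    cfg = {**base, **presets[name], **overrides}
    return SceneParams(**cfg)


PRESET_NAMES = ("wildtype", "rgs3_morphant", "wnt5b_morphant", "double_morphant", "roi_suppression")


# ---------------------------------------------------------------------------
# config round-trip

def params_to_yaml(params: SceneParams) -> str:
    """Serialize SceneParams to human-editable YAML."""
    return yaml.safe_dump(dataclasses.asdict(params), sort_keys=False)


def params_from_yaml(text: str) -> SceneParams:
    """Rebuild SceneParams from YAML written by :func:`params_to_yaml`."""
    raw = yaml.safe_load(text)
    raw["optics"] = OpticsParams(**raw.get("optics", {}))
    raw["noise"] = NoiseParams(**raw.get("noise", {}))
    if raw.get("roi_suppression"):
        rs = raw["roi_suppression"]
        rs["center"] = tuple(rs["center"])
        raw["roi_suppression"] = RoiSuppression(**rs)
    raw["sustained_domains"] = [
        SustainedDomain(**{**d, "center": tuple(d["center"]) if d.get("center") else None})
        for d in raw.get("sustained_domains", [])
    ]
    for key in ("transient_duration_frames", "transient_radius_px", "transient_amplitude_c"):
        raw[key] = tuple(raw[key])
    return SceneParams(**raw)


# ---------------------------------------------------------------------------
# detection scoring against ground truth

def score_detection(
    detected: EventTable,
    truth: GroundTruthEvents,
    tol_frames: int = 1,
    tol_px: float = 5.0,
) -> tuple[float, float, float]:
    """Greedy one-to-one matching of detected events to the truth log.

    A detection matches a truth event when the onset differs by at most
    ``tol_frames`` and the centroid is within ``tol_px``.  Candidate
    pairs are consumed best-first (smallest onset difference, then
    distance, then lowest truth index).  Returns (precision, recall,
    F1); precision with no detections and recall with empty truth are
    reported as 0.0 (the undefined case, flagged in the docstring
    convention rather than raising).
    """
    if tol_frames < 0 or tol_px < 0:
        raise ValidationError("tolerances must be >= 0")
    pairs = []
    for di, det in enumerate(detected.events):
        for ti, tru in enumerate(truth):
            d_onset = abs(det.onset_frame - tru.onset_frame)
            dist = float(
                np.hypot(det.centroid[0] - tru.center[0], det.centroid[1] - tru.center[1])
            )
            if d_onset <= tol_frames and dist <= tol_px:
                pairs.append((d_onset, dist, ti, di))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches = 0
    for _, _, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matches += 1
    n_det = len(detected.events)
    n_tru = len(truth)
    precision = matches / n_det if n_det else 0.0
    recall = matches / n_tru if n_tru else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return precision, recall, f1
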