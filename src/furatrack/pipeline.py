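"""End-to-end convenience wrappers: stack -> ratio -> events.

These chain the stage functions with their defaults; every parameter of
the underlying stages remains reachable through the arguments.
"""
from __future__ import annotations

from typing import Optional

from .detection import DetectionParams, detect_events
from .events import EventTable
from .ratiometry import compute_embryo_mask, compute_ratio
from .simulate import GroundTruthEvents, SceneParams, simulate_scene
from .stacks import ImagePairStack, Mask, RatioStack


def analyze_stack(
    stack: ImagePairStack,
    params: Optional[DetectionParams] = None,
    mask: Optional[Mask] = None,
    mask_quantile: float = 0.1,
    eps: Optional[float] = None,
) -> tuple[RatioStack, EventTable]:
    """Mask the embryo, compute the ratio stack, and detect events."""
    if mask is None:
        mask = compute_embryo_mask(stack, quantile_q=mask_quantile)
    ratios = compute_ratio(stack, mask, eps=eps)
    table = detect_events(ratios, params)
    return ratios, table


def simulate_and_detect(
    scene: SceneParams,
    params: Optional[DetectionParams] = None,
) -> tuple[ImagePairStack, GroundTruthEvents, RatioStack, EventTable]:
    """Simulate a scene and run the full detection pipeline on it."""
    stack, truth = simulate_scene(scene)
    ratios, table = analyze_stack(stack, params=params)
    return stack, truth, ratios, table
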