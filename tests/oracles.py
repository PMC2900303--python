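"""Independent brute-force oracles used only by the tests.

These are deliberately naive implementations — exhaustive enumeration
and 3-D connected-component labelling on tiny inputs — kept free of any
code shared with the package's own algorithms.
"""
from __future__ import annotations

from math import comb

import numpy as np
from scipy import ndimage


def fisher_two_tailed_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p by float enumeration of the hypergeometric support."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    probs = {
        k: comb(row1, k) * comb(n - row1, col1 - k) / denom
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    }
    p_obs = probs[a]
    return min(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)), 1.0)


def anova_f_by_hand(groups: list[list[float]]) -> tuple[float, float, float]:
    """(F, SS_between, SS_within) from first-principles sums of squares."""
    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ss_b = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_w = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_b / df_b) / (ss_w / df_w), ss_b, ss_w


def oracle_detect_noise_free(ratio: np.ndarray, min_area_px: int):
    """Brute-force event detection on a noise-free piecewise-constant stack.

    The per-pixel baseline is frame 0; every strictly elevated pixel in
    frames >= 1 is active, active voxels are grouped by 3-D
    26-connectivity, and components whose largest per-frame footprint
    falls below ``min_area_px`` are dropped.  Returns events as
    (onset, offset, {frame: sorted flat pixel indices}) sorted by onset
    then by smallest pixel index.
    """
    T, h, w = ratio.shape
    elevated = ratio > ratio[0][None]
    elevated[0] = False
    labels, n = ndimage.label(elevated, structure=np.ones((3, 3, 3), dtype=bool))
    events = []
    for lab in range(1, n + 1):
        tt, rr, cc = np.nonzero(labels == lab)
        frames: dict[int, np.ndarray] = {}
        for t in np.unique(tt):
            sel = tt == t
            frames[int(t)] = np.sort(rr[sel] * w + cc[sel])
        if max(px.size for px in frames.values()) < min_area_px:
            continue
        events.append((int(tt.min()), int(tt.max()), frames))
    events.sort(key=lambda e: (e[0], int(e[2][e[0]][0])))
    return events


def random_piecewise_scene(
    rng: np.random.Generator,
    shape: tuple[int, int, int] = (20, 16, 16),
    baseline: float = 1.0,
):
    """A random noise-free piecewise-constant stack of rectangular events.

    Events are constant-footprint blocks placed on a cell grid so that
    footprints of distinct events never touch (8-connectivity) and
    events sharing a cell are separated by >= 2 clean frames.  Some
    blocks are smaller than typical detection area floors; the oracle
    and the detector must agree on all of them.  Returns
    (ratio_stack, events) where events lists
    (onset, duration, row0, col0, height, width, amplitude).
    """
    T, H, W = shape
    ratio = np.full(shape, baseline)
    cell = 6  # 4x4 usable pixels + 2 blank pixels of separation
    cells = [(r, c) for r in range(H // cell) for c in range(W // cell)]
    rng.shuffle(cells)
    events = []
    n_cells = int(rng.integers(1, min(len(cells), 5) + 1))
    for r_cell, c_cell in cells[:n_cells]:
        n_here = int(rng.integers(1, 3))
        t_cursor = 1
        for _ in range(n_here):
            dur = int(rng.integers(1, 5))
            if t_cursor + dur + 2 > T:
                break
            onset = int(rng.integers(t_cursor, T - dur - 1))
            bh = int(rng.integers(1, 5))
            bw = int(rng.integers(1, 5))
            r0 = r_cell * cell + int(rng.integers(0, 5 - bh))
            c0 = c_cell * cell + int(rng.integers(0, 5 - bw))
            amp = float(rng.uniform(0.3, 1.0))
            ratio[onset:onset + dur, r0:r0 + bh, c0:c0 + bw] += amp
            events.append((onset, dur, r0, c0, bh, bw, amp))
            t_cursor = onset + dur + 2
    np.clip(ratio, 0.05, None, out=ratio)
    return ratio, events
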