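"""Transient-frequency quantification and group statistics.

The headline measurement is transients per hour inside a
developmental-stage window.  Somite number serves as the developmental
clock: a linear :class:`StageClock` converts acquisition time to somite
stage, and events are binned by onset stage into a half-open window
``[s_lo, s_hi)`` so rates are additive across adjacent windows.

Group comparisons follow standard small-n practice: one-way ANOVA with
Tukey HSD adjusted pairwise p-values (studentized-range distribution),
and the two-tailed Fisher exact test for 2x2 contingency tables using
the sum-of-small-probabilities convention.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .events import EventTable

#: relative tolerance for probability ties in the two-tailed Fisher test
_FISHER_TIE_RTOL = 1e-7


@dataclass
class StageClock:
    """Linear map from acquisition time to somite stage.

    stage(t) = s0 + somites_per_hour * t / 3600, strictly increasing.
    Defaults (s0=2, 5 somites/h) let a 2-h session span roughly the
    2- to 12-somite stages.
    """

    s0: float = 2.0
    somites_per_hour: float = 5.0

    def __post_init__(self) -> None:
        if not (self.somites_per_hour > 0):
            raise ValidationError(
                f"somites_per_hour must be > 0; got {self.somites_per_hour}"
            )

    def stage_at(self, t_s: float) -> float:
        return self.s0 + self.somites_per_hour * t_s / 3600.0

    def time_of_stage(self, stage: float) -> float:
        return (stage - self.s0) * 3600.0 / self.somites_per_hour


@dataclass
class GroupSummary:
    """Per-group transient-rate summary (one rate per embryo)."""

    label: str
    rates: list[float]
    n: int
    mean_rate: float


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey HSD adjusted pairwise p-values."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey_p: dict[tuple[str, str], float]


def window_hours(clock: StageClock, s_lo: float, s_hi: float) -> float:
    """Duration, in hours, of the stage window [s_lo, s_hi)."""
    if not (s_lo < s_hi):
        raise ValidationError(f"need s_lo < s_hi; got [{s_lo}, {s_hi}]")
    return (s_hi - s_lo) / clock.somites_per_hour


def rate_per_hour(
    table: EventTable,
    clock: StageClock,
    s_lo: float,
    s_hi: float,
) -> float:
    """Transient events per hour with onset stage in [s_lo, s_hi).

    Only ``transient``-labelled events count; an event straddling the
    window boundary counts iff its onset falls inside.  The window must
    lie within the session's stage span.
    """
    hours = window_hours(clock, s_lo, s_hi)
    session_start = clock.stage_at(table.t0_s)
    # the session spans the full frame grid (n * dt), so a 480-frame,
    # 15-s acquisition covers exactly 2 h of stage progression
    session_end = clock.stage_at(table.t0_s + table.n_frames * table.dt_s)
    tol = 1e-9
    if s_lo < session_start - tol or s_hi > session_end + tol:
        raise ValidationError(
            f"stage window [{s_lo}, {s_hi}] outside session span "
            f"[{session_start:.3f}, {session_end:.3f}]"
        )
    count = 0
    for event in table.transients:
        stage = clock.stage_at(table.t0_s + event.onset_frame * table.dt_s)
        if s_lo <= stage < s_hi:
            count += 1
    return count / hours


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact p for a 2x2 table of non-negative counts.

    Conditional on the margins, sums the hypergeometric probabilities of
    every table whose point probability is at most that of the observed
    table (ties resolved with relative tolerance 1e-7) — the
    sum-of-small-probabilities convention.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"need a 2x2 table; got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValidationError("table entries must be integers")
        arr = arr.astype(np.int64)
    if arr.min() < 0:
        raise ValidationError("table entries must be non-negative")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if min(row1, col1, c + d, b + d) <= 0:
        raise ValidationError("all margins must be positive")
    # hypergeometric point probabilities share the denominator C(n, col1);
    # comparing integer numerators keeps the tie rule exact
    numer = {
        k: comb(row1, k) * comb(n - row1, col1 - k)
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    }
    n_obs = numer[a]
    scale = 10**7  # integer form of the 1e-7 relative tie tolerance
    tail = sum(v for v in numer.values() if v * scale <= n_obs * (scale + 1))
    p = tail / comb(n, col1)
    return min(float(p), 1.0)


def anova_oneway_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA with all-pairs Tukey HSD.

    F = (SS_between/df_between)/(SS_within/df_within); the omnibus p
    comes from the F distribution.  The Tukey-Kramer statistic for a
    pair is q = |m_i - m_j| / sqrt(MS_within (1/n_i + 1/n_j) / 2), with
    the adjusted p from the studentized-range distribution.  All pairs
    are tested regardless of omnibus significance, per standard HSD
    practice.
    """
    if len(groups) < 2:
        raise ValidationError(f"need >= 2 groups; got {len(groups)}")
    data = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for name, values in data.items():
        if values.size < 2:
            raise ValidationError(f"group {name!r} has {values.size} observation(s); need >= 2")
    k = len(data)
    all_values = np.concatenate(list(data.values()))
    n_total = all_values.size
    grand = all_values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_between = k - 1
    df_within = n_total - k
    if ss_within <= 0:
        raise DegenerateInputError("zero within-group variance; F undefined")
    ms_within = ss_within / df_within
    f_stat = (ss_between / df_between) / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within))

    tukey: dict[tuple[str, str], float] = {}
    for (name_i, vi), (name_j, vj) in combinations(data.items(), 2):
        q = abs(vi.mean() - vj.mean()) / np.sqrt(
            ms_within * (1.0 / vi.size + 1.0 / vj.size) / 2.0
        )
        tukey[(name_i, name_j)] = float(stats.studentized_range.sf(q, k, df_within))
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        tukey_p=tukey,
    )


def summarize_groups(
    group_tables: Mapping[str, Sequence[EventTable]],
    clock: StageClock,
    s_lo: float,
    s_hi: float,
) -> tuple[dict[str, GroupSummary], AnovaResult | None]:
    """Per-embryo rates aggregated into group summaries plus ANOVA.

    Each embryo contributes one transients-per-hour value over the stage
    window; groups report their n and arithmetic mean.  ANOVA/Tukey runs
    when at least two groups have >= 2 embryos each (and within-group
    variance is not identically zero); otherwise the second return value
    is None.
    """
    summaries: dict[str, GroupSummary] = {}
    for label, tables in group_tables.items():
        if len(tables) < 1:
            raise ValidationError(f"group {label!r} has no embryos")
        rates = [rate_per_hour(tbl, clock, s_lo, s_hi) for tbl in tables]
        summaries[label] = GroupSummary(
            label=label, rates=rates, n=len(rates), mean_rate=float(np.mean(rates))
        )
    eligible = {k: s.rates for k, s in summaries.items() if s.n >= 2}
    anova = None
    if len(eligible) >= 2:
        try:
            anova = anova_oneway_tukey(eligible)
        except DegenerateInputError:
            anova = None
    return summaries, anova
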