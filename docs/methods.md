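# Methods

This note documents the models, algorithms and numerical choices in
furatrack, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the problem admitted more than one
reasonable answer.

## Ratio computation

The observable is a pair of aligned fluorescence stacks, F₃₄₀ and F₃₈₀,
acquired at a fixed interval Δt (default 15 s). The analysis quantity
is the pixel-wise ratio R = F₃₄₀/F₃₈₀, which increases strictly with
the fraction of Ca²⁺-bound indicator and cancels factors common to both
channels. No absolute [Ca²⁺] calibration is attempted: all results are
in ratio units, and transient detection depends only on ratio *changes*.

Two masking rules keep the quotient well defined:

- **Embryo mask.** A pixel is tissue when its time-mean F₃₈₀ is
  positive *and* at least the `quantile_q` quantile (default 0.1) of
  the time-mean image; holes are filled. The positivity guard handles
  the exactly-zero background of an ideal dark camera, where the
  quantile itself can be zero. A mask covering less than `min_fill`
  (default 5%) of the frame raises a degenerate-input error. Real
  acquisitions with a nonzero camera offset need `quantile_q` placed
  between the background fraction and the tissue fraction of the frame;
  the default is tuned for dark-background data.
- **Denominator floor.** ε defaults to 1% of the 99th percentile of
  F₃₈₀ — a relative rule, robust to bit depth. Pixels with F₃₈₀ < ε or
  F₃₄₀ ≤ 0 are invalid in that frame and excluded from every downstream
  statistic; invalid entries are stored as 0, never NaN, so array code
  stays finite.

Pseudocolor rendering clamps R to a display range [lo, hi] (default:
1st/99th percentiles of valid session ratios), encodes level =
⌊255·s⌋ with s the clamped unit-scaled value (s = 1 → 255), and maps
levels through a fixed blue→green→yellow→red 256×3 lookup table shipped
as CSV so renders are bit-reproducible. Invalid pixels render black.

## Transient detection (the subtractive algorithm)

Given a ratio stack R with validity mask V:

1. **Differences.** D[t] = R[t] − R[t−1] for t = 1..T−1, on pixels
   valid in both frames. Only positive-going differences are
   considered: the analysis counts Ca²⁺ release, not clearance.
2. **Noise scale.** σ = 1.4826 · median(|D − median(D)|), pooled over
   all valid difference samples (`noise_mode="pooled"`, the default).
   On noise-free piecewise-constant input σ = 0 and the threshold
   degenerates to "any strictly positive jump", which is what makes
   exact oracle comparisons possible.
3. **Seeding.** Pixels with D[t] > k·σ (default k = 4) are active;
   per-frame 8-connected components with area ≥ `min_area_px`
   (default 4) become detections.
4. **Linking and persistence.** Detections in consecutive frames
   (allowing ≤ `max_gap_frames` dropouts, default 0) are linked into
   one event when footprints overlap by ≥ `link_min_overlap` (default
   0.25) of the smaller footprint. Independently, a pixel remains part
   of an ongoing event while R stays above that pixel's *pre-onset
   baseline* + k·σ, so event duration measures how long Ca²⁺ stays
   elevated, not merely how fast it rose — without this, a slow 30-s
   plateau would fragment into spurious short events.
5. **Labelling.** Duration is (offset − onset + 1)·Δt over the
   inclusive active frame range. Events with duration ≤ `d_max_s`
   (default 30 s) are `transient`, otherwise `sustained` — the bound is
   inclusive, so a 2-frame event at 15-s sampling is exactly a
   transient and a 3-frame event (45 s) is sustained.

Two design points deserve emphasis:

- **Linking is rise-to-rise.** A fresh detection joins an existing
  event only if that event itself rose recently (within the gap
  allowance) or is dormant inside a tolerated dropout. It never joins
  an event merely because the event's *elevation* persists under it.
  Otherwise a transient firing on top of a long-elevated sustained
  domain would be absorbed into the sustained event and vanish from the
  frequency count; with rise-to-rise linking it becomes its own event,
  measured against the elevated pre-onset level.
- **Size never disqualifies.** Footprint area is recorded (`area_px`)
  but is not an exclusion criterion, because enlarged release domains
  are a real phenotype that must remain countable. An optional
  `max_area_px` exists for sensitivity analyses only.

**Noise modes.** Shot noise on a ratio is approximately proportional to
the ratio, so scenes mixing bright sustained domains with baseline
tissue are strongly heteroscedastic: the pooled σ under-estimates the
difference noise inside high-ratio domains by roughly the ratio
contrast (≈4× in the default simulated scenes) and floods them with
false detections. `noise_mode="per_pixel"` instead computes σ per pixel
as 1.4826·MAD over that pixel's own difference trace, which restores
uniform false-positive control. The pooled estimator remains the
default (it is the minimal reading of a single subtractive threshold
and is exact in the noise-free limit); the per-pixel mode is
recommended — and used throughout the examples and the acceptance
script — whenever the scene contains sustained structure.

**Known limitation.** A negative deflection (Ca²⁺ dip) produces a
positive difference when it recovers; the recovery is detected as an
event whose elevation (relative to the dipped pre-onset level)
persists, so it is labelled sustained. Dips therefore never inflate
transient counts, but they do appear in the sustained tally.

## Composite maps and ROI contrasts

The composite map increments, per pixel, one count for each transient
event whose union footprint covers it (each event counts once per pixel
regardless of how many frames it occupied there). Sustained events are
excluded by default and available behind a flag. Conservation holds
exactly: Σcounts = Σ event footprint sizes, max(counts) ≤ n_events.

The ROI contrast assigns transients by centroid membership (nearest
pixel; fractional-overlap assignment was considered and rejected as a
default for determinacy), yielding an exact partition:
rate_in·hours + rate_out·hours = transient count. Ratio means are taken
over valid pixels in each region across all frames. The ROI itself is
segmented from the lineage-tracer reference image as the largest
8-connected component at ≥ 50% of the image maximum.

## Stage clock and rates

Somite stage is a linear clock: stage(t) = s0 + r·t/3600, default
s0 = 2 and r = 5 somites/h, so a 2-h, 480-frame session spans stages
2–12. The session's stage span is computed over the full frame grid
(n·Δt). Transients are assigned to the window [s_lo, s_hi) by onset
stage — half-open, so rates are exactly additive over adjacent windows;
an event straddling the boundary counts iff its onset is inside.
Session length, clock rate and window are all configuration, never
hard-coded.

## Statistics

- **Fisher exact (two-tailed).** Conditional on the margins, the p-value
  sums hypergeometric probabilities of all tables whose point
  probability is at most that of the observed table
  (sum-of-small-probabilities convention). Point probabilities are
  compared as exact integer numerators (the common denominator C(n, c₁)
  cancels) with the 1e−7 relative tie tolerance applied in integer
  arithmetic, so results carry no floating-point tie ambiguity.
- **One-way ANOVA + Tukey HSD.** Textbook sums of squares;
  F = (SS_b/df_b)/(SS_w/df_w); omnibus p from the F distribution. The
  Tukey–Kramer statistic q = |mᵢ−mⱼ|/√(MS_w(1/nᵢ+1/nⱼ)/2) is referred
  to the studentized-range distribution (scipy's implementation,
  numerically integrated). All pairs are tested regardless of omnibus
  significance, per standard HSD practice. Groups need ≥ 2 observations
  each; identically-zero within-group variance is a degenerate-input
  error rather than an infinite F.

## Synthetic movie generator

The generator emulates a live dual-wavelength acquisition well enough
to validate every pipeline stage against known truth:

- **Geometry.** An elliptical embryo on dark background; two lateral
  sustained stripes (elevation Δc = 0.25) flanking the midline; four
  intersomitic boundary bands (Δc = 0.2) switching on sequentially
  through the session, approximating progressive somite formation.
  Geometry is configuration, not hard-coded biology.
- **Transients.** A homogeneous Poisson process at
  `transient_rate_per_hour`, with i.i.d. marks: disc radius uniform on
  {2, 3} px, amplitude uniform on [0.2, 0.3] (normalized Ca²⁺ units),
  duration uniform on {1, 2} frames. Kinetics are rectangular: at 15-s
  sampling the threshold/duration analysis cannot resolve sub-frame
  kinetics (an optional exponential tail exists for robustness checks).
  Onsets are drawn on frames [1, T−1−d] so both the rise and the return
  are observable — an onset at frame 0 has no predecessor frame and is
  undetectable by any differencing method — while the expected count
  stays rate × session length. Contributions add and clamp at c = 1.
- **Morphant mode** models enlarged release domains: radius doubled,
  amplitude ×1.5, duration pinned to the top of the support (2 frames =
  30 s, still inside the transient bound — longer durations would be
  reclassified sustained and drop out of the frequency count, which is
  not the phenotype being modelled).
- **Forward model.** Two-state linear indicator:
  F = bleach(t)·(g_free·(1−c) + g_bound·c) + offset per channel, with
  g₃₄₀ increasing and g₃₈₀ decreasing in c (so R is strictly increasing
  in c), bleach(t) = exp(−t/τ), τ default 8 h (≈22% decay over 2 h;
  both channels bleach equally, so the ratio is bleach-invariant).
  The camera offset defaults to 0 — an ideal dark background, which
  makes the quantile embryo mask exact; a positive offset is available
  and then requires a matched mask quantile.
- **Noise.** Per-pixel, per-frame, per-channel Poisson counts with mean
  `photon_scale` × intensity (default 2000 photons per unit, ≈2.6%
  relative ratio noise at baseline — bright, slow-scan acquisition).
- **Determinism.** Identical parameters including the seed give
  byte-identical stacks and truth logs.
- **Presets.** `wildtype` (5.3 transients/h), `rgs3_morphant` (21.7/h,
  morphant mode), `wnt5b_morphant` (1.3/h), `double_morphant` (1.8/h) —
  2-h, 480-frame, 128×128 sessions — and `roi_suppression`, a 300-frame
  (75-min) blastula-style session with elevated release (12/h) and a
  tracer-positive clone in which the rate is multiplied by 0.1 and the
  Ca²⁺ level by 0.6, with a matching 540-nm reference image.

**What passing tests do and do not show.** The generator reproduces the
statistical structure the analysis depends on (two release modes,
Poisson arrivals, ratio-dependent shot noise, bleaching) but not cell
movement, indicator compartmentalization, differential channel
bleaching, optical blur, or focus drift. Validation on these movies
demonstrates that the pipeline recovers known event statistics under
the stated noise model; it does not certify performance on real data
whose artifacts fall outside that model — in particular, real scenes
with motion would need registration upstream (explicitly out of scope:
stacks are assumed aligned).

## Problem sizes

The test suite validates the detector exactly against a brute-force 3-D
connected-component oracle on 200 randomized noise-free 16×16×20
scenes, and runs full-pipeline recovery at rates {1.3, 1.8, 5.3, 21.7}
per hour over 20 seeded 2-h 128×128 sessions each; the ROI contrast is
checked over 50 seeded 75-min sessions. The acceptance script uses
cohorts of 3/3/2/5 embryos at full session size. These sizes were
chosen so that every stochastic assertion has comfortable Monte-Carlo
margins while the whole validation remains a desk-scale computation.
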