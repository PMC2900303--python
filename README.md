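# furatrack

Ratiometric Fura-2 calcium-imaging analysis for developmental biology:
from paired 340/380-nm fluorescence stacks to counted Ca²⁺ transients
and group statistics.

## The problem

Fura-2 is a ratiometric Ca²⁺ indicator: its excitation optimum shifts
from ~380 nm (Ca²⁺-free) to ~340 nm (Ca²⁺-bound), so the pixel-wise
ratio R = F₃₄₀/F₃₈₀ increases monotonically with intracellular free
Ca²⁺ and cancels common multiplicative factors (dye load, illumination,
uniform bleaching). In live zebrafish embryos imaged at 15-s intervals,
Ca²⁺ release appears in two modes: *sustained* elevations (presomitic
stripes, intersomitic boundaries) and *transients* — localized
elevations persisting no longer than 30 s (an inclusive 2-frame bound
at 15-s sampling). The frequency of transients per hour over a
developmental-stage window is the headline measurement, compared across
experimental groups (wild-type vs morpholino knockdowns) with one-way
ANOVA + Tukey HSD, or with the two-tailed Fisher exact test for
categorical outcomes.

furatrack implements this pipeline end to end for researchers doing
ratiometric Ca²⁺ imaging:

- **ratiometry** — masked ratio stacks with a robust denominator floor,
  pseudocolor rendering (blue = low Ca²⁺ → yellow/red = high) through a
  fixed, shipped 256-entry lookup table, ROI segmentation from a
  lineage-tracer (Texas Red, 540-nm) reference image;
- **detection** — the subtractive algorithm: consecutive-frame
  differences D[t] = R[t] − R[t−1], thresholded at k·σ where σ is a
  robust (MAD-based) noise scale, grouped into 8-connected components,
  linked through time by footprint overlap, with event duration
  measured by persistence of elevation above the pre-onset baseline;
  events are labelled `transient` (duration ≤ 30 s) or `sustained`;
- **composite maps** — per-pixel counts of transient coverage over a
  session, plus ROI-vs-complement rate and mean-ratio contrasts;
- **quantification** — transients/hour inside a somite-stage window via
  a linear stage clock, group summaries, exact-enumeration Fisher test,
  ANOVA with studentized-range Tukey p-values;
- **simulation** — a dual-wavelength movie generator with a two-state
  Fura-2 forward model, Poisson transient arrivals, photobleaching and
  shot noise, returning exact ground-truth event logs for validation.

## Worked example

```sh
python examples/simulate_and_detect.py
```

```
simulated 480 frame pairs at dt=15s (2.0 h); ground truth holds 9 transients
detected 13 events: 9 transient (<= 30 s), 4 sustained (the domain turn-ons)
transient frequency over somites [6, 12): 4.17 events/h (generator rate 5.3/h)
```

The 480-frame session covers somite stages 2→12 under the default
stage clock (5 somites/h from stage 2). All 9 simulated transients are
recovered; the 4 sustained events are the intersomitic boundary bands
switching on, correctly excluded from the transient count by the 30-s
rule. The 4.17/h estimate is the Poisson-sampled realization of the
5.3/h generating rate inside the 1.2-h window.

`examples/group_statistics.py` runs four simulated cohorts (rates 5.3,
21.7, 1.3, 1.8 transients/h; n = 3, 3, 2, 5 embryos) through the full
pipeline and prints:

```
group              mean rate (/h)   n
wildtype                 5.56      3
rgs3_morphant           20.56      3
wnt5b_morphant           1.25      2
double_morphant          2.17      5

one-way ANOVA: F(3,9) = 24.79, p = 0.0001102
  Tukey wildtype vs rgs3_morphant: p = 0.001174 *
  Tukey wnt5b_morphant vs double_morphant: p = 0.9847
```

The high-rate morphant group separates from every other group while the
two low-rate knockdowns are indistinguishable — the epistasis pattern
the statistics are designed to resolve. See also
`examples/composite_and_roi.py` (localized-suppression assay) and
`examples/render_pseudocolor.py`.

## Command line

Each stage is also a subcommand of the `furatrack` CLI
(`simulate`, `detect`, `render`, `quantify`, `compare`, `pipeline`),
writing TIFF/CSV/PNG/JSON artifacts with a `provenance.json` capturing
the effective parameters. `furatrack pipeline --preset wildtype --seed 1
--out run/` chains simulate → detect → quantify in one shot.

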