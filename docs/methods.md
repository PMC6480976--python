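# Methods

This note records the statistical model behind each layer of a raincloud
figure, the defaults and why they were chosen, what the synthetic generators
do and do not emulate, and the numerical/design decisions that were genuinely
open.

## Density estimation (the cloud)

The cloud is a Gaussian kernel density estimate,
`f(v) = (n h)^-1 Σ_i φ((v − x_i)/h)`, evaluated on a uniform grid of 512
points. The grid spans `[min(x) − cut·h, max(x) + cut·h]` with `cut = 3` by
default; `trim = True` restricts it to the data range instead (the
violin-style trimmed look), and `cut = 0` reproduces the untrimmed-but-tight
grid some plotting stacks use. With `cut ≥ 4` the trapezoid mass of the curve
is within 10⁻³ of 1; smaller cuts deliberately truncate tail mass.

**Bandwidth.** Reference implementations of this plot family disagree on the
default rule (nrd0, Scott, and a normal-reference rule respectively). We use
Silverman's nrd0 everywhere — `h = 0.9·min(σ̂, IQR/1.34)·n^(−1/5)` — because
it is the default of the R stack this plot style grew out of, with `adjust`
as a pure multiplier on the rule and `bandwidth_override` replacing it
outright. When the spread estimate degenerates (IQR = 0, then sd = 0) the
rule falls back to sd, then |first value|, then 1, so a positive bandwidth
always exists. For a single observation, where the rule is undefined
(n ≥ 2 required), the composers use `0.9·max(|x₁|, 1)` — the same fallback
scale the rule ends at.

**Average shifted histogram.** The `ash` method averages `m` histograms of
bin width `w` whose origins shift by `w/m`. We compute it exactly on a fine
grid of `w/m` cells: cell `j+k` shares a bin with cell `j` in `m − |k|` of
the `m` shifted histograms, so the average is a triangular moving window over
cell counts — which is also why ASH converges to a triangular-kernel KDE of
bandwidth `w` as `m` grows. Default `m = 32`; the curve is renormalized to
unit trapezoid mass. Robust reweighting variants of ASH are out of scope;
the plain estimator is labeled `ash`.

## Boxplot statistics

Quartiles use type-7 linear interpolation of order statistics (the shared
default of the R and Python scientific stacks, verified against an
independent sort-based oracle on every small integer multiset in the tests).
Whiskers reach to the most extreme *attained data values* inside the Tukey
fences `[q1 − k·IQR, q3 + k·IQR]`, `k = 1.5`; data beyond the fences are
outliers. Because the rain already shows every observation, box glyphs hide
their outlier markers by default (`show_outliers=False`) to avoid
double-plotting the same points.

## Grouped summaries

`summary_se` reports per group: `N` (non-missing count), mean, median, `sd`
with denominator N−1, `se = sd/√N`, and `ci = se·t_{(1+conf)/2, N−1}`. The
Student-t quantile (not a normal quantile) is forced by the arithmetic of
the reference tables this implementation reproduces: their printed ci/se
ratios match t quantiles at N−1 degrees of freedom to all printed digits.
Groups of size 1 report NaN spread columns with a warning. Missing values
are dropped at `Sample` construction and logged; `N` counts non-missing
observations only.

## Geometry and layout

Internal coordinates are always (position, value); category k (1-based) sits
at position k, and orientation ("v"/"h") is metadata applied once at render
time, which makes the flip operation an exact involution. Layout constants
default to the step-by-step recipe: cloud nudged +0.2 off the tick, box at
+0.25, rain at the tick (shifted by `−move` when the rain should fall clear
of the box), jitter width 0.15, box width 0.1. All are exposed on
`PlotConfig`.

Jitter is uniform on `±width/2` (both reference stacks use uniform jitter),
drawn from `numpy.random.default_rng(seed)`; value-axis jitter defaults to 0
and is opt-in for ordinal data. Per-cell seeds are derived from the figure
seed and the cell indices through a fixed integer hash, so adding a level
does not silently reshuffle the other cells.

Violin scaling defaults to `width` (each cloud's mode reaches `max_width`);
`area` mode divides by a caller-supplied sibling maximum so that sibling
clouds share one scale — keeping the operation pure rather than having it
inspect global state.

Whether dodged boxplots should also dodge their clouds is handled by dodging
the whole cell (cloud, rain and box move together); overlaid clouds with
dodged boxes remain reachable by composing manually with `apply_offset`.

## Repeated-measures designs

The 1×1 design places two paired arms at ticks 1 and 2; each row gets one
uniform jitter draw (`jit_distance`, default 0.09, seed default 321), and
each subject's pair of observations is connected by a segment whose
endpoints are *bitwise* the rain coordinates — the line touches its dots.
Clouds face outward (arm 1 left, arm 2 right) unless `align_clouds` makes
both face right. The 2×2 design spreads four arms over ticks 1–4
(`spread_x_ticks`) or overlays two conditions on ticks 1–2; subjects are
linked within each condition's pre/post pair only — linking across
conditions at a shared tick is not well defined and is not drawn.

The stacked factorial variant lays one band per timepoint at integer
positions along a horizontal axis, overlays the G group densities per band
with a shared density scale, rescales the tallest cloud to 0.8 band
spacings so neighbouring bands cannot overlap (a deterministic rescale in
place of manual axis limits), marks each cell mean, and threads each
group's means across bands with T−1 segments.

## Synthetic data

`simulate_two_groups` draws Group1 from a shifted exponential with scale
`sd` and shift `mean − sd` — the unique parameterization whose population
mean *and* sd both equal the targets — and Group2 from N(mean, sd). Defaults
target mean 50, sd 25; the benchmark size is 1000 per group and the tutorial
size 250. The optional second factor splits each group into a "high" first
half and "low" second half. `simulate_repeated_measures` generates the
2-group (n = 18/11) × 3-timepoint factorial with cell means and sds set to
the reference summary table, making that table the generative ground truth
in expectation. `simulate_bimodal` is a two-component normal mixture used to
demonstrate what a boxplot hides: its box spans both clusters while the
density shows two modes. Note that with well-separated modes the *sample*
median is unstable — it lands inside whichever cluster holds more than half
the draws — so tests assert the box spans the gap rather than a median
near zero.

The generators emulate the moment structure, sample sizes and factorial
shape of the motivating datasets, not their exact draws (the original seeds
are unpublished, so quantities like a specific sample mean of 49.45877 are
not reproducible; the se/ci arithmetic is, and is tested to all printed
digits). They produce i.i.d. draws: no within-subject correlation across
timepoints, no measurement error model, no missingness. Passing tests
therefore demonstrate correctness of the statistics and geometry, not
robustness to the messier features of real data.

## Rendering

SVG is the reference backend: each primitive maps to a fixed element
structure (polygon → `path`, point set → `g` of `circle`s, box →
`g class="box-glyph"`, error bar → three `line`s, mean marker → a diamond
`path`), coordinates pass through one linear transform recorded in `data-*`
attributes on the root (so tests invert it), floats are written with four
decimals, and identical scenes produce identical bytes. PNG export goes
through matplotlib and is explicitly not byte-stable.

## Problem sizes in the tests

The suite runs distributional checks at n ≤ 1000 per group and the
moment-recovery property over 200 seeds at n = 1000; exhaustive boxplot
validation covers all ~1300 integer multisets of size ≤ 8 over {0..4}.
These sizes keep the full suite to a few seconds while leaving the
sampling-error bounds tight enough to detect parameterization mistakes
(e.g., a wrong exponential shift moves Group1's mean by a full sd of the
sampling distribution).

## Known limitations

* No weighted observations, beeswarm packing, polar coordinates, or
  significance annotations.
* `area` violin scaling requires the caller to supply the sibling maximum.
* The ASH estimator is the plain (unweighted) version.
* CSV is the only tabular input format; SVG 1.1 and PNG the only outputs.
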