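# raincloudpy

Raincloud plots for Python: a composite statistical graphic that shows a
distribution three ways at once —

* a **cloud**: the kernel density estimate drawn on one side of the category
  axis only (a "flat" or un-mirrored half-violin),
* the **rain**: every raw observation, jittered along the category axis to
  reduce overplotting, and
* a robust **summary**: a Tukey boxplot, or the group mean with a Student-t
  95% confidence interval.

Bar plots of group means hide distribution shape entirely; two groups with
identical means and standard deviations — one skewed, one normal — produce
identical bars. A raincloud keeps central tendency, spread, skew, outliers,
bimodality and the individual data points all visible in one figure, which is
why the format has become popular in biostatistics and neuroscience.

The package is built for reproducibility-minded users: figures are assembled
as an explicit, backend-agnostic **scene graph** (`FigureScene`, an ordered
list of polygons, point sets, segments, box glyphs, error bars and markers in
(category-position, value) coordinates). Scenes render deterministically to
SVG — the same data, configuration and seed always produce byte-identical
output — or to PNG through matplotlib. Grouped/dodged, faceted, and linked
repeated-measures variants (per-subject connecting lines, and the stacked
factorial layout) are included, along with seeded synthetic-data generators
so every feature can be exercised without external data.

## The statistics underneath

* **Density**: Gaussian KDE, `f(v) = (nh)^-1 Σ_i φ((v − x_i)/h)`, evaluated
  on a uniform grid extending `cut·h` beyond the data range (or trimmed to
  it). The default bandwidth is Silverman's rule-of-thumb
  `h = 0.9·min(σ̂, IQR/1.34)·n^(−1/5)`, with `adjust` as a pure multiplier
  and an explicit bandwidth override. An average shifted histogram (`ash`)
  is available as an alternative estimator; it converges to a
  triangular-kernel KDE as the number of shifts grows.
* **Boxplot**: type-7 (linearly interpolated) quartiles, whiskers at the most
  extreme data values within `1.5·IQR` fences, points beyond them flagged as
  outliers.
* **Summary table**: per group `N`, mean, median, `sd` (denominator N−1),
  `se = sd/√N`, and `ci = se·t_{(1+conf)/2, N−1}`, the half-width of the
  t-based confidence interval.
* **Jitter**: uniform on `±width/2`, drawn from a generator seeded by a
  single integer, so point clouds and subject-linking lines are exactly
  reproducible.

## Worked example

```python
import raincloudpy as rc
from raincloudpy.scene import Polygon, PointSet, BoxGlyph

# two groups with equal target moments (mean 50, sd 25): one shifted
# exponential, one normal
table = rc.simulate_two_groups(
    rc.SimSpec(n_per_group=250, target_mean=50, target_sd=25, seed=42)
)
print(rc.summary_se_frame(table, "score", ["group"]).to_string(index=False))

scene = rc.compose_raincloud(table, "group", "score", rc.PlotConfig(seed=42))
print("polygons:", scene.count(Polygon),
      "point sets:", [len(p) for p in scene.of_type(PointSet)],
      "boxes:", scene.count(BoxGlyph))
rc.write_scene_svg(scene, "raincloud.svg")
```

prints

```
 group   N  score_mean  score_median        sd       se       ci
Group1 250   49.588548     42.969314 22.772750 1.440275 2.836675
Group2 250   51.201997     52.295585 25.060806 1.584985 3.121685
polygons: 2 point sets: [250, 250] boxes: 2
```

Both group means sit near 50, but Group1's median (43.0) falls well below its
mean — the skew of the exponential group, invisible in a bar plot, that the
cloud and rain make obvious. `se` is `sd/√250` and `ci` is `se` times the
97.5% Student-t quantile with 249 degrees of freedom. The scene contains one
half-violin, one 250-point rain layer and one box glyph per group;
`raincloud.svg` renders them deterministically.

The same figures are available from the shell:

```bash
raincloud simulate --kind two-groups --n 250 --seed 42 --output sim.csv
raincloud plot --input sim.csv --x group --y score --seed 42 --output fig.svg
raincloud summary --input sim.csv --measure score --group group
raincloud repmes --input wide.csv --design 1x1 --jit-seed 321 --output linked.svg
```

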