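"""Assemble complete raincloud figures as :class:`FigureScene` objects.

A raincloud is three aligned layers per category: a one-sided kernel density
("cloud", nudged off the category position), the jittered raw observations
("rain"), and a summary glyph (Tukey boxplot by default, or a mean +/- CI
overlay).  This module builds the single-factor, hue-grouped/dodged and
faceted variants, plus the bar-and-error-bar comparison figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import palettes
from .geometry import Offset, build_half_violin, dodge_offsets, jitter_points
from .scene import Bar, BoxGlyph, ErrorBar, FigureScene, Marker, PointSet, Segment
from .stats import (
    Sample,
    SummaryStats,
    ash_density,
    box_stats,
    kde_density,
    nrd0_bandwidth,
    summary_se,
)

__all__ = [
    "PlotConfig",
    "compose_raincloud",
    "compose_grouped",
    "add_mean_ci_overlay",
    "compose_facets",
    "compose_barplot",
]


@dataclass(frozen=True)
class PlotConfig:
    """All user-tunable knobs of a raincloud figure.

    Layout defaults follow the step-by-step R recipe: the cloud is nudged
    +0.2 category units off the tick, the box +0.25, the rain sits at the
    tick (shifted by ``-move`` when the rain should fall below the box),
    jitter width 0.15 and box width 0.1.  ``adjust`` multiplies the nrd0
    bandwidth; an explicit ``bandwidth_override`` wins over the rule.
    """

    orientation: str = "v"
    adjust: float = 1.0
    bandwidth_override: float | None = None
    cut: float = 3.0
    trim: bool = False
    density_method: str = "kde"  # or "ash"
    ash_shifts: int = 32
    cloud_width: float = 0.4
    cloud_offset: float = 0.2
    cloud_side: int = 1
    rain_width: float = 0.15
    jitter_height: float = 0.0
    move: float = 0.0
    box_on: bool = True
    box_width: float = 0.1
    box_offset: float = 0.25
    whisker_k: float = 1.5
    show_outliers: bool = False
    dodge: bool = False
    dodge_amount: float = 0.3
    alpha: float = 0.65
    pointplot: bool = False
    pointplot_stat: str = "mean"  # or "median"
    scale_mode: str = "width"
    palette: str = "default"
    seed: int = 42

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        for name in ("cloud_width", "rain_width", "box_width"):
            if getattr(self, name) < 0 or (name != "rain_width" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.density_method not in ("kde", "ash"):
            raise ValueError("density_method must be 'kde' or 'ash'")
        if self.orientation not in ("v", "h"):
            raise ValueError("orientation must be 'v' or 'h'")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _levels(series: pd.Series) -> list:
    """Category levels in first-appearance order (Categorical order wins)."""
    if isinstance(series.dtype, pd.CategoricalDtype):
        present = set(series.dropna().unique().tolist())
        return [lv for lv in series.cat.categories if lv in present]
    return list(pd.unique(series.dropna()))


def _rule_bandwidth(sample: Sample) -> float:
    if sample.n >= 2:
        return nrd0_bandwidth(sample)
    # single observation: the spread rule is undefined; use the same
    # fallback scale the rule itself ends at
    return 0.9 * (abs(float(sample.values[0])) or 1.0)


def _density(sample: Sample, config: PlotConfig):
    if config.density_method == "ash":
        bw = config.bandwidth_override
        if bw is None:
            bw = _rule_bandwidth(sample) * config.adjust * 2.0  # bin width ~ 2h
        return ash_density(sample, bw, config.ash_shifts)
    bw = config.bandwidth_override
    if bw is None:
        bw = _rule_bandwidth(sample) * config.adjust
    return kde_density(sample, bw, cut=config.cut, trim=config.trim)


def _cell_seed(base: int, *indices: int) -> int:
    # distinct, reproducible per-cell jitter streams below 2**31
    s = base
    for i in indices:
        s = (s * 1_000_003 + i + 1) % (2**31 - 1)
    return s


def _cell_layers(
    values: np.ndarray,
    center: float,
    config: PlotConfig,
    color: str,
    label: tuple,
    cell_seed: int,
):
    """Cloud, rain and (optionally) box primitives for one cell.

    Returns three lists so the caller can enforce the cloud -> rain -> box
    draw order across cells.
    """
    sample = Sample(values)
    curve = _density(sample, config)
    cloud = build_half_violin(
        curve,
        center + config.cloud_offset,
        config.cloud_width,
        side=config.cloud_side,
        scale_mode="width",
        color=color,
        alpha=config.alpha,
        label=label,
    )
    rain = jitter_points(
        sample,
        center - config.move,
        config.rain_width,
        seed=cell_seed,
        height=config.jitter_height,
        color=color,
        alpha=min(1.0, config.alpha + 0.2),
        label=label,
    )
    boxes = []
    if config.box_on:
        bs = box_stats(sample, config.whisker_k)
        boxes.append(
            BoxGlyph(
                center=center + config.box_offset,
                width=config.box_width,
                q1=bs.q1,
                median=bs.median,
                q3=bs.q3,
                whisker_lo=bs.whisker_lo,
                whisker_hi=bs.whisker_hi,
                outliers=bs.outliers,
                show_outliers=config.show_outliers,
                fill=color,
                alpha=config.alpha,
                label=label,
            )
        )
    return [cloud], [rain], boxes


def _value_range(primitives) -> tuple:
    lo, hi = np.inf, -np.inf
    for p in primitives:
        if isinstance(p, (PointSet,)) and len(p):
            lo, hi = min(lo, p.values.min()), max(hi, p.values.max())
        elif hasattr(p, "values") and np.size(getattr(p, "values")) > 0:
            lo, hi = min(lo, np.min(p.values)), max(hi, np.max(p.values))
        elif isinstance(p, BoxGlyph):
            lo, hi = min(lo, p.whisker_lo), max(hi, p.whisker_hi)
        elif isinstance(p, ErrorBar):
            lo, hi = min(lo, p.lo), max(hi, p.hi)
        elif isinstance(p, (Marker,)):
            lo, hi = min(lo, p.value), max(hi, p.value)
        elif isinstance(p, Bar):
            lo, hi = min(lo, 0.0, p.value), max(hi, 0.0, p.value)
        elif isinstance(p, Segment):
            lo = min(lo, p.p0[1], p.p1[1])
            hi = max(hi, p.p0[1], p.p1[1])
    if not np.isfinite(lo):
        return (0.0, 1.0)
    return (float(lo), float(hi))


def _check_table(table: pd.DataFrame, cols) -> None:
    if table is None or len(table) == 0:
        raise ValueError("input table is empty")
    for c in cols:
        if c is not None and c not in table.columns:
            raise KeyError(f"column {c!r} not in table; available: {list(table.columns)}")


def compose_raincloud(
    table: pd.DataFrame, x: str, y: str, config: PlotConfig | None = None
) -> FigureScene:
    """Single-factor raincloud: one cloud + rain (+ box) per level of ``x``.

    Level k (first-appearance order) sits at position k; clouds are drawn
    first, then rain, then boxes, so the summary overplots the raw layers.
    """
    config = config or PlotConfig()
    _check_table(table, [x, y])
    levels = _levels(table[x])
    if not levels:
        raise ValueError(f"column {x!r} has no non-missing levels")
    clouds, rains, boxes = [], [], []
    for k, level in enumerate(levels):
        vals = pd.to_numeric(
            table.loc[table[x] == level, y], errors="coerce"
        ).dropna().to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"level {level!r} of {x!r} has no observations")
        color = palettes.color_for(config.palette, k)
        c, r, b = _cell_layers(
            vals, k + 1.0, config, color, (str(level),), _cell_seed(config.seed, k)
        )
        clouds += c
        rains += r
        boxes += b
    prims = clouds + rains + boxes
    scene = FigureScene(
        primitives=prims,
        orientation=config.orientation,
        category_labels=tuple(str(lv) for lv in levels),
        category_positions=tuple(float(k + 1) for k in range(len(levels))),
        value_range=_value_range(prims),
        value_label=y,
        position_label=x,
        seed=config.seed,
        config=config.to_dict(),
    )
    return scene


def compose_grouped(
    table: pd.DataFrame,
    x: str,
    y: str,
    hue: str,
    config: PlotConfig | None = None,
) -> FigureScene:
    """Two-factor raincloud: one cell per (x level, hue level).

    With ``dodge`` the hue levels shift symmetrically around the tick by
    ``dodge_amount``; otherwise they overplot at the shared position with the
    configured alpha.  ``pointplot`` adds a mean (or median) marker per cell
    and line segments joining adjacent x levels within each hue level.
    """
    config = config or PlotConfig()
    _check_table(table, [x, y, hue])
    x_levels = _levels(table[x])
    hue_levels = _levels(table[hue])
    if not x_levels or not hue_levels:
        raise ValueError("x and hue must each have at least one level")
    offs = (
        dodge_offsets(len(hue_levels), config.dodge_amount)
        if config.dodge
        else np.zeros(len(hue_levels))
    )
    clouds, rains, boxes, overlays = [], [], [], []
    stat_fn = np.mean if config.pointplot_stat == "mean" else np.median
    cell_stat = {}
    for j, hv in enumerate(hue_levels):
        color = palettes.color_for(config.palette, j)
        for k, xv in enumerate(x_levels):
            mask = (table[x] == xv) & (table[hue] == hv)
            vals = pd.to_numeric(table.loc[mask, y], errors="coerce").dropna().to_numpy(float)
            if vals.size == 0:
                raise ValueError(f"cell ({x}={xv!r}, {hue}={hv!r}) has no observations")
            center = k + 1.0 + offs[j]
            c, r, b = _cell_layers(
                vals,
                center,
                config,
                color,
                (str(xv), str(hv)),
                _cell_seed(config.seed, k, j),
            )
            clouds += c
            rains += r
            boxes += b
            cell_stat[(k, j)] = (center, float(stat_fn(vals)))
    if config.pointplot:
        for j, hv in enumerate(hue_levels):
            color = palettes.color_for(config.palette, j)
            for k in range(len(x_levels) - 1):
                overlays.append(
                    Segment(
                        cell_stat[(k, j)],
                        cell_stat[(k + 1, j)],
                        color=color,
                        label=(str(hv),),
                    )
                )
            for k, xv in enumerate(x_levels):
                pos, m = cell_stat[(k, j)]
                overlays.append(
                    Marker(pos, m, color=color, label=(str(xv), str(hv)))
                )
    prims = clouds + rains + boxes + overlays
    return FigureScene(
        primitives=prims,
        orientation=config.orientation,
        category_labels=tuple(str(lv) for lv in x_levels),
        category_positions=tuple(float(k + 1) for k in range(len(x_levels))),
        value_range=_value_range(prims),
        value_label=y,
        position_label=x,
        seed=config.seed,
        config=config.to_dict(),
    )


def add_mean_ci_overlay(
    scene: FigureScene, stats: list[SummaryStats], offset: Offset | None = None
) -> FigureScene:
    """Append a mean marker and a t-CI error bar per category.

    ``stats`` must carry one row per scene category, in category order (as
    returned by :func:`raincloudpy.stats.summary_se` on the same table).
    """
    offset = offset or Offset(0.0, 0.0)
    if len(stats) != len(scene.category_positions):
        raise ValueError(
            f"need one stats row per category: got {len(stats)} rows for "
            f"{len(scene.category_positions)} categories"
        )
    extra = []
    for pos, row in zip(scene.category_positions, stats):
        p = pos + offset.d_position
        m = row.mean + offset.d_value
        extra.append(Marker(p, m, color="#000000", label=row.group_labels))
        extra.append(
            ErrorBar(p, m, row.ci, color="#000000", label=row.group_labels)
        )
    prims = list(scene.primitives) + extra
    return replace(
        scene, primitives=tuple(prims), value_range=_value_range(prims)
    )


def compose_facets(
    table: pd.DataFrame,
    x: str,
    y: str,
    facet: str,
    config: PlotConfig | None = None,
) -> list[FigureScene]:
    """One raincloud panel per facet level, with a shared value-axis range."""
    config = config or PlotConfig()
    _check_table(table, [x, y, facet])
    facet_levels = _levels(table[facet])
    scenes = []
    for lv in facet_levels:
        sub = table.loc[table[facet] == lv]
        scene = compose_raincloud(sub, x, y, config)
        scenes.append(replace(scene, title=str(lv)))
    lo = min(s.value_range[0] for s in scenes)
    hi = max(s.value_range[1] for s in scenes)
    return [replace(s, value_range=(lo, hi)) for s in scenes]


def compose_barplot(
    stats: list[SummaryStats],
    error: str = "se",
    bar_width: float = 0.8,
    palette: str = "default",
) -> FigureScene:
    """The comparison figure: one bar (0 to mean) +/- se or ci per group."""
    if not stats:
        raise ValueError("stats must be non-empty")
    if error not in ("se", "ci"):
        raise ValueError("error must be 'se' or 'ci'")
    bars, ebars = [], []
    for k, row in enumerate(stats):
        color = palettes.color_for(palette, k)
        pos = k + 1.0
        bars.append(Bar(pos, row.mean, bar_width, color=color, label=row.group_labels))
        half = row.se if error == "se" else row.ci
        ebars.append(ErrorBar(pos, row.mean, half, label=row.group_labels))
    prims = bars + ebars
    return FigureScene(
        primitives=prims,
        orientation="v",
        category_labels=tuple("/".join(map(str, r.group_labels)) for r in stats),
        category_positions=tuple(float(k + 1) for k in range(len(stats))),
        value_range=_value_range(prims),
        config={"error": error, "bar_width": bar_width, "palette": palette},
    )
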