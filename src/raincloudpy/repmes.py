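"""Repeated-measures rainclouds: linked 1x1 / 2x2 designs and the stacked
factorial ("rm") variant.

The linked designs place each experimental arm at an integer tick, jitter
every observation's position once (seeded), and connect each subject's paired
observations with a line through the very coordinates its rain points use.
The stacked factorial variant lays T timepoint bands along the position axis,
overlays the G group densities in each band, and threads each group's cell
means across bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import palettes
from .compose import PlotConfig, _cell_seed, _density, _value_range
from .geometry import build_half_violin, jitter_points
from .scene import BoxGlyph, FigureScene, Marker, PointSet, Segment
from .stats import Sample, box_stats

__all__ = [
    "RepMesTable",
    "CellGrid",
    "make_data_1x1",
    "make_data_2x2",
    "compose_linked_raincloud",
    "compose_rm_raincloud",
]


@dataclass(frozen=True)
class RepMesTable:
    """Long-format paired data with precomputed jittered x coordinates.

    Each row is one observation: ``subject_id`` (0-based within the design),
    ``arm`` (1..n_arms), ``value``, the arm's tick position ``x_tick`` and
    the jittered position ``x_jit`` with ``|x_jit - x_tick| <= jit_distance/2``.
    ``linked_pairs`` lists the (arm, arm) pairs whose subject observations
    get connecting lines.
    """

    frame: pd.DataFrame
    jit_distance: float
    jit_seed: int
    labels: tuple = ()
    linked_pairs: tuple = ((1, 2),)

    @property
    def n_arms(self) -> int:
        return int(self.frame["arm"].max())

    @property
    def n_subjects(self) -> int:
        return int(self.frame["subject_id"].nunique())

    def arm(self, a: int) -> pd.DataFrame:
        return self.frame.loc[self.frame["arm"] == a]


def _jittered_table(
    arrays: list[np.ndarray],
    ticks: list[float],
    jit_distance: float,
    jit_seed: int,
) -> pd.DataFrame:
    if jit_distance < 0:
        raise ValueError("jit_distance must be nonnegative")
    n = arrays[0].size
    rng = np.random.default_rng(jit_seed)
    rows = []
    for arm_idx, (arr, tick) in enumerate(zip(arrays, ticks), start=1):
        if jit_distance > 0:
            jit = rng.uniform(-jit_distance / 2.0, jit_distance / 2.0, n)
        else:
            jit = np.zeros(n)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": np.arange(n),
                    "arm": arm_idx,
                    "value": arr,
                    "x_tick": float(tick),
                    "x_jit": tick + jit,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def make_data_1x1(
    array_1,
    array_2,
    jit_distance: float = 0.09,
    jit_seed: int = 321,
    labels: tuple = ("pre", "post"),
) -> RepMesTable:
    """Two paired arms at ticks 1 and 2; subject i links the i-th entries."""
    a1 = np.asarray(array_1, float).ravel()
    a2 = np.asarray(array_2, float).ravel()
    if a1.size != a2.size:
        raise ValueError(f"paired arrays differ in length: {a1.size} vs {a2.size}")
    if a1.size < 1:
        raise ValueError("paired arrays must be non-empty")
    frame = _jittered_table([a1, a2], [1.0, 2.0], jit_distance, jit_seed)
    return RepMesTable(frame, jit_distance, jit_seed, tuple(labels), ((1, 2),))


def make_data_2x2(
    array_1,
    array_2,
    array_3,
    array_4,
    labels: tuple = ("condition 1", "condition 2"),
    jit_distance: float = 0.09,
    jit_seed: int = 321,
    spread_x_ticks: bool = True,
) -> RepMesTable:
    """Four paired arms: (pre, post) for each of two conditions.

    With ``spread_x_ticks`` the arms occupy ticks 1..4 and subjects are
    linked within each condition's pre/post pair (arms 1-2 and 3-4); without
    it the two conditions share ticks 1 and 2 and are overlaid, still linked
    within condition only.
    """
    arrays = [np.asarray(a, float).ravel() for a in (array_1, array_2, array_3, array_4)]
    sizes = {a.size for a in arrays}
    if len(sizes) != 1:
        raise ValueError(f"all four arrays must share one length, got {sorted(sizes)}")
    if arrays[0].size < 1:
        raise ValueError("arrays must be non-empty")
    ticks = [1.0, 2.0, 3.0, 4.0] if spread_x_ticks else [1.0, 2.0, 1.0, 2.0]
    frame = _jittered_table(arrays, ticks, jit_distance, jit_seed)
    return RepMesTable(
        frame, jit_distance, jit_seed, tuple(labels), ((1, 2), (3, 4))
    )


@dataclass(frozen=True)
class CellGrid:
    """T x G grid of samples for the stacked factorial raincloud."""

    samples: tuple  # tuple of T rows, each a tuple of G Sample
    group_labels: tuple = ()
    time_labels: tuple = ()

    def __post_init__(self):
        rows = tuple(tuple(r) for r in self.samples)
        if not rows or not rows[0]:
            raise ValueError("CellGrid needs at least one cell")
        g = len(rows[0])
        if any(len(r) != g for r in rows):
            raise ValueError("all timepoints must have the same number of groups")
        norm = tuple(
            tuple(c if isinstance(c, Sample) else Sample(c) for c in r) for r in rows
        )
        object.__setattr__(self, "samples", norm)

    @property
    def n_times(self) -> int:
        return len(self.samples)

    @property
    def n_groups(self) -> int:
        return len(self.samples[0])

    @classmethod
    def from_long(
        cls, table: pd.DataFrame, measure: str, time: str, group: str
    ) -> "CellGrid":
        times = list(pd.unique(table[time].dropna()))
        groups = list(pd.unique(table[group].dropna()))
        rows = []
        for t in times:
            row = []
            for g in groups:
                vals = pd.to_numeric(
                    table.loc[(table[time] == t) & (table[group] == g), measure],
                    errors="coerce",
                ).dropna().to_numpy(float)
                if vals.size == 0:
                    raise ValueError(f"cell ({time}={t!r}, {group}={g!r}) is empty")
                row.append(Sample(vals))
            rows.append(tuple(row))
        return cls(tuple(rows), tuple(map(str, groups)), tuple(map(str, times)))


def compose_linked_raincloud(
    data: RepMesTable,
    config: PlotConfig | None = None,
    align_clouds: bool = False,
) -> FigureScene:
    """Linked repeated-measures raincloud from a :class:`RepMesTable`.

    Per arm: a half-violin and the rain at its precomputed jittered
    coordinates (plus a box glyph when configured); beneath the points, one
    line per subject per linked pair connecting exactly the rain
    coordinates.  For the two-arm design the clouds face outward (arm 1
    left, arm 2 right) unless ``align_clouds`` makes them all face right.
    """
    config = config or PlotConfig()
    if data.n_subjects == 0:
        raise ValueError("no subjects in the design")
    n_arms = data.n_arms
    clouds, boxes, rains, links = [], [], [], []
    tick_of_arm = {}
    for a in range(1, n_arms + 1):
        sub = data.arm(a)
        tick = float(sub["x_tick"].iloc[0])
        tick_of_arm[a] = tick
        vals = sub["value"].to_numpy(float)
        sample = Sample(vals)
        color = palettes.color_for(config.palette, a - 1)
        if align_clouds or n_arms != 2:
            side = 1
        else:
            side = -1 if a == 1 else 1
        curve = _density(sample, config)
        clouds.append(
            build_half_violin(
                curve,
                tick + side * config.cloud_offset,
                config.cloud_width,
                side=side,
                color=color,
                alpha=config.alpha,
                label=(str(a),),
            )
        )
        rains.append(
            PointSet(
                sub["x_jit"].to_numpy(float),
                vals,
                color=color,
                alpha=min(1.0, config.alpha + 0.2),
                label=(str(a),),
            )
        )
        if config.box_on:
            bs = box_stats(sample, config.whisker_k)
            boxes.append(
                BoxGlyph(
                    center=tick + side * config.box_offset,
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
                    label=(str(a),),
                )
            )
    for a, b in data.linked_pairs:
        left = data.arm(a).set_index("subject_id")
        right = data.arm(b).set_index("subject_id")
        common = left.index.intersection(right.index)
        if len(common) == 0:
            raise ValueError(f"arms {a} and {b} share no subjects")
        for sid in common:
            links.append(
                Segment(
                    (float(left.loc[sid, "x_jit"]), float(left.loc[sid, "value"])),
                    (float(right.loc[sid, "x_jit"]), float(right.loc[sid, "value"])),
                    color="#999999",
                    alpha=0.5,
                    label=(str(sid),),
                )
            )
    prims = clouds + links + rains + boxes
    ticks = sorted(set(tick_of_arm.values()))
    labels = tuple(data.labels) if data.labels else tuple(str(t) for t in ticks)
    return FigureScene(
        primitives=prims,
        orientation=config.orientation,
        category_labels=labels,
        category_positions=tuple(ticks),
        value_range=_value_range(prims),
        seed=data.jit_seed,
        config=config.to_dict(),
    )


def compose_rm_raincloud(
    cells: CellGrid, config: PlotConfig | None = None
) -> FigureScene:
    """Stacked factorial raincloud: one band per timepoint, groups overlaid.

    Bands sit at integer positions 1..T along the (horizontal) position axis;
    density height within a band is rescaled so the tallest cloud spans 0.8
    band spacings, keeping neighbours from overlapping.  One mean marker per
    cell, and per group a polyline of T-1 segments threading its cell means
    across bands.
    """
    config = config or PlotConfig()
    T, G = cells.n_times, cells.n_groups
    clouds, rains, markers, lines = [], [], [], []
    curves = [[_density(s, config) for s in row] for row in cells.samples]
    peak = max(float(np.max(c.density)) for row in curves for c in row)
    cell_mean = {}
    for t in range(T):
        for g in range(G):
            sample = cells.samples[t][g]
            color = palettes.color_for(config.palette, g)
            center = t + 1.0
            clouds.append(
                build_half_violin(
                    curves[t][g],
                    center,
                    0.8,
                    side=1,
                    scale_mode="area",
                    sibling_max=peak,
                    color=color,
                    alpha=config.alpha,
                    label=(str(t + 1), str(g + 1)),
                )
            )
            rains.append(
                jitter_points(
                    sample,
                    center - 0.15,
                    config.rain_width,
                    seed=_cell_seed(config.seed, t, g),
                    color=color,
                    alpha=min(1.0, config.alpha + 0.2),
                    label=(str(t + 1), str(g + 1)),
                )
            )
            m = float(sample.values.mean())
            cell_mean[(t, g)] = m
            markers.append(
                Marker(center, m, color=color, label=(str(t + 1), str(g + 1)))
            )
    for g in range(G):
        color = palettes.color_for(config.palette, g)
        for t in range(T - 1):
            lines.append(
                Segment(
                    (t + 1.0, cell_mean[(t, g)]),
                    (t + 2.0, cell_mean[(t + 1, g)]),
                    color=color,
                    label=(str(g + 1),),
                )
            )
    prims = clouds + rains + lines + markers
    labels = cells.time_labels or tuple(str(t + 1) for t in range(T))
    return FigureScene(
        primitives=prims,
        orientation="h",
        category_labels=tuple(labels),
        category_positions=tuple(float(t + 1) for t in range(T)),
        value_range=_value_range(prims),
        seed=config.seed,
        config=config.to_dict(),
    )
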