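"""File I/O: long-format CSV reading and deterministic SVG scene rendering.

The SVG writer is the reference renderer: each scene primitive maps to a
fixed element structure (polygon -> ``path``, point set -> a group of
``circle`` elements, box glyph -> a ``g`` of rects/lines, ...), coordinates
go through one linear transform that is recorded in the root element's
``data-*`` attributes so tests can invert it, and identical scenes always
produce identical bytes.  PNG export delegates to matplotlib and is not
byte-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .scene import (
    Bar,
    BoxGlyph,
    ErrorBar,
    FigureScene,
    Marker,
    PointSet,
    Polygon,
    Segment,
    Text,
)

logger = logging.getLogger(__name__)

__all__ = ["ColumnMap", "read_long_table", "write_scene_svg", "render_png"]


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from semantic roles to CSV column names.

    ``measure`` plus at least one of ``group``/``time`` must be present.
    ``has_header=None`` auto-detects a header row (a file is considered
    headed when the measure name appears on its first line).  For headerless
    files, ``names`` assigns column names positionally, in file order.
    """

    measure: str
    group: str | None = None
    hue: str | None = None
    subject: str | None = None
    time: str | None = None
    facet: str | None = None
    has_header: bool | None = None
    names: tuple | None = None

    def __post_init__(self):
        if self.group is None and self.time is None:
            raise ValueError("ColumnMap needs at least one of group/time")

    def mapped(self) -> list[str]:
        cols = [self.measure, self.group, self.hue, self.subject, self.time, self.facet]
        return [c for c in cols if c is not None]


def read_long_table(path, cmap: ColumnMap) -> pd.DataFrame:
    """Read a long-format CSV into a typed table.

    Categorical columns become ordered categoricals in first-appearance
    order; rows whose measure is missing are dropped (and counted in the
    log); a measure cell that is present but not numeric raises with its
    1-based file line number.
    """
    header_fields = list(pd.read_csv(path, nrows=0).columns)
    has_header = cmap.has_header
    if has_header is None:
        # headed unless positional names are supplied and the measure name is
        # absent from the first line
        has_header = cmap.names is None or cmap.measure in header_fields
    if has_header:
        table = pd.read_csv(path)
        first_data_line = 2
    else:
        if cmap.names is None:
            raise ValueError("headerless file needs ColumnMap.names (positional)")
        table = pd.read_csv(path, header=None, names=list(cmap.names))
        first_data_line = 1
    missing = [c for c in cmap.mapped() if c not in table.columns]
    if missing:
        raise KeyError(
            f"mapped column(s) {missing} not found; available: {list(table.columns)}"
        )
    raw = table[cmap.measure]
    numeric = pd.to_numeric(raw, errors="coerce")
    bad = numeric.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        idx = int(bad.idxmax())
        raise ValueError(
            f"non-numeric measure value {raw[idx]!r} in column "
            f"{cmap.measure!r} at line {idx + first_data_line}"
        )
    table[cmap.measure] = numeric
    n_missing = int(numeric.isna().sum())
    if n_missing:
        logger.info("dropped %d row(s) with missing %r", n_missing, cmap.measure)
        table = table.loc[numeric.notna()].reset_index(drop=True)
    for role in ("group", "hue", "subject", "time", "facet"):
        col = getattr(cmap, role)
        if col is not None:
            levels = list(pd.unique(table[col].dropna()))
            table[col] = pd.Categorical(table[col], categories=levels, ordered=True)
    return table


# ---------------------------------------------------------------------------
# SVG rendering


def _fmt(v: float) -> str:
    return f"{float(v):.4f}"


class _Canvas:
    """Linear map from scene coordinates to pixels (value axis up)."""

    def __init__(self, scene: FigureScene, width: int, height: int, margin: float):
        p_lo, p_hi = scene.position_range()
        v_lo, v_hi = scene.value_range
        p_pad = 0.05 * (p_hi - p_lo) or 0.5
        v_pad = 0.05 * (v_hi - v_lo) or 0.5
        p_lo, p_hi = p_lo - p_pad, p_hi + p_pad
        v_lo, v_hi = v_lo - v_pad, v_hi + v_pad
        # after orientation, x-data is position (v) or value (h)
        if scene.orientation == "v":
            self.x0, self.x1, self.y0, self.y1 = p_lo, p_hi, v_lo, v_hi
        else:
            self.x0, self.x1, self.y0, self.y1 = v_lo, v_hi, p_lo, p_hi
        self.width, self.height, self.margin = width, height, margin
        self.sx = (width - 2 * margin) / (self.x1 - self.x0)
        self.sy = (height - 2 * margin) / (self.y1 - self.y0)
        self.scene = scene

    def xy(self, position: float, value: float) -> tuple:
        cx, cy = self.scene.canvas_xy(position, value)
        px = self.margin + (cx - self.x0) * self.sx
        py = self.height - self.margin - (cy - self.y0) * self.sy
        return px, py

    def meta(self) -> dict:
        return {
            "data-orientation": self.scene.orientation,
            "data-x0": _fmt(self.x0),
            "data-y0": _fmt(self.y0),
            "data-sx": _fmt(self.sx),
            "data-sy": _fmt(self.sy),
            "data-margin": _fmt(self.margin),
        }


def _svg_polygon(p: Polygon, cv: _Canvas) -> str:
    pts = [cv.xy(a, b) for a, b in zip(p.positions, p.values)]
    d = "M " + " L ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts) + " Z"
    return (
        f'<path class="polygon" d="{d}" fill="{p.color}" '
        f'fill-opacity="{_fmt(p.alpha)}" stroke="none"/>'
    )


def _svg_pointset(p: PointSet, cv: _Canvas) -> str:
    circles = []
    for a, b in zip(p.positions, p.values):
        x, y = cv.xy(a, b)
        circles.append(
            f'<circle cx="{_fmt(x)}" cy="{_fmt(y)}" r="{_fmt(p.size)}" '
            f'fill="{p.color}" fill-opacity="{_fmt(p.alpha)}"/>'
        )
    return '<g class="point-set">' + "".join(circles) + "</g>"


def _svg_line(x0, y0, x1, y1, color, alpha, width=1.0, cls=None) -> str:
    cls_attr = f' class="{cls}"' if cls else ""
    return (
        f'<line{cls_attr} x1="{_fmt(x0)}" y1="{_fmt(y0)}" x2="{_fmt(x1)}" '
        f'y2="{_fmt(y1)}" stroke="{color}" stroke-opacity="{_fmt(alpha)}" '
        f'stroke-width="{_fmt(width)}"/>'
    )


def _svg_segment(s: Segment, cv: _Canvas) -> str:
    x0, y0 = cv.xy(*s.p0)
    x1, y1 = cv.xy(*s.p1)
    return _svg_line(x0, y0, x1, y1, s.color, s.alpha, s.width, cls="segment")


def _svg_box(b: BoxGlyph, cv: _Canvas) -> str:
    half = b.width / 2.0
    x_lo, y_q1 = cv.xy(b.center - half, b.q1)
    x_hi, y_q3 = cv.xy(b.center + half, b.q3)
    xs = sorted((x_lo, x_hi))
    ys = sorted((y_q3, y_q1))
    parts = [
        f'<rect x="{_fmt(xs[0])}" y="{_fmt(ys[0])}" '
        f'width="{_fmt(xs[1] - xs[0])}" height="{_fmt(ys[1] - ys[0])}" '
        f'fill="{b.fill}" fill-opacity="{_fmt(b.alpha)}" stroke="{b.color}"/>'
    ]
    mx0, my = cv.xy(b.center - half, b.median)
    mx1, _ = cv.xy(b.center + half, b.median)
    parts.append(_svg_line(mx0, my, mx1, my, b.color, 1.0, 1.5))
    for q, w in ((b.q3, b.whisker_hi), (b.q1, b.whisker_lo)):
        wx0, wy0 = cv.xy(b.center, q)
        wx1, wy1 = cv.xy(b.center, w)
        parts.append(_svg_line(wx0, wy0, wx1, wy1, b.color, 1.0))
    if b.show_outliers:
        for o in b.outliers:
            ox, oy = cv.xy(b.center, float(o))
            parts.append(
                f'<circle cx="{_fmt(ox)}" cy="{_fmt(oy)}" r="2.0000" '
                f'fill="none" stroke="{b.color}"/>'
            )
    return '<g class="box-glyph">' + "".join(parts) + "</g>"


def _svg_errorbar(e: ErrorBar, cv: _Canvas) -> str:
    x0, y0 = cv.xy(e.position, e.lo)
    x1, y1 = cv.xy(e.position, e.hi)
    cap = e.cap / 2.0
    cl0 = cv.xy(e.position - cap, e.lo)
    cl1 = cv.xy(e.position + cap, e.lo)
    ch0 = cv.xy(e.position - cap, e.hi)
    ch1 = cv.xy(e.position + cap, e.hi)
    parts = [
        _svg_line(x0, y0, x1, y1, e.color, e.alpha, 1.5),
        _svg_line(*cl0, *cl1, e.color, e.alpha),
        _svg_line(*ch0, *ch1, e.color, e.alpha),
    ]
    return '<g class="error-bar">' + "".join(parts) + "</g>"


def _svg_marker(m: Marker, cv: _Canvas) -> str:
    x, y = cv.xy(m.position, m.value)
    s = m.size
    d = (
        f"M {_fmt(x)},{_fmt(y - s)} L {_fmt(x + s)},{_fmt(y)} "
        f"L {_fmt(x)},{_fmt(y + s)} L {_fmt(x - s)},{_fmt(y)} Z"
    )
    return (
        f'<path class="marker" d="{d}" fill="{m.color}" '
        f'fill-opacity="{_fmt(m.alpha)}"/>'
    )


def _svg_bar(b: Bar, cv: _Canvas) -> str:
    half = b.width / 2.0
    x0, y_base = cv.xy(b.position - half, 0.0)
    x1, y_val = cv.xy(b.position + half, b.value)
    xs = sorted((x0, x1))
    ys = sorted((y_base, y_val))
    return (
        f'<rect class="bar" x="{_fmt(xs[0])}" y="{_fmt(ys[0])}" '
        f'width="{_fmt(xs[1] - xs[0])}" height="{_fmt(ys[1] - ys[0])}" '
        f'fill="{b.color}" fill-opacity="{_fmt(b.alpha)}"/>'
    )


def _svg_text(t: Text, cv: _Canvas) -> str:
    x, y = cv.xy(t.position, t.value)
    return (
        f'<text x="{_fmt(x)}" y="{_fmt(y)}" fill="{t.color}" '
        f'font-size="12">{escape(t.text)}</text>'
    )


_RENDERERS = {
    Polygon: _svg_polygon,
    PointSet: _svg_pointset,
    Segment: _svg_segment,
    BoxGlyph: _svg_box,
    ErrorBar: _svg_errorbar,
    Marker: _svg_marker,
    Bar: _svg_bar,
    Text: _svg_text,
}


def scene_to_svg(
    scene: FigureScene, width: int = 640, height: int = 480, margin: float = 50.0
) -> str:
    """Render a scene to a standalone SVG 1.1 document string."""
    cv = _Canvas(scene, width, height, margin)
    meta = " ".join(f'{k}="{v}"' for k, v in cv.meta().items())
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}" {meta}>',
        f'<rect class="background" x="0" y="0" width="{width}" '
        f'height="{height}" fill="#ffffff"/>',
    ]
    # axes frame
    parts.append(
        _svg_line(margin, margin, margin, height - margin, "#000000", 1.0, cls="axis")
    )
    parts.append(
        _svg_line(
            margin,
            height - margin,
            width - margin,
            height - margin,
            "#000000",
            1.0,
            cls="axis",
        )
    )
    for prim in scene.primitives:
        parts.append(_RENDERERS[type(prim)](prim, cv))
    if scene.title:
        parts.append(
            f'<text class="title" x="{_fmt(width / 2)}" y="{_fmt(margin / 2)}" '
            f'text-anchor="middle" font-size="14">{escape(scene.title)}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def write_scene_svg(scene: FigureScene, path, **kwargs) -> None:
    """Write a scene to ``path`` as SVG; identical scenes give identical bytes."""
    svg = scene_to_svg(scene, **kwargs)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(svg)


def render_png(scene: FigureScene, path, dpi: int = 100) -> None:
    """Rasterize a scene through matplotlib (not byte-stable)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    fig, ax = plt.subplots(figsize=(6.4, 4.8), dpi=dpi)
    for prim in scene.primitives:
        if isinstance(prim, Polygon):
            xy = [scene.canvas_xy(a, b) for a, b in zip(prim.positions, prim.values)]
            ax.add_patch(
                MplPolygon(xy, closed=True, facecolor=prim.color, alpha=prim.alpha)
            )
        elif isinstance(prim, PointSet):
            xs, ys = zip(
                *(scene.canvas_xy(a, b) for a, b in zip(prim.positions, prim.values))
            )
            ax.scatter(xs, ys, s=prim.size**2, c=prim.color, alpha=prim.alpha)
        elif isinstance(prim, Segment):
            (x0, y0), (x1, y1) = scene.canvas_xy(*prim.p0), scene.canvas_xy(*prim.p1)
            ax.plot([x0, x1], [y0, y1], color=prim.color, alpha=prim.alpha)
        elif isinstance(prim, BoxGlyph):
            x0, yq1 = scene.canvas_xy(prim.center - prim.width / 2, prim.q1)
            x1, yq3 = scene.canvas_xy(prim.center + prim.width / 2, prim.q3)
            ax.plot([x0, x1, x1, x0, x0], [yq1, yq1, yq3, yq3, yq1], color=prim.color)
            mx0, my = scene.canvas_xy(prim.center - prim.width / 2, prim.median)
            mx1, _ = scene.canvas_xy(prim.center + prim.width / 2, prim.median)
            ax.plot([mx0, mx1], [my, my], color=prim.color)
        elif isinstance(prim, ErrorBar):
            x0, lo = scene.canvas_xy(prim.position, prim.lo)
            _, hi = scene.canvas_xy(prim.position, prim.hi)
            if scene.orientation == "v":
                ax.plot([x0, x0], [lo, hi], color=prim.color)
            else:
                ax.plot([lo, hi], [x0, x0], color=prim.color)
        elif isinstance(prim, Marker):
            x, y = scene.canvas_xy(prim.position, prim.value)
            ax.scatter([x], [y], marker="D", c=prim.color, s=prim.size**2)
        elif isinstance(prim, Bar):
            if scene.orientation == "v":
                ax.bar(prim.position, prim.value, prim.width, color=prim.color)
            else:
                ax.barh(prim.position, prim.value, prim.width, color=prim.color)
        elif isinstance(prim, Text):
            x, y = scene.canvas_xy(prim.position, prim.value)
            ax.text(x, y, prim.text, color=prim.color)
    ax.autoscale_view()
    fig.savefig(path)
    plt.close(fig)
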