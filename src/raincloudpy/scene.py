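"""Backend-agnostic drawing primitives and the figure scene graph.

All primitives live in internal (position, value) coordinates: ``position``
runs along the categorical axis (category k sits at position k, 1-based) and
``value`` along the measure axis.  Orientation ("v" or "h") is metadata that
is applied once, at render time, by :meth:`FigureScene.canvas_xy`; flipping a
scene therefore never touches primitive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Polygon",
    "PointSet",
    "Segment",
    "BoxGlyph",
    "ErrorBar",
    "Marker",
    "Bar",
    "Text",
    "FigureScene",
]


def _arr(a) -> np.ndarray:
    return np.asarray(a, dtype=float)


@dataclass(frozen=True)
class Polygon:
    """Filled polygon (half-violin outline) as (position, value) vertex pairs."""

    positions: np.ndarray
    values: np.ndarray
    color: str = "#808080"
    alpha: float = 1.0
    label: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "positions", _arr(self.positions))
        object.__setattr__(self, "values", _arr(self.values))

    def translated(self, d_position: float, d_value: float) -> "Polygon":
        return replace(
            self, positions=self.positions + d_position, values=self.values + d_value
        )


@dataclass(frozen=True)
class PointSet:
    """A set of raw-data markers (the rain), one point per observation."""

    positions: np.ndarray
    values: np.ndarray
    color: str = "#404040"
    alpha: float = 1.0
    size: float = 2.0
    label: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "positions", _arr(self.positions))
        object.__setattr__(self, "values", _arr(self.values))

    def __len__(self) -> int:
        return self.positions.size

    def translated(self, d_position: float, d_value: float) -> "PointSet":
        return replace(
            self, positions=self.positions + d_position, values=self.values + d_value
        )


@dataclass(frozen=True)
class Segment:
    """A straight line between two (position, value) endpoints."""

    p0: tuple
    p1: tuple
    color: str = "#404040"
    alpha: float = 1.0
    width: float = 1.0
    label: tuple = ()

    def translated(self, d_position: float, d_value: float) -> "Segment":
        return replace(
            self,
            p0=(self.p0[0] + d_position, self.p0[1] + d_value),
            p1=(self.p1[0] + d_position, self.p1[1] + d_value),
        )


@dataclass(frozen=True)
class BoxGlyph:
    """Boxplot glyph: box from q1 to q3, median line, whiskers, outliers."""

    center: float
    width: float
    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray = field(default_factory=lambda: np.empty(0))
    show_outliers: bool = False
    color: str = "#000000"
    fill: str = "#ffffff"
    alpha: float = 1.0
    label: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "outliers", _arr(self.outliers))

    def translated(self, d_position: float, d_value: float) -> "BoxGlyph":
        return replace(
            self,
            center=self.center + d_position,
            q1=self.q1 + d_value,
            median=self.median + d_value,
            q3=self.q3 + d_value,
            whisker_lo=self.whisker_lo + d_value,
            whisker_hi=self.whisker_hi + d_value,
            outliers=self.outliers + d_value,
        )


@dataclass(frozen=True)
class ErrorBar:
    """Vertical (in value) error bar centered at ``(position, center)``."""

    position: float
    center: float
    halfwidth: float
    cap: float = 0.05
    color: str = "#000000"
    alpha: float = 1.0
    label: tuple = ()

    @property
    def lo(self) -> float:
        return self.center - self.halfwidth

    @property
    def hi(self) -> float:
        return self.center + self.halfwidth

    def translated(self, d_position: float, d_value: float) -> "ErrorBar":
        return replace(
            self, position=self.position + d_position, center=self.center + d_value
        )


@dataclass(frozen=True)
class Marker:
    """A single emphasized point (e.g. a group mean)."""

    position: float
    value: float
    color: str = "#000000"
    alpha: float = 1.0
    size: float = 5.0
    shape: str = "diamond"
    label: tuple = ()

    def translated(self, d_position: float, d_value: float) -> "Marker":
        return replace(
            self, position=self.position + d_position, value=self.value + d_value
        )


@dataclass(frozen=True)
class Bar:
    """A bar from the value baseline (0) to ``value``."""

    position: float
    value: float
    width: float
    color: str = "#808080"
    alpha: float = 1.0
    label: tuple = ()

    def translated(self, d_position: float, d_value: float) -> "Bar":
        return replace(
            self, position=self.position + d_position, value=self.value + d_value
        )


@dataclass(frozen=True)
class Text:
    """An annotation anchored at a (position, value) point."""

    position: float
    value: float
    text: str
    color: str = "#000000"
    alpha: float = 1.0
    label: tuple = ()

    def translated(self, d_position: float, d_value: float) -> "Text":
        return replace(
            self, position=self.position + d_position, value=self.value + d_value
        )


PRIMITIVE_TYPES = (Polygon, PointSet, Segment, BoxGlyph, ErrorBar, Marker, Bar, Text)


@dataclass(frozen=True)
class FigureScene:
    """An ordered list of drawing primitives plus axis metadata.

    Primitives are drawn in list order (later entries overplot earlier ones);
    the composers append cloud, then rain, then box/overlay layers.  The seed
    and config used to build the scene are echoed for reproducibility checks.
    """

    primitives: tuple
    orientation: str = "v"
    category_labels: tuple = ()
    category_positions: tuple = ()
    value_range: tuple = (0.0, 1.0)
    value_label: str = ""
    position_label: str = ""
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    title: str = ""

    def __post_init__(self):
        object.__setattr__(self, "primitives", tuple(self.primitives))
        if self.orientation not in ("v", "h"):
            raise ValueError("orientation must be 'v' or 'h'")

    def canvas_xy(self, position, value):
        """Map internal (position, value) to canvas (x, y) per orientation."""
        if self.orientation == "v":
            return position, value
        return value, position

    def of_type(self, cls) -> list:
        return [p for p in self.primitives if isinstance(p, cls)]

    def count(self, cls) -> int:
        return len(self.of_type(cls))

    def with_primitives(self, primitives) -> "FigureScene":
        return replace(self, primitives=tuple(primitives))

    def position_range(self) -> tuple:
        """Bounding interval of primitive positions (for axis limits)."""
        los, his = [], []
        for p in self.primitives:
            if isinstance(p, (Polygon, PointSet)):
                if p.positions.size:
                    los.append(float(p.positions.min()))
                    his.append(float(p.positions.max()))
            elif isinstance(p, Segment):
                los.append(min(p.p0[0], p.p1[0]))
                his.append(max(p.p0[0], p.p1[0]))
            elif isinstance(p, BoxGlyph):
                los.append(p.center - p.width / 2)
                his.append(p.center + p.width / 2)
            elif isinstance(p, Bar):
                los.append(p.position - p.width / 2)
                his.append(p.position + p.width / 2)
            elif isinstance(p, (ErrorBar, Marker, Text)):
                los.append(p.position)
                his.append(p.position)
        if not los:
            return (0.0, 1.0)
        return (min(los), max(his))
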