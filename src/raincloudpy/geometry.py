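"""Positional geometry: half-violin polygons, seeded jitter, offsets, dodge.

These operations turn statistics into positioned primitives but know nothing
about figure assembly.  All randomness (jitter) is driven by an explicit
integer seed through :class:`numpy.random.Generator`, so identical inputs
yield bitwise-identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .scene import FigureScene, PointSet, Polygon
from .stats import DensityCurve, Sample

__all__ = [
    "Offset",
    "build_half_violin",
    "jitter_points",
    "apply_offset",
    "dodge_offsets",
    "flip_orientation",
]


@dataclass(frozen=True)
class Offset:
    """A rigid translation: ``d_position`` along the category axis,
    ``d_value`` along the measure axis.  Offsets compose additively."""

    d_position: float
    d_value: float = 0.0

    def __add__(self, other: "Offset") -> "Offset":
        return Offset(self.d_position + other.d_position, self.d_value + other.d_value)


def build_half_violin(
    curve: DensityCurve,
    center: float,
    max_width: float,
    side: int = 1,
    scale_mode: str = "width",
    sibling_max: float | None = None,
    **style,
) -> Polygon:
    """Build the one-sided ("flat") violin polygon for a density curve.

    The density is rescaled so its mode reaches ``max_width`` from the
    baseline at ``center`` (scale_mode="width").  With scale_mode="area" the
    caller passes ``sibling_max``, the largest density mode across sibling
    curves, so sibling violins share one scale and their areas stay
    proportional to mass.  ``side`` +1 draws toward increasing positions,
    -1 mirrors.  The first and last vertices sit on the baseline so the
    closed polygon is simple.
    """
    if max_width <= 0:
        raise ValueError("max_width must be positive")
    if side not in (1, -1):
        raise ValueError("side must be +1 or -1")
    if scale_mode not in ("width", "area"):
        raise ValueError("scale_mode must be 'width' or 'area'")
    peak = float(np.max(curve.density))
    if peak <= 0:
        raise ValueError("cannot build a half-violin from an all-zero density")
    if scale_mode == "area":
        if sibling_max is None or sibling_max <= 0:
            raise ValueError("scale_mode='area' requires a positive sibling_max")
        peak = float(sibling_max)
    offsets = max_width * curve.density / peak
    positions = np.concatenate(([center], center + side * offsets, [center]))
    values = np.concatenate(([curve.grid[0]], curve.grid, [curve.grid[-1]]))
    return Polygon(positions, values, **style)


def jitter_points(
    values,
    center: float,
    width: float,
    seed: int,
    height: float = 0.0,
    **style,
) -> PointSet:
    """Uniformly jittered raw-data points (the rain).

    Positions draw from ``center + U(-width/2, +width/2)`` using a fresh
    :func:`numpy.random.default_rng` seeded with ``seed``; values optionally
    get ``U(-height/2, +height/2)`` perturbation (for ordinal data).
    Observation order is preserved and identical inputs reproduce bitwise.
    """
    if width < 0 or height < 0:
        raise ValueError("jitter width and height must be nonnegative")
    vals = values.values if isinstance(values, Sample) else np.asarray(values, float)
    n = vals.size
    rng = np.random.default_rng(seed)
    if width > 0:
        positions = center + rng.uniform(-width / 2.0, width / 2.0, n)
    else:
        positions = np.full(n, float(center))
        rng.uniform(-0.5, 0.5, n)  # keep the stream position independent of width
    if height > 0:
        vals = vals + rng.uniform(-height / 2.0, height / 2.0, n)
    return PointSet(positions, vals, **style)


def apply_offset(primitive, offset: Offset):
    """Translate a primitive or a whole scene by an :class:`Offset`.

    Shape-preserving; applying (a, b) then (c, d) equals applying
    (a + c, b + d).
    """
    if isinstance(primitive, FigureScene):
        return primitive.with_primitives(
            p.translated(offset.d_position, offset.d_value) for p in primitive.primitives
        )
    return primitive.translated(offset.d_position, offset.d_value)


def dodge_offsets(n_levels: int, dodge_amount: float) -> np.ndarray:
    """Symmetric per-level position offsets, evenly spaced around 0.

    Level k of n (0-based) gets ``(k - (n-1)/2) * dodge_amount``, so two
    levels dodge to -a/2 and +a/2 and the offsets always sum to zero.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if dodge_amount < 0:
        raise ValueError("dodge_amount must be nonnegative")
    k = np.arange(n_levels, dtype=float)
    return (k - (n_levels - 1) / 2.0) * dodge_amount


def flip_orientation(scene: FigureScene) -> FigureScene:
    """Toggle a scene between vertical and horizontal layout.

    Internal (position, value) coordinates are untouched; only the canvas
    mapping recorded in the metadata changes, so flipping twice restores the
    original scene exactly.
    """
    return replace(scene, orientation="h" if scene.orientation == "v" else "v")
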