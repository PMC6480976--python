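"""Statistical primitives behind the cloud and the summary layers.

Everything here is pure computation on numeric samples: kernel density
estimation (the "cloud" before any geometry), the average shifted histogram
alternative, Tukey boxplot statistics, and grouped summary statistics with
Student-t confidence intervals (the ``summarySE`` table of the R workflow).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "Sample",
    "DensityCurve",
    "BoxStats",
    "SummaryStats",
    "nrd0_bandwidth",
    "kde_density",
    "ash_density",
    "box_stats",
    "summary_se",
]


@dataclass(frozen=True)
class Sample:
    """A clean numeric sample: finite values only, missing entries counted.

    Parameters
    ----------
    values : array-like
        Raw observations; NaN/inf entries are dropped at construction.

    Attributes
    ----------
    values : ndarray
        The retained finite observations, input order preserved.
    n_dropped : int
        How many non-finite entries were removed.
    """

    values: np.ndarray
    n_dropped: int = 0

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=float).ravel()
        finite = np.isfinite(arr)
        n_dropped = int((~finite).sum())
        arr = arr[finite]
        if arr.size < 1:
            raise ValueError("Sample requires at least one finite value")
        if n_dropped:
            logger.info("Sample construction dropped %d non-finite value(s)", n_dropped)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "n_dropped", n_dropped)

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class DensityCurve:
    """A density evaluated on a uniform grid; the cloud before geometry.

    ``grid`` is strictly increasing in measure units; ``density`` is the
    nonnegative estimate (1/measure units) at each grid point.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    method: str  # "kde" or "ash"
    trimmed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        if self.grid.size != self.density.size or self.grid.size < 2:
            raise ValueError("grid and density must share length >= 2")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    def integral(self) -> float:
        """Trapezoid mass of the curve."""
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class BoxStats:
    """Tukey five-number summary with k*IQR whiskers and outliers."""

    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray
    whisker_k: float = 1.5

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class SummaryStats:
    """One row of the per-group summary table (N, mean, median, sd, se, ci).

    ``se = sd / sqrt(N)`` and ``ci`` is the half-width of the level-``conf``
    Student-t interval, ``se * t_{(1+conf)/2, N-1}``.  With N = 1 the spread
    columns are NaN.
    """

    group_labels: tuple
    N: int
    mean: float
    median: float
    sd: float
    se: float
    ci: float
    conf: float = 0.95


def nrd0_bandwidth(x: Sample) -> float:
    """Silverman's rule-of-thumb bandwidth (R's ``bw.nrd0``).

    Returns ``0.9 * L * n**(-1/5)`` with ``L = min(sd, IQR/1.34)``; when the
    spread estimate degenerates to zero it falls back to the sd, then the
    absolute first value, then 1, so a positive bandwidth always comes back.
    """
    if not isinstance(x, Sample):
        x = Sample(x)
    if x.n < 2:
        raise ValueError("nrd0_bandwidth requires n >= 2")
    v = x.values
    sd = float(np.std(v, ddof=1))
    q3, q1 = np.quantile(v, [0.75, 0.25])
    iqr = float(q3 - q1)
    lo = min(sd, iqr / 1.34) if iqr > 0 else sd
    if lo == 0:
        lo = sd
    if lo == 0:
        lo = abs(float(v[0]))
    if lo == 0:
        lo = 1.0
    return 0.9 * lo * x.n ** (-0.2)


def kde_density(
    x: Sample,
    bandwidth: float,
    cut: float = 3.0,
    gridsize: int = 512,
    trim: bool = False,
) -> DensityCurve:
    """Gaussian kernel density estimate on a uniform grid.

    The estimate is ``f(v) = (1/(n h)) sum_i phi((v - x_i)/h)`` with phi the
    standard normal density.  The grid spans ``[min(x) - cut*h, max(x) + cut*h]``
    unless ``trim`` restricts it to the data range (``cut`` is then ignored),
    matching violin ``trim=TRUE`` semantics.
    """
    if not isinstance(x, Sample):
        x = Sample(x)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if cut < 0:
        raise ValueError("cut must be nonnegative")
    if gridsize < 2:
        raise ValueError("gridsize must be >= 2")
    v = x.values
    lo, hi = float(v.min()), float(v.max())
    if not trim:
        lo -= cut * bandwidth
        hi += cut * bandwidth
    if lo == hi:  # single-point sample with trim: give the grid some width
        lo -= bandwidth
        hi += bandwidth
    grid = np.linspace(lo, hi, gridsize)
    z = (grid[:, None] - v[None, :]) / bandwidth
    dens = sps.norm.pdf(z).sum(axis=1) / (x.n * bandwidth)
    return DensityCurve(grid, dens, float(bandwidth), "kde", trimmed=bool(trim))


def ash_density(x: Sample, bin_width: float, n_shifts: int = 32) -> DensityCurve:
    """Average shifted histogram density.

    Averages ``n_shifts`` histograms whose origins are offset by
    ``bin_width / n_shifts``, then renormalizes to unit trapezoid mass.  With
    one shift this is the ordinary histogram density; as the number of shifts
    grows it converges to a triangular-kernel KDE with bandwidth ``bin_width``.
    """
    if not isinstance(x, Sample):
        x = Sample(x)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if n_shifts < 1:
        raise ValueError("n_shifts must be >= 1")
    v = x.values
    delta = bin_width / n_shifts
    lo = float(v.min()) - bin_width
    hi = float(v.max()) + bin_width
    # fine grid of width-delta cells; each shifted histogram is piecewise
    # constant on these cells, so the average is exact on them
    n_cells = int(np.ceil((hi - lo) / delta))
    edges = lo + delta * np.arange(n_cells + 1)
    counts, _ = np.histogram(v, bins=edges)
    cell_dens = counts / (x.n * delta)
    # cell j+k shares a bin with cell j in exactly (m - |k|) of the m shifted
    # histograms, so the shift average is a triangular moving window
    m = n_shifts
    k = np.arange(-(m - 1), m)
    kernel = (1.0 - np.abs(k) / m) / m
    avg = np.convolve(cell_dens, kernel, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2.0
    mass = np.trapezoid(avg, centers)
    if mass > 0:
        avg = avg / mass
    return DensityCurve(centers, avg, float(bin_width), "ash")


def box_stats(x: Sample, whisker_k: float = 1.5) -> BoxStats:
    """Tukey boxplot statistics.

    Quartiles use linear interpolation of order statistics (quantile type 7);
    whiskers reach to the most extreme data values inside the
    ``q1 - k*IQR, q3 + k*IQR`` fences; anything beyond is an outlier.
    """
    if not isinstance(x, Sample):
        x = Sample(x)
    if whisker_k <= 0:
        raise ValueError("whisker_k must be positive")
    v = x.values
    q1, med, q3 = (float(q) for q in np.quantile(v, [0.25, 0.5, 0.75]))
    iqr = q3 - q1
    lo_fence = q1 - whisker_k * iqr
    hi_fence = q3 + whisker_k * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    # quartiles are interpolated so at least the median is always inside
    whisker_lo = float(inside.min())
    whisker_hi = float(inside.max())
    outliers = np.sort(v[(v < lo_fence) | (v > hi_fence)])
    return BoxStats(q1, med, q3, whisker_lo, whisker_hi, outliers, float(whisker_k))


def _t_halfwidth(se: float, n: int, conf: float) -> float:
    return float(se * sps.t.ppf((1.0 + conf) / 2.0, n - 1))


def summary_se(
    table: pd.DataFrame,
    measure: str,
    group_vars,
    conf: float = 0.95,
) -> list[SummaryStats]:
    """Per-group N/mean/median/sd/se/ci, the ``summarySE`` table.

    ``sd`` uses denominator N-1, ``se = sd/sqrt(N)`` and ``ci`` is the
    t-based half-width at level ``conf``.  Groups of size 1 report NaN for
    sd/se/ci with a warning.  Group order follows first appearance.
    """
    if isinstance(group_vars, str):
        group_vars = [group_vars]
    group_vars = list(group_vars)
    for col in [measure, *group_vars]:
        if col not in table.columns:
            raise KeyError(
                f"column {col!r} not in table; available: {list(table.columns)}"
            )
    out: list[SummaryStats] = []
    grouped = table.groupby(group_vars, sort=False, observed=True)
    for labels, sub in grouped:
        if not isinstance(labels, tuple):
            labels = (labels,)
        vals = pd.to_numeric(sub[measure], errors="coerce").dropna().to_numpy(float)
        n = vals.size
        if n < 1:
            raise ValueError(f"group {labels!r} has no non-missing observations")
        mean = float(vals.mean())
        median = float(np.median(vals))
        if n == 1:
            warnings.warn(
                f"group {labels!r} has N = 1; sd/se/ci reported as missing",
                stacklevel=2,
            )
            sd = se = ci = float("nan")
        else:
            sd = float(np.std(vals, ddof=1))
            se = sd / np.sqrt(n)
            ci = _t_halfwidth(se, n, conf)
        out.append(SummaryStats(tuple(labels), n, mean, median, sd, se, ci, conf))
    return out


def summary_se_frame(
    table: pd.DataFrame, measure: str, group_vars, conf: float = 0.95
) -> pd.DataFrame:
    """``summary_se`` as a DataFrame with the printed column names."""
    if isinstance(group_vars, str):
        group_vars = [group_vars]
    rows = summary_se(table, measure, group_vars, conf)
    recs = []
    for r in rows:
        rec = dict(zip(group_vars, r.group_labels))
        rec.update(
            N=r.N,
            **{
                f"{measure}_mean": r.mean,
                f"{measure}_median": r.median,
            },
            sd=r.sd,
            se=r.se,
            ci=r.ci,
        )
        recs.append(rec)
    return pd.DataFrame(recs)
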