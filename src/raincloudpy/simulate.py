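"""Seeded synthetic datasets with the statistical structure of the examples.

Three generators:

* ``simulate_two_groups`` — two groups with equal population mean and sd,
  one drawn from a shifted exponential (skewed) and one normal.  A barplot
  of means cannot tell them apart; a raincloud can.  Defaults: mean 50,
  sd 25, n = 1000 per group.
* ``simulate_repeated_measures`` — two groups (n = 18 and 11) measured at
  three timepoints, cell means/sds set to the reference summary table so
  the generated data reproduces its structure in expectation.
* ``simulate_bimodal`` — a two-component normal mixture whose bimodality a
  boxplot hides but a density reveals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import Sample

logger = logging.getLogger(__name__)

__all__ = [
    "SimSpec",
    "simulate_two_groups",
    "simulate_repeated_measures",
    "simulate_bimodal",
    "REPEATED_MEASURES_MEANS",
    "REPEATED_MEASURES_SDS",
    "REPEATED_MEASURES_NS",
]


@dataclass(frozen=True)
class SimSpec:
    """Specification of the two-group simulation."""

    n_per_group: int = 250
    target_mean: float = 50.0
    target_sd: float = 25.0
    seed: int = 42
    second_factor: bool = False

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")


def simulate_two_groups(spec: SimSpec) -> pd.DataFrame:
    """Two equal-moment groups: shifted exponential vs normal.

    Group1 is exponential with scale ``sd`` shifted by ``mean - sd``, so its
    population mean and sd both hit the targets exactly; Group2 is
    N(mean, sd).  With ``second_factor`` a balanced ``gr2`` column splits
    each group into a "high" first half and "low" second half.
    """
    rng = np.random.default_rng(spec.seed)
    n, mu, sd = spec.n_per_group, spec.target_mean, spec.target_sd
    shift = mu - sd
    if shift < 0:
        logger.warning(
            "target_sd >= target_mean: shifted-exponential support starts at %g < 0",
            shift,
        )
    g1 = shift + rng.exponential(scale=sd, size=n)
    g2 = rng.normal(loc=mu, scale=sd, size=n)
    frame = pd.DataFrame(
        {
            "group": np.repeat(["Group1", "Group2"], n),
            "score": np.concatenate([g1, g2]),
        }
    )
    if spec.second_factor:
        half = n // 2
        per_group = ["high"] * half + ["low"] * (n - half)
        frame["gr2"] = per_group * 2
    return frame


# Reference factorial structure: 2 groups x 3 timepoints, unbalanced
REPEATED_MEASURES_NS = (18, 11)
REPEATED_MEASURES_MEANS = (
    (6.362222, 7.468333, 10.482778),
    (1.847273, 3.684545, 7.358182),
)
REPEATED_MEASURES_SDS = (
    (1.658861, 1.546880, 1.060254),
    (2.010279, 2.135108, 2.236273),
)


def simulate_repeated_measures(
    n_group1: int = 18,
    n_group2: int = 11,
    base_means=REPEATED_MEASURES_MEANS,
    sds=REPEATED_MEASURES_SDS,
    seed: int = 42,
) -> pd.DataFrame:
    """Factorial repeated-measures data: 2 groups x 3 timepoints.

    Cell (g, t) draws ``n_group{g}`` values from N(base_means[g][t],
    sds[g][t]).  Columns: ``score``, ``time`` in {1,2,3}, ``group`` in
    {1,2}, plus a within-group ``subject`` id reused across timepoints so
    the table feeds the linked repeated-measures constructors directly.
    """
    base_means = np.asarray(base_means, float)
    sds = np.asarray(sds, float)
    if base_means.shape != sds.shape or base_means.ndim != 2:
        raise ValueError("base_means and sds must be equal-shape 2-D arrays")
    if np.any(sds <= 0):
        raise ValueError("all cell sds must be positive")
    n_groups, n_times = base_means.shape
    ns = [n_group1, n_group2][:n_groups]
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        for t in range(n_times):
            vals = rng.normal(base_means[g, t], sds[g, t], ns[g])
            rows.append(
                pd.DataFrame(
                    {
                        "score": vals,
                        "time": t + 1,
                        "group": g + 1,
                        "subject": np.arange(ns[g]),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_bimodal(
    n: int,
    modes=(-2.0, 2.0),
    sds=(0.5, 0.5),
    weight: float = 0.5,
    seed: int = 42,
) -> Sample:
    """Two-component normal mixture (component 1 with probability ``weight``)."""
    if not (0.0 < weight < 1.0):
        raise ValueError("weight must lie strictly inside (0, 1)")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < weight
    vals = np.where(
        comp,
        rng.normal(modes[0], sds[0], n),
        rng.normal(modes[1], sds[1], n),
    )
    return Sample(vals)
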