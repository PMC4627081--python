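"""Hydrogen-bond quality index for Watson-Crick G:C pairs.

The index scores the deviation of the three G:C hydrogen bonds from ideal
geometry:

    I_H = sum_{i=1..3} [ (d_i - d0_i)^2 + (1 + cos gamma_i)^2 ]

where d_i is the observed donor-acceptor distance, d0_i the ideal value
(O6(G)-N4(C) 2.91 A, N1(G)-N3(C) 2.95 A, N2(G)-O2(C) 2.86 A) and gamma_i
the D-H...A angle, ideally 180 deg.  Ideal geometry scores exactly 0; the
index mixes squared Angstrom and dimensionless angle terms with no
reweighting, as published.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import BondGeometrySeries

__all__ = ["IdealBondParams", "IHSeriesResult", "CompareResult",
           "ih_index", "ih_series", "compare_ih"]


@dataclass(frozen=True)
class IdealBondParams:
    """Ideal G:C hydrogen-bond geometry (distances in Angstrom, angle deg)."""

    d0: tuple[float, float, float] = (2.91, 2.95, 2.86)
    gamma0: float = 180.0

    def __post_init__(self) -> None:
        if len(self.d0) != 3 or any(d <= 0 for d in self.d0):
            raise ValueError("d0 must be three positive distances")
        if self.gamma0 != 180.0:
            raise ValueError("the ideal D-H...A angle is 180 degrees")


IDEAL_GC = IdealBondParams()


def ih_index(
    distances: Sequence[float],
    angles: Sequence[float],
    ideal: IdealBondParams = IDEAL_GC,
) -> float:
    """The quality index for one frame (three distances, three angles).

    Always >= 0, and 0 iff every distance equals its ideal and every angle
    is 180 deg.  Angles are taken in degrees.
    """
    d = np.asarray(distances, dtype=float)
    g = np.asarray(angles, dtype=float)
    if d.shape != (3,) or g.shape != (3,):
        raise ValueError("expected exactly three distances and three angles")
    return float(np.sum((d - np.asarray(ideal.d0)) ** 2
                        + (1.0 + np.cos(np.deg2rad(g))) ** 2))


@dataclass
class IHSeriesResult:
    """Per-frame index values with their median and quartiles."""

    values: np.ndarray
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def ih_series(
    series: BondGeometrySeries,
    ideal: IdealBondParams = IDEAL_GC,
) -> IHSeriesResult:
    """Evaluate the index per frame and summarize by median and 25-75 range."""
    if series.n_frames == 0:
        raise ValueError("empty geometry series")
    d0 = np.asarray(ideal.d0)
    values = np.sum(
        (series.distances - d0) ** 2
        + (1.0 + np.cos(np.deg2rad(series.angles))) ** 2,
        axis=1,
    )
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return IHSeriesResult(values=values, median=float(med), q1=float(q1), q3=float(q3))


@dataclass(frozen=True)
class CompareResult:
    median_difference: float
    absolute_difference: float
    p_value: float
    U: float


def compare_ih(adducted: np.ndarray, control: np.ndarray) -> CompareResult:
    """Compare two per-frame index distributions (adducted vs control).

    Reports the signed and absolute difference of medians together with a
    two-sided Mann-Whitney U p-value.  Identical samples give difference 0
    and p = 1.
    """
    from .trajectory_stats import mann_whitney_u

    adducted = np.asarray(adducted, dtype=float)
    control = np.asarray(control, dtype=float)
    if adducted.size == 0 or control.size == 0:
        raise ValueError("both index series must be non-empty")
    diff = float(np.median(adducted) - np.median(control))
    mw = mann_whitney_u(adducted, control)
    return CompareResult(
        median_difference=diff,
        absolute_difference=abs(diff),
        p_value=mw.p_value,
        U=mw.U,
    )
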