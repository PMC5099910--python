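"""Developmental milestones extracted from simulated trajectories.

Emergence of a population is the first time its size reaches one cell
(1e-7 units by default, configurable), located by linear interpolation
between bracketing solver grid points.  Composition fractions are taken
over the four live populations (the apoptotic sink is excluded), and the
DN%/DP% crossing is the first sign change of their difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dde import Trajectory
from .parameters import ONE_CELL, Population

__all__ = [
    "MilestoneReport",
    "Crossing",
    "emergence_times",
    "composition_fractions",
    "crossing_time",
    "milestone_report",
]

_LIVE = (Population.DN, Population.DP, Population.SP4, Population.SP8)
_COL = {Population.DN: 0, Population.DP: 1, Population.SP4: 2, Population.SP8: 3}


@dataclass
class Crossing:
    time: float
    degenerate: bool = False  # curves equal from the first grid point on


@dataclass
class MilestoneReport:
    """Emergence times (dpc, None if never reached), pairwise delays,
    composition crossing, and the total-thymocyte peak."""

    emergence: dict = field(default_factory=dict)
    dn_dp_delay: Optional[float] = None
    dp_sp4_delay: Optional[float] = None
    dp_sp8_delay: Optional[float] = None
    dn_dp_crossing: Optional[Crossing] = None
    peak_time: Optional[float] = None
    peak_total: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "emergence_dpc": {k.value: v for k, v in self.emergence.items()},
            "dn_dp_delay_days": self.dn_dp_delay,
            "dp_sp4_delay_days": self.dp_sp4_delay,
            "dp_sp8_delay_days": self.dp_sp8_delay,
            "dn_dp_crossing_dpc": None if self.dn_dp_crossing is None else self.dn_dp_crossing.time,
            "peak_time_dpc": self.peak_time,
            "peak_total_1e7cells": self.peak_total,
        }


def _first_crossing_up(t: np.ndarray, y: np.ndarray, threshold: float) -> Optional[float]:
    """Earliest time y reaches threshold, linearly interpolated."""
    above = y >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1 = t[i - 1], t[i]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (threshold - y0) * (t1 - t0) / (y1 - y0))


def emergence_times(traj: Trajectory, threshold: float = ONE_CELL) -> MilestoneReport:
    """First-appearance time of each live population (one-cell threshold)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    report = MilestoneReport()
    for pop in _LIVE:
        report.emergence[pop] = _first_crossing_up(
            traj.times, traj.states[:, _COL[pop]], threshold
        )
    e = report.emergence
    if e[Population.DN] is not None and e[Population.DP] is not None:
        report.dn_dp_delay = e[Population.DP] - e[Population.DN]
    if e[Population.DP] is not None and e[Population.SP4] is not None:
        report.dp_sp4_delay = e[Population.SP4] - e[Population.DP]
    if e[Population.DP] is not None and e[Population.SP8] is not None:
        report.dp_sp8_delay = e[Population.SP8] - e[Population.DP]
    return report


def composition_fractions(traj: Trajectory, t) -> np.ndarray:
    """Fractions of DN, DP, SP4, SP8 among live thymocytes at time(s) t."""
    values = np.atleast_2d(traj(t))[:, :4]
    total = values.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("composition undefined: zero live population")
    fractions = values / total[:, None]
    return fractions[0] if np.ndim(t) == 0 else fractions


def crossing_time(
    traj: Trajectory,
    fraction_a=Population.DN,
    fraction_b=Population.DP,
    t_min: Optional[float] = None,
) -> Optional[Crossing]:
    """Earliest time the two populations' composition fractions cross.

    Linear interpolation refines the sign change.  Returns None when the
    curves never cross; a degenerate flag when they are equal from the
    first usable grid point onward.
    """
    a, b = _COL[Population(fraction_a)], _COL[Population(fraction_b)]
    total = traj.total_live()
    usable = total > 0
    if t_min is not None:
        usable &= traj.times >= t_min
    if not usable.any():
        return None
    t = traj.times[usable]
    frac = traj.states[usable, :4] / total[usable, None]
    diff = frac[:, a] - frac[:, b]
    if np.all(diff == 0):
        return Crossing(float(t[0]), degenerate=True)
    sign = np.sign(diff)
    nonzero = sign != 0
    if diff[0] == 0:
        return Crossing(float(t[0]))
    change = np.where(sign[:-1] * sign[1:] < 0)[0]
    exact = np.where((sign[1:] == 0) & (sign[:-1] != 0))[0]
    candidates = []
    if change.size:
        i = int(change[0])
        frac_t = diff[i] / (diff[i] - diff[i + 1])
        candidates.append(float(t[i] + frac_t * (t[i + 1] - t[i])))
    if exact.size:
        candidates.append(float(t[int(exact[0]) + 1]))
    if not candidates:
        return None
    return Crossing(min(candidates))


def milestone_report(traj: Trajectory, threshold: float = ONE_CELL) -> MilestoneReport:
    """Bundle emergence times, delays, DN%/DP% crossing, and total peak."""
    report = emergence_times(traj, threshold)
    report.dn_dp_crossing = crossing_time(traj, Population.DN, Population.DP)
    total = traj.total_live()
    if total.max() > 0:
        i = int(np.argmax(total))
        report.peak_time = float(traj.times[i])
        report.peak_total = float(total[i])
    return report
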