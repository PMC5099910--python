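"""In-silico progenitor ablation: postnatal dynamics with versus without
bone-marrow progenitor influx.

Two scenarios share the prenatal segment (always driven by the logistic
influx) and differ only after birth: the influx is either held constant at
its birth-level plateau b0, or set to zero for the remainder of life.  The
impact is tabulated as the percentage difference

    (with - without) / with * 100%

per population at standard postnatal checkpoints (6 weeks; 3, 6, 12, 18,
24 months).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dde import Trajectory, simulate
from .milestones import milestone_report
from .parameters import InfluxMode, ModelSpec

__all__ = [
    "DEFAULT_CHECKPOINTS",
    "ScenarioComparison",
    "run_progenitor_scenario",
    "compare_progenitor_ablation",
    "percentage_difference_table",
    "milestone_report",
]

#: postnatal days: 6 weeks, 3/6 months, 1 year, 18 months, 2 years
DEFAULT_CHECKPOINTS = (42.0, 91.0, 182.0, 365.0, 548.0, 730.0)
CHECKPOINT_LABELS = ("6 weeks", "3 months", "6 months", "1 year", "18 months", "2 years")

_ROWS = ("DN", "DP", "SP4", "SP8", "Total thymocytes")
_ROW_POPS = ("DN", "DP", "SP4", "SP8", "total")


@dataclass
class ScenarioComparison:
    trajectory_with: Trajectory      # postnatal influx b(t) = b0
    trajectory_without: Trajectory   # postnatal influx b(t) = 0
    checkpoints: Sequence[float] = DEFAULT_CHECKPOINTS  # days postnatal
    labels: Sequence[str] = CHECKPOINT_LABELS
    flagged_cells: list = field(default_factory=list)


def run_progenitor_scenario(
    spec: ModelSpec, mode=InfluxMode.CONSTANT_B0, **sim_kwargs
) -> Trajectory:
    """Simulate one postnatal-influx regime (prenatal always logistic)."""
    mode = InfluxMode(mode)
    if mode is InfluxMode.LOGISTIC:
        raise ValueError("postnatal scenario mode must be constant_b0 or zero")
    return simulate(spec, influx_mode_postnatal=mode, **sim_kwargs)


def compare_progenitor_ablation(
    spec: ModelSpec,
    checkpoints: Sequence[float] = DEFAULT_CHECKPOINTS,
    labels: Optional[Sequence[str]] = None,
    **sim_kwargs,
) -> ScenarioComparison:
    """Run both scenarios over a horizon covering all checkpoints."""
    checkpoints = tuple(float(c) for c in checkpoints)
    if labels is None:
        labels = (
            CHECKPOINT_LABELS
            if checkpoints == DEFAULT_CHECKPOINTS
            else tuple(f"day {c:g}" for c in checkpoints)
        )
    t_end = max(spec.birth_time + max(checkpoints), spec.horizon)
    with_traj = run_progenitor_scenario(spec, InfluxMode.CONSTANT_B0, t_end=t_end, **sim_kwargs)
    without_traj = run_progenitor_scenario(spec, InfluxMode.ZERO, t_end=t_end, **sim_kwargs)
    return ScenarioComparison(with_traj, without_traj, checkpoints, labels)


def percentage_difference_table(
    cmp: ScenarioComparison, include_apoptotic_in_total: bool = False
) -> pd.DataFrame:
    """Percent impact of ablation, (with - without)/with * 100, per
    population and checkpoint.

    Cells whose with-progenitor denominator is zero are NaN and recorded in
    ``cmp.flagged_cells`` (never silently produced).
    """
    times = np.asarray(cmp.checkpoints) + cmp.trajectory_with.birth_time
    data = {}
    cmp.flagged_cells.clear()
    for row, pop in zip(_ROWS, _ROW_POPS):
        w = np.asarray(cmp.trajectory_with.population(pop, times), dtype=float)
        wo = np.asarray(cmp.trajectory_without.population(pop, times), dtype=float)
        if pop == "total" and include_apoptotic_in_total:
            w = w + np.asarray(cmp.trajectory_with.population("D", times))
            wo = wo + np.asarray(cmp.trajectory_without.population("D", times))
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = (w - wo) / w * 100.0
        zero = w == 0
        if zero.any():
            for j in np.where(zero)[0]:
                cmp.flagged_cells.append((row, cmp.labels[j]))
            pct[zero] = np.nan
        data[row] = pct
    table = pd.DataFrame.from_dict(data, orient="index", columns=list(cmp.labels))
    table.index.name = "Thymocytes population"
    return table
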