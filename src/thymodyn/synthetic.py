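"""Synthetic ground truth and observation generator.

The generator emulates the experimental design behind the model: litters
sampled at E17.5, E18.5 and E19.5 prenatally, then every 5 postnatal days
up to day 50 plus day 80, several animals per time point, with counts per
population obtained from total thymocyte counts and flow-cytometry
percentages.  Counts are reproduced as model predictions corrupted by
multiplicative lognormal noise (counts are positive and span four orders
of magnitude); they stay real-valued, since flow-cytometry-derived totals
at the 10^6-10^8-cell scale are effectively continuous.

The pinned ground-truth parameter set is not fitted to any data: it is a
documented, version-pinned instance chosen to reproduce the qualitative
developmental arc of the mouse thymus (DN emergence ~E10-11, DP ~3 days
later, SP4/SP8 ~1 day after DP, DN%/DP% crossing shortly before birth,
postnatal expansion peaking within weeks at the 10^8-cell scale, then
gradual involution with DP% staying above DN%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import ObservationSet
from .dde import simulate
from .model import ensure_beta, progenitor_influx
from .parameters import (
    CELLS_PER_UNIT,
    InfluxMode,
    ModelClass,
    ModelSpec,
    StageParameters,
    Variant,
)

__all__ = [
    "StudyDesign",
    "default_ground_truth",
    "simulate_observations",
    "progenitor_series",
    "fit_logistic_influx",
]

DEFAULT_POSTNATAL_DAYS = tuple(float(d) for d in range(0, 55, 5)) + (80.0,)


@dataclass
class StudyDesign:
    """Sampling plan for a synthetic study."""

    prenatal_times: Sequence[float] = (17.5, 18.5, 19.5)   # dpc
    postnatal_days: Sequence[float] = DEFAULT_POSTNATAL_DAYS
    replicates: int = 4
    cv: float = 0.10  # multiplicative lognormal noise, coefficient of variation
    populations: Sequence[str] = ("DN", "DP", "SP4", "SP8", "apoptotic")

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if list(self.prenatal_times) != sorted(self.prenatal_times):
            raise ValueError("prenatal_times must be sorted")
        if list(self.postnatal_days) != sorted(self.postnatal_days):
            raise ValueError("postnatal_days must be sorted")

    def times_dpc(self, birth_time: float = 19.5) -> np.ndarray:
        times = list(self.prenatal_times) + [birth_time + d for d in self.postnatal_days]
        return np.unique(np.asarray(times, dtype=float))

    def to_dict(self) -> dict:
        return {
            "prenatal_times": list(self.prenatal_times),
            "postnatal_days": list(self.postnatal_days),
            "replicates": self.replicates,
            "cv": self.cv,
            "populations": list(self.populations),
        }


# -- pinned ground truth -------------------------------------------------------

_PRENATAL = dict(
    b_N=0.4, b_P=0.45, b_4=0.25, b_8=0.25,
    c_N=20.2, c_P=85.0, c_48=4.0,
    s_N=0.4, s_4=0.10, s_8=0.05, s_04=0.1, s_08=0.1,
    d_N=0.07, d_P=0.40, d_4=0.15, d_8=0.15,
    delta=0.5, tau_N=3.0,
)

# postnatal amplitudes are on the absolute-clock form c * exp(-b * t):
# the rates at birth are c*exp(-19.5 b) ~ (0.09, 0.31, 0.6, 0.6) per day
_POSTNATAL = dict(
    b_N=0.018, b_P=0.06, b_4=0.30, b_8=0.30,
    c_N=0.128, c_P=1.005, c_48=208.0,
    s_N=0.03, s_4=0.009, s_8=0.005, s_04=0.05, s_08=0.06,
    d_N=0.015, d_P=0.012, d_4=0.03, d_8=0.03,
    delta=0.3, tau_N=2.0,
)

# under V2 the postnatal amplitudes are derived from the prenatal stage, so
# sane postnatal proliferation requires decay rates near the prenatal ones;
# these pinned values keep the birth-time rates at the same magnitude as V1
_V2_POSTNATAL_DECAY = dict(b_N=0.416, b_P=0.486, b_4=0.179, b_8=0.179)

_GLOBALS = dict(t0=10.3, b0=0.0005, tau_b=14.0)

# capacities sit above the typical population scale so density control is a
# late-regulating factor rather than the dominant dynamics
_CAPACITIES = dict(pre=dict(K_N=1.0, K=3.0), post=dict(K_N=3.0, K=40.0))


def default_ground_truth(model_class="M1", variant="V1", seed: int = 0) -> ModelSpec:
    """Version-pinned ground-truth model for the requested class/variant.

    The parameter values are fixed constants (the ``seed`` argument is
    accepted for interface symmetry but the set is pinned, not sampled).
    Under V2 the postnatal amplitudes are derived from the prenatal ones;
    under M2 carrying capacities are attached to both stages.
    """
    model_class, variant = ModelClass(model_class), Variant(variant)
    pre = dict(_PRENATAL)
    post = dict(_POSTNATAL)
    if variant is Variant.V2:
        post.update(_V2_POSTNATAL_DECAY)
    if model_class is ModelClass.M2:
        pre.update(_CAPACITIES["pre"])
        post.update(_CAPACITIES["post"])
    spec = ModelSpec(
        model_class=model_class,
        variant=variant,
        prenatal=StageParameters(**pre),
        postnatal=StageParameters(**post),
        **_GLOBALS,
    )
    spec = ensure_beta(spec).with_constraint_applied()
    spec.validate()
    return spec


# -- observation generation ----------------------------------------------------


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def simulate_observations(
    spec: ModelSpec,
    design: Optional[StudyDesign] = None,
    seed: int = 0,
    **sim_kwargs,
) -> ObservationSet:
    """Noisy replicate counts at the design's time points.

    Each record is the model prediction (converted to cells) times an
    independent lognormal factor with mean 1 and the design's CV.
    Deterministic given ``seed``.
    """
    design = design or StudyDesign()
    design.validate()
    times = design.times_dpc(spec.birth_time)
    if times.min() < spec.t0:
        raise ValueError(f"design time {times.min()} precedes thymopoiesis onset t0={spec.t0}")
    traj = simulate(spec, t_end=float(times.max()) + 1e-6, **sim_kwargs)

    rng = np.random.default_rng(seed)
    records = []
    for pop in design.populations:
        pred_units = np.asarray(traj.population(pop, times))
        for t, value in zip(times, pred_units):
            noise = _lognormal_factors(rng, design.cv, design.replicates)
            for rep in range(design.replicates):
                records.append(
                    (t, pop, rep, value * CELLS_PER_UNIT * noise[rep])
                )
    frame = pd.DataFrame(records, columns=list(ObservationSet.COLUMNS))
    return ObservationSet(frame)


def progenitor_series(
    spec: ModelSpec,
    times: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy fetal progenitor counts along the logistic influx curve.

    Emulates staged progenitor counts for exercising the logistic-refit
    path.  Returns columns ``time_dpc`` and ``count_cells``.
    """
    spec = ensure_beta(spec)
    times = np.asarray(times, dtype=float)
    if times.max() > spec.birth_time + 1e-9:
        raise ValueError("progenitor series times must lie in the prenatal window")
    values = np.array(
        [progenitor_influx(spec, t, InfluxMode.LOGISTIC) for t in times]
    )
    rng = np.random.default_rng(seed)
    counts = values * CELLS_PER_UNIT * _lognormal_factors(rng, noise_cv, times.size)
    return pd.DataFrame({"time_dpc": times, "count_cells": counts})


def fit_logistic_influx(times, counts_cells, p0=None):
    """Least-squares refit of the three-parameter logistic to a progenitor
    series; returns (b0, tau_b, beta) on model units."""
    from scipy.optimize import curve_fit

    times = np.asarray(times, dtype=float)
    y = np.asarray(counts_cells, dtype=float) / CELLS_PER_UNIT

    def logistic(t, b0, tau_b, beta):
        return b0 / (1.0 + np.exp(-beta * (t - tau_b)))

    if p0 is None:
        p0 = (max(y.max(), 1e-6), float(np.median(times)), 1.0)
    popt, _ = curve_fit(logistic, times, y, p0=p0, maxfev=20000)
    b0, tau_b, beta = popt
    return float(b0), float(tau_b), float(beta)
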