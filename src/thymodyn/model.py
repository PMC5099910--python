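"""Rate functions and right-hand side of the thymocyte DDE system.

The dynamics of the five compartments (DN = N, DP = P, SP4, SP8, apoptotic
sink D) are

    dN/dt   = rho_N(t) N  - d_N N - s_N N          + b(t)
    dP/dt   = rho_P(t) P  - d_P P - (s_4 + s_8) P  + s_N N(t - tau_N)
    dSP4/dt = rho_4(t) S4 - d_4 S4 - s_04 S4       + s_4 P
    dSP8/dt = rho_8(t) S8 - d_8 S8 - s_08 S8       + s_8 P
    dD/dt   = d_N N + d_P P + d_4 S4 + d_8 S8 - delta D

where the per-capita proliferation rates decrease exponentially in time
(model class M1):

    prenatal   rho_X(t) = c_X * b_X * exp(-b_X * (t - t0)),
    postnatal  rho_X(t) = c_X * exp(-b_X * t)        (absolute clock).

The postnatal form is the one under which the variant-V2 amplitude
constraint, c_post = b_pre * c_pre * exp(b_pre * t0), is exactly a
continuity condition on the proliferation function at birth when the decay
rate b is carried over unchanged.  Model class M2
multiplies rho by a logistic density factor, (1 - N/K_N) for the DN
compartment and (1 - (P + SP4 + SP8)/K) for the other three.

The progenitor influx b(t) is logistic before birth,

    b(t) = b0 / (1 + exp(-beta * (t - tau_b))),

with beta derived so that b(t0) equals exactly one cell (1e-7 units): the
first progenitor activates thymopoiesis at t0.  After birth the influx is
either held constant at b0 (normal thymus) or set to zero (in-silico
progenitor ablation).

Export of mature SP4/SP8 cells (s_04, s_08) leaves the system: exported
cells become peripheral T cells, not apoptotic ones.  D receives only the
death terms and is degraded at rate delta.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import (
    ONE_CELL,
    InfluxMode,
    ModelClass,
    ModelSpec,
    Population,
    StageParameters,
)

__all__ = [
    "proliferation_rate",
    "progenitor_influx",
    "solve_beta",
    "rhs",
    "InfeasibleInfluxError",
]


class InfeasibleInfluxError(ValueError):
    """No admissible logistic steepness reproduces one cell at ``t0``."""


_PROLIF_PAIRS = {
    Population.DN: ("b_N", "c_N"),
    Population.DP: ("b_P", "c_P"),
    Population.SP4: ("b_4", "c_48"),
    Population.SP8: ("b_8", "c_48"),
}


def _decaying_rate(b: float, c: float, t: float, stage: StageParameters, spec: ModelSpec) -> float:
    """Exponentially decreasing proliferation rate of one population.

    Prenatal form: c * b * exp(-b * (t - t0)).  Postnatal form (default,
    absolute clock): c * exp(-b * t), under which the V2 amplitude
    constraint c_post = b_pre * c_pre * exp(b_pre * t0) enforces exact
    continuity at birth whenever the decay rate is carried over unchanged.
    The configurable alternative restarts the prenatal form at birth.
    """
    if stage is spec.postnatal:
        if spec.postnatal_clock == "absolute":
            return c * math.exp(-b * t)
        return c * b * math.exp(-b * (t - spec.birth_time))
    return c * b * math.exp(-b * (t - spec.t0))


def proliferation_rate(
    stage: StageParameters,
    spec: ModelSpec,
    population: Population,
    t: float,
    state=None,
) -> float:
    """Per-capita proliferation rate of one population at time ``t`` (1/day).

    Under M1 the rate is the pure exponential decay above and ``state`` is
    ignored.  Under M2 the logistic density factor is applied and ``state``
    (the five-component state vector) is required.

    Raises ``ValueError`` for t < t0 (before thymopoiesis onset) or an
    unknown population.
    """
    population = Population(population)
    if t < spec.t0 - 1e-12:
        raise ValueError(f"proliferation rate undefined before t0={spec.t0}: t={t}")
    b_name, c_name = _PROLIF_PAIRS[population]
    b = getattr(stage, b_name)
    c = getattr(stage, c_name)
    rate = _decaying_rate(b, c, t, stage, spec)
    if spec.model_class is ModelClass.M2:
        if state is None:
            raise ValueError("M2 proliferation rate requires the state vector")
        N, P, S4, S8 = state[0], state[1], state[2], state[3]
        if population is Population.DN:
            rate *= 1.0 - N / stage.K_N
        else:
            rate *= 1.0 - (P + S4 + S8) / stage.K
    return rate


def progenitor_influx(spec: ModelSpec, t: float, mode=InfluxMode.LOGISTIC) -> float:
    """Progenitor influx b(t) into the DN compartment, 10^7 cells/day."""
    mode = InfluxMode(mode)
    if mode is InfluxMode.ZERO:
        return 0.0
    if mode is InfluxMode.CONSTANT_B0:
        return spec.b0
    if spec.beta is None:
        raise ValueError("beta not derived; call solve_beta first")
    return spec.b0 / (1.0 + math.exp(-spec.beta * (t - spec.tau_b)))


def solve_beta(b0: float, tau_b: float, t0: float) -> float:
    """Derive the logistic steepness from the one-cell-at-onset condition.

    Solves b0 / (1 + exp(-beta (t0 - tau_b))) = 1e-7 in closed form:
    beta = ln(b0/1e-7 - 1) / (tau_b - t0).  Feasibility requires a plateau
    above two cells (b0 > 2e-7, so that beta > 0 and the influx is
    non-decreasing) and t0 < tau_b.
    """
    if tau_b <= t0:
        raise InfeasibleInfluxError(f"tau_b ({tau_b}) must exceed t0 ({t0})")
    ratio = b0 / ONE_CELL - 1.0
    if ratio <= 1.0:
        raise InfeasibleInfluxError(
            f"b0={b0} admits no positive steepness: plateau must exceed 2e-7"
        )
    return math.log(ratio) / (tau_b - t0)


def rhs(
    t: float,
    state,
    delayed_N: float,
    spec: ModelSpec,
    stage: StageParameters,
    influx_mode=InfluxMode.LOGISTIC,
) -> np.ndarray:
    """Time derivative of (N, P, SP4, SP8, D) at ``t``, 10^7 cells/day.

    ``delayed_N`` is N(t - tau_N), supplied by the solver's history.  Under
    the default conveyor delay convention the outflow from DN is
    instantaneous (-s_N N(t)) while the arrival into DP is delayed
    (+s_N N(t - tau_N)); the alternative convention delays both terms.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError(f"negative state components at t={t}: {state}")
    N, P, S4, S8, D = state
    rho_N = proliferation_rate(stage, spec, Population.DN, t, state)
    rho_P = proliferation_rate(stage, spec, Population.DP, t, state)
    rho_4 = proliferation_rate(stage, spec, Population.SP4, t, state)
    rho_8 = proliferation_rate(stage, spec, Population.SP8, t, state)
    influx = progenitor_influx(spec, t, influx_mode)

    dn_outflow = stage.s_N * (delayed_N if spec.delay_convention == "both_delayed" else N)
    dN = rho_N * N - stage.d_N * N - dn_outflow + influx
    dP = rho_P * P - stage.d_P * P - (stage.s_4 + stage.s_8) * P + stage.s_N * delayed_N
    dS4 = rho_4 * S4 - stage.d_4 * S4 - stage.s_04 * S4 + stage.s_4 * P
    dS8 = rho_8 * S8 - stage.d_8 * S8 - stage.s_08 * S8 + stage.s_8 * P
    dD = (
        stage.d_N * N + stage.d_P * P + stage.d_4 * S4 + stage.d_8 * S8
        - stage.delta * D
    )
    return np.array([dN, dP, dS4, dS8, dD])


def ensure_beta(spec: ModelSpec) -> ModelSpec:
    """Return ``spec`` with ``beta`` derived (idempotent)."""
    if spec.beta is None:
        from dataclasses import replace

        return replace(spec, beta=solve_beta(spec.b0, spec.tau_b, spec.t0))
    return spec
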