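"""Method-of-steps integration of the delayed thymocyte system.

The DN->DP differentiation delay tau_N makes the model a delay differential
equation.  Integration proceeds in windows no longer than the current
stage's delay, so the delayed argument N(t - tau_N) always falls inside the
already-computed history, which is queried through the integrator's dense
interpolant.  History before thymopoiesis onset t0 is identically zero: the
thymus is seeded purely through the progenitor influx b(t).

Birth (19.5 dpc) is handled as a hard integration restart: the stage
parameters (and influx regime) may jump there, but the state itself is
continuous.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .model import ensure_beta
from .parameters import (
    InfluxMode,
    ModelClass,
    ModelSpec,
    Population,
    StageParameters,
)

__all__ = ["Trajectory", "BlowUpError", "simulate"]

#: components more negative than this (relative to unit scale) indicate a
#: genuine integration failure rather than floating-point noise
NEGATIVITY_TOLERANCE = 1e-9

_POP_INDEX = {
    Population.DN: 0,
    Population.DP: 1,
    Population.SP4: 2,
    Population.SP8: 3,
}
STATE_NAMES = ("N", "P", "SP4", "SP8", "D")


class BlowUpError(RuntimeError):
    """Integration produced a non-finite or strongly negative state."""

    def __init__(self, t: float, message: str = ""):
        self.t = t
        super().__init__(message or f"integration failed near t={t:.4f} dpc")


@dataclass
class Trajectory:
    """Dense solution of the five-compartment system.

    ``times`` is the strictly increasing solver grid (dpc); ``states`` the
    matching (n, 5) array of (N, P, SP4, SP8, D) in 10^7-cell units.  The
    object is callable for continuous evaluation at arbitrary times,
    returning zeros before t0 and clamping floating-point negatives to 0.
    """

    times: np.ndarray
    states: np.ndarray
    t0: float
    birth_time: float
    t_end: float
    spec: ModelSpec
    influx_mode_postnatal: InfluxMode
    _segments: list = field(default_factory=list, repr=False)

    def __call__(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros((t_arr.size, 5))
        bounds = [seg[0] for seg in self._segments]
        for j, tj in enumerate(t_arr):
            if tj <= self.t0:
                continue
            if tj > self.t_end + 1e-9:
                raise ValueError(f"time {tj} beyond trajectory end {self.t_end}")
            i = bisect.bisect_right(bounds, tj) - 1
            i = max(i, 0)
            lo, hi, sol = self._segments[i]
            out[j] = np.maximum(sol(min(tj, hi)), 0.0)
        return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out

    def population(self, population, t):
        """Evaluate one live population (or 'total' of the four, or 'D')."""
        values = self(t)
        values = np.atleast_2d(values)
        if population in ("total", "live"):
            res = values[:, :4].sum(axis=1)
        elif population in ("D", "apoptotic"):
            res = values[:, 4]
        else:
            res = values[:, _POP_INDEX[Population(population)]]
        return res[0] if np.ndim(t) == 0 else res

    def delayed_N(self, t: float) -> float:
        """N(t) through the dense history; zero before t0."""
        if t <= self.t0:
            return 0.0
        return float(self(t)[0])

    def total_live(self) -> np.ndarray:
        return self.states[:, :4].sum(axis=1)

    def to_frame(self):
        """Tidy table: time_dpc, time_postnatal, N, P, SP4, SP8, D."""
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_postnatal", self.times - self.birth_time)
        df.insert(0, "time_dpc", self.times)
        return df


def _compiled_rhs(spec: ModelSpec, stage: StageParameters, influx_mode: InfluxMode):
    """Bind stage parameters into a fast scalar-closure RHS.

    Mirrors :func:`thymodyn.model.rhs` exactly (asserted by a property
    test); exists because the solver calls it thousands of times per fit.
    """
    b_N, c_N = stage.b_N, stage.c_N
    b_P, c_P = stage.b_P, stage.c_P
    b_4, b_8, c_48 = stage.b_4, stage.b_8, stage.c_48
    s_N, s_4, s_8 = stage.s_N, stage.s_4, stage.s_8
    s_04, s_08 = stage.s_04, stage.s_08
    d_N, d_P, d_4, d_8 = stage.d_N, stage.d_P, stage.d_4, stage.d_8
    delta = stage.delta
    is_m2 = spec.model_class is ModelClass.M2
    K_N = stage.K_N if is_m2 else None
    K = stage.K if is_m2 else None
    both_delayed = spec.delay_convention == "both_delayed"

    # proliferation form, mirroring model._decaying_rate
    if stage is spec.postnatal and spec.postnatal_clock == "absolute":
        t_ref, with_b_prefactor = 0.0, False
    elif stage is spec.postnatal:
        t_ref, with_b_prefactor = spec.birth_time, True
    else:
        t_ref, with_b_prefactor = spec.t0, True
    amp_N = c_N * b_N if with_b_prefactor else c_N
    amp_P = c_P * b_P if with_b_prefactor else c_P
    amp_4 = c_48 * b_4 if with_b_prefactor else c_48
    amp_8 = c_48 * b_8 if with_b_prefactor else c_48

    influx_mode = InfluxMode(influx_mode)
    if influx_mode is InfluxMode.ZERO:
        influx = lambda t: 0.0
    elif influx_mode is InfluxMode.CONSTANT_B0:
        b0 = spec.b0
        influx = lambda t: b0
    else:
        b0, beta, tau_b = spec.b0, spec.beta, spec.tau_b
        if beta is None:
            raise ValueError("beta not derived; call solve_beta first")
        influx = lambda t: b0 / (1.0 + math.exp(-beta * (t - tau_b)))

    def f(t, y, delayed_N):
        N, P, S4, S8, D = y
        dt = t - t_ref
        rho_N = amp_N * math.exp(-b_N * dt)
        rho_P = amp_P * math.exp(-b_P * dt)
        rho_4 = amp_4 * math.exp(-b_4 * dt)
        rho_8 = amp_8 * math.exp(-b_8 * dt)
        if is_m2:
            rho_N *= 1.0 - N / K_N
            factor = 1.0 - (P + S4 + S8) / K
            rho_4 *= factor
            rho_8 *= factor
            rho_P *= factor
        dn_out = s_N * (delayed_N if both_delayed else N)
        return (
            rho_N * N - d_N * N - dn_out + influx(t),
            rho_P * P - d_P * P - (s_4 + s_8) * P + s_N * delayed_N,
            rho_4 * S4 - d_4 * S4 - s_04 * S4 + s_4 * P,
            rho_8 * S8 - d_8 * S8 - s_08 * S8 + s_8 * P,
            d_N * N + d_P * P + d_4 * S4 + d_8 * S8 - delta * D,
        )

    return f


def simulate(
    spec: ModelSpec,
    influx_mode_postnatal=InfluxMode.CONSTANT_B0,
    t_end: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-14,
    method: str = "RK45",
    max_window: Optional[float] = None,
    history_resolution: float = 0.005,
) -> Trajectory:
    """Integrate the model from t0 to ``t_end`` (default: spec horizon).

    The prenatal segment always uses the logistic influx; the postnatal
    segment uses ``influx_mode_postnatal`` (constant b0 or zero).  Under V2
    the postnatal amplitude constraint is applied before integration, and
    beta is derived if unset.  Raises :class:`BlowUpError` with the failure
    time on non-finite or strongly negative states.

    Delayed DN history is evaluated from a uniform fine grid (linear
    interpolation at ``history_resolution`` days, refined below the delay),
    whose interpolation error is far below the default solver tolerances;
    the trajectory itself keeps the integrator's dense interpolant.
    """
    spec = ensure_beta(spec).with_constraint_applied()
    spec.validate()
    t_end = spec.horizon if t_end is None else float(t_end)
    if t_end <= spec.t0:
        raise ValueError(f"t_end={t_end} must exceed t0={spec.t0}")

    segments_plan = []
    if spec.t0 < spec.birth_time:
        segments_plan.append(
            (spec.t0, min(spec.birth_time, t_end), spec.prenatal, InfluxMode.LOGISTIC)
        )
    if t_end > spec.birth_time:
        segments_plan.append(
            (spec.birth_time, t_end, spec.postnatal, InfluxMode(influx_mode_postnatal))
        )

    dense_segments: list = []   # (t_lo, t_hi, OdeSolution)
    times = [spec.t0]
    states = [np.zeros(5)]
    state = np.zeros(5)

    # delayed-N history on a uniform fine grid; zero before and at t0
    hist_t = np.array([spec.t0])
    hist_N = np.array([0.0])

    for seg_start, seg_end, stage, influx_mode in segments_plan:
        f = _compiled_rhs(spec, stage, influx_mode)
        tau = stage.tau_N
        window = seg_end - seg_start if tau <= 0 else tau
        if max_window is not None:
            window = min(window, max_window)
        hist_dt = min(history_resolution, tau / 10) if tau > 0 else history_resolution
        cur = seg_start
        while cur < seg_end - 1e-12:
            w_end = min(cur + window, seg_end)

            if tau > 0:
                ht, hN, _tau = hist_t, hist_N, tau

                def ode(t, y, _f=f, _ht=ht, _hN=hN, _tau=_tau):
                    yc = np.maximum(y, 0.0)
                    td = t - _tau
                    delayed = 0.0 if td <= _ht[0] else float(np.interp(td, _ht, _hN))
                    return _f(t, yc, delayed)
            else:
                def ode(t, y, _f=f):
                    yc = np.maximum(y, 0.0)
                    return _f(t, yc, yc[0])

            sol = solve_ivp(
                ode, (cur, w_end), state,
                method=method, dense_output=True, rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise BlowUpError(cur, f"solver failed in window [{cur}, {w_end}]: {sol.message}")
            if not np.all(np.isfinite(sol.y)):
                bad = np.where(~np.isfinite(sol.y).all(axis=0))[0][0]
                raise BlowUpError(sol.t[bad], f"non-finite state at t={sol.t[bad]:.4f}")
            scale = max(1.0, float(np.nanmax(np.abs(sol.y))))
            if sol.y.min() < -NEGATIVITY_TOLERANCE * scale:
                bad = np.where(sol.y.min(axis=0) < -NEGATIVITY_TOLERANCE * scale)[0][0]
                raise BlowUpError(sol.t[bad], f"strongly negative state at t={sol.t[bad]:.4f}")

            dense_segments.append((cur, w_end, sol.sol))
            times.extend(sol.t[1:])
            states.extend(np.maximum(sol.y[:, 1:], 0.0).T)
            state = np.maximum(sol.y[:, -1], 0.0)
            # extend the delayed-N history grid over the finished window
            n_pts = max(int(np.ceil((w_end - cur) / hist_dt)), 2)
            tgrid = np.linspace(cur, w_end, n_pts + 1)[1:]
            hist_t = np.concatenate([hist_t, tgrid])
            hist_N = np.concatenate(
                [hist_N, np.maximum(sol.sol(tgrid)[0], 0.0)]
            )
            cur = w_end

    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states),
        t0=spec.t0,
        birth_time=spec.birth_time,
        t_end=t_end,
        spec=spec,
        influx_mode_postnatal=InfluxMode(influx_mode_postnatal),
        _segments=dense_segments,
    )
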