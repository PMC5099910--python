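"""Brute-force fixed-step Euler integration of the delayed system.

Deliberately naive: a uniform grid, explicit Euler updates through the
public :func:`thymodyn.model.rhs`, and a plain array ring buffer for the
delayed DN history.  It shares nothing with the method-of-steps engine
except the model definition, which makes it the independent numerical
cross-check for solver correctness (at small step sizes the two must
agree).  It is far too slow for calibration; use :func:`thymodyn.dde.simulate`
for real work.
"""

from __future__ import annotations

import numpy as np

from .model import ensure_beta, rhs
from .parameters import InfluxMode, ModelSpec

__all__ = ["euler_simulate"]


def euler_simulate(
    spec: ModelSpec,
    t_end: float,
    h: float = 1e-3,
    influx_mode_postnatal=InfluxMode.CONSTANT_B0,
):
    """Explicit Euler solution on a uniform grid of step ``h`` days.

    Returns ``(times, states)`` with states clamped at zero (Euler can
    overshoot into tiny negatives).  Delayed evaluation looks up the
    nearest-grid-point history, exact when tau_N is a multiple of ``h``.
    """
    spec = ensure_beta(spec).with_constraint_applied()
    spec.validate()
    n_steps = int(round((t_end - spec.t0) / h))
    times = spec.t0 + h * np.arange(n_steps + 1)
    states = np.zeros((n_steps + 1, 5))
    hist_N = np.zeros(n_steps + 1)

    for i in range(n_steps):
        t = times[i]
        stage = spec.stage_at(t)
        if t < spec.birth_time:
            mode = InfluxMode.LOGISTIC
        else:
            mode = InfluxMode(influx_mode_postnatal)
        tau = stage.tau_N
        if tau <= 0:
            delayed = states[i, 0]
        else:
            k = i - int(round(tau / h))
            delayed = hist_N[k] if k >= 0 else 0.0
        dy = rhs(t, states[i], delayed, spec, stage, mode)
        nxt = np.maximum(states[i] + h * dy, 0.0)
        states[i + 1] = nxt
        hist_N[i + 1] = nxt[0]

    return times, states
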