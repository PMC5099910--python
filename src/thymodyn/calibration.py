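"""Model calibration: MSE objective, AIC scoring, hybrid global/local
fitting, and bootstrap confidence intervals.

Fitting minimizes the mean squared error between transformed observed and
predicted counts (default transform: log10 of counts in 10^7-cell units,
floored at 1e-8 units, appropriate for data spanning several orders of
magnitude).  The optimizer is a differential-evolution-style population
search over box-constrained parameters with periodic Nelder-Mead
refinement of the incumbent.  The logistic steepness beta is re-derived
from (b0, tau_b, t0) at every evaluation; under V2 the postnatal
amplitudes are recomputed from the prenatal ones at every evaluation; the
postnatal DP feasibility constraint s_N > d_P + s_4 + s_8 is enforced by a
death penalty (infinite objective).

Uncertainty is quantified by case-resampling bootstrap: replicates are
resampled with replacement within each (time, population) cell and the
model is re-fit from the incumbent of a preliminary run; percentile
intervals and averages are taken over the re-estimated parameter vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dde import BlowUpError, simulate
from .model import InfeasibleInfluxError, solve_beta
from .parameters import (
    CELLS_PER_UNIT,
    ModelClass,
    ModelSpec,
    Variant,
    count_free_parameters,
    free_parameter_names,
)

__all__ = [
    "POPULATION_LABELS",
    "ObservationSet",
    "SearchRanges",
    "FitResult",
    "BootstrapResult",
    "mse_objective",
    "aic_score",
    "fit",
    "bootstrap_fit",
]

POPULATION_LABELS = ("DN", "DP", "SP4", "SP8", "total", "apoptotic")

#: floor (10^7-cell units) applied before the log10 transform
LOG_FLOOR = 1e-8


class ObservationSet:
    """Replicate-structured thymocyte counts, the calibration target.

    Wraps a tidy table with columns ``time_dpc`` (days post-conception),
    ``population`` (DN/DP/SP4/SP8/total/apoptotic), ``replicate`` (id
    within a time point), and ``count_cells`` (cells, not 10^7 units).
    """

    COLUMNS = ("time_dpc", "population", "replicate", "count_cells")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        bad_pop = ~frame["population"].isin(POPULATION_LABELS)
        if bad_pop.any():
            row = int(np.where(bad_pop)[0][0])
            raise ValueError(
                f"row {row}: unknown population {frame['population'][row]!r}; "
                f"accepted labels: {', '.join(POPULATION_LABELS)}"
            )
        counts = pd.to_numeric(frame["count_cells"], errors="coerce")
        if counts.isna().any():
            row = int(np.where(counts.isna())[0][0])
            raise ValueError(f"row {row}: malformed count_cells")
        if (counts < 0).any():
            row = int(np.where(counts < 0)[0][0])
            raise ValueError(f"row {row}: negative count_cells ({counts[row]})")
        frame["count_cells"] = counts.astype(float)
        frame["time_dpc"] = frame["time_dpc"].astype(float)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, ObservationSet) and self.frame.equals(other.frame)

    @property
    def populations(self) -> list:
        return sorted(self.frame["population"].unique())

    @property
    def max_time(self) -> float:
        return float(self.frame["time_dpc"].max())

    def counts_units(self) -> np.ndarray:
        """Counts on the model's 10^7-cell scale."""
        return self.frame["count_cells"].to_numpy() / CELLS_PER_UNIT

    def resample(self, rng: np.random.Generator) -> "ObservationSet":
        """Case-resampling bootstrap: within each (time, population) cell,
        draw replicates with replacement."""
        pieces = []
        for _, group in self.frame.groupby(["time_dpc", "population"], sort=True):
            idx = rng.integers(0, len(group), size=len(group))
            piece = group.iloc[idx].copy()
            piece["replicate"] = np.arange(len(piece))
            pieces.append(piece)
        return ObservationSet(pd.concat(pieces, ignore_index=True))

    def n_replicates(self) -> int:
        """Maximum replicate multiplicity over (time, population) cells."""
        return int(self.frame.groupby(["time_dpc", "population"]).size().max())


class SearchRanges(dict):
    """Per-parameter box constraints: flat key -> (lower, upper)."""

    def validate(self) -> None:
        for name, (lo, hi) in self.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")

    def arrays(self, names: Sequence[str]):
        lo = np.array([self[n][0] for n in names])
        hi = np.array([self[n][1] for n in names])
        return lo, hi


# -- objective ---------------------------------------------------------------


def predicted_counts(
    spec: ModelSpec, obs: ObservationSet, engine: str = "dense", **sim_kwargs
) -> np.ndarray:
    """Model predictions (10^7-cell units) matching each observation record.

    ``engine="dense"`` uses the adaptive method-of-steps solver;
    ``engine="fast"`` the compiled fixed-step integrator (used inside
    optimization loops, where the forward solve dominates the cost).
    """
    t_end = max(obs.max_time + 1e-6, spec.t0 + 1.0)
    times = np.minimum(obs.frame["time_dpc"].to_numpy(), t_end)
    unique_times, inverse = np.unique(times, return_inverse=True)
    if engine == "fast":
        from .fastsim import fast_states_at

        values = fast_states_at(spec, unique_times, **sim_kwargs)
    elif engine == "dense":
        traj = simulate(spec, t_end=t_end, **sim_kwargs)
        values = np.atleast_2d(traj(np.minimum(unique_times, traj.t_end)))
    else:
        raise ValueError(f"unknown engine {engine!r}")
    per_pop = {
        "DN": values[:, 0], "DP": values[:, 1],
        "SP4": values[:, 2], "SP8": values[:, 3],
        "total": values[:, :4].sum(axis=1), "apoptotic": values[:, 4],
    }
    pops = obs.frame["population"].to_numpy()
    out = np.empty(len(obs))
    for pop in np.unique(pops):
        mask = pops == pop
        out[mask] = per_pop[pop][inverse[mask]]
    return out


def _transform(x: np.ndarray, scale: str, observed: Optional[np.ndarray] = None):
    if scale == "log10":
        return np.log10(np.maximum(x, LOG_FLOOR))
    if scale == "linear":
        return x
    raise ValueError(f"unknown residual scale {scale!r}")


def mse_objective(
    spec: ModelSpec,
    obs: ObservationSet,
    residual_scale: str = "log10",
    engine: str = "dense",
    **sim_kwargs,
) -> float:
    """Mean squared residual between transformed observed and predicted
    counts; +inf when the simulation fails (penalty)."""
    try:
        pred = predicted_counts(spec, obs, engine=engine, **sim_kwargs)
    except (BlowUpError, InfeasibleInfluxError, FloatingPointError, ValueError):
        return math.inf
    observed = obs.counts_units()
    if residual_scale == "relative":
        resid = (pred - observed) / np.maximum(np.abs(observed), LOG_FLOOR)
    else:
        resid = _transform(pred, residual_scale) - _transform(observed, residual_scale)
    return float(np.mean(resid**2))


def aic_score(mse: float, k: int, n: int) -> float:
    """Gaussian least-squares Akaike information criterion, n ln(MSE) + 2k."""
    if n <= 0:
        raise ValueError("n must be positive")
    if mse <= 0:
        raise ValueError("AIC undefined for mse <= 0")
    return n * math.log(mse) + 2 * k


# -- parameter-vector <-> spec mapping ---------------------------------------


class SpecBuilder:
    """Maps a free-parameter vector onto a ModelSpec.

    ``names`` selects which flat keys the vector controls; everything else
    is taken from ``base_spec``.  beta is always re-derived and, under V2,
    postnatal amplitudes are recomputed downstream (in simulate).
    """

    def __init__(self, model_class, variant, names: Sequence[str], base_spec: ModelSpec):
        self.model_class = ModelClass(model_class)
        self.variant = Variant(variant)
        allowed = set(free_parameter_names(self.model_class, self.variant))
        unknown = [n for n in names if n not in allowed]
        if unknown:
            raise ValueError(f"not free parameters of {self.model_class.value}."
                             f"{self.variant.value}: {unknown}")
        self.names = list(names)
        self.base = replace(
            base_spec, model_class=self.model_class, variant=self.variant, beta=None
        )

    def build(self, x: np.ndarray) -> ModelSpec:
        flat = self.base.to_flat_dict()
        flat["beta"] = None
        for name, value in zip(self.names, x):
            flat[name] = float(value)
        return ModelSpec.from_flat_dict(flat)

    def vector(self, spec: ModelSpec) -> np.ndarray:
        flat = spec.to_flat_dict()
        return np.array([flat[n] for n in self.names])


# -- hybrid evolutionary + Nelder-Mead fit -----------------------------------


@dataclass
class FitResult:
    spec: ModelSpec
    params: dict
    mse: float
    aic: Optional[float]
    k: int
    n: int
    n_evals: int
    seed: int
    trace: list = field(default_factory=list)  # best objective per generation
    names: list = field(default_factory=list)

    def vector(self) -> np.ndarray:
        return np.array([self.params[n] for n in self.names])

    def to_dict(self) -> dict:
        return {
            "model_class": self.spec.model_class.value,
            "variant": self.spec.variant.value,
            "params": self.params,
            "mse": self.mse,
            "aic": self.aic,
            "k": self.k,
            "n": self.n,
            "n_evals": self.n_evals,
            "seed": self.seed,
        }


def _default_base_spec(model_class, variant) -> ModelSpec:
    from .synthetic import default_ground_truth

    return default_ground_truth(model_class, variant)


def fit(
    obs: ObservationSet,
    model_class,
    variant,
    ranges: SearchRanges,
    seed: int = 0,
    budget: Optional[int] = None,
    base_spec: Optional[ModelSpec] = None,
    residual_scale: str = "log10",
    popsize: Optional[int] = None,
    max_generations: int = 200,
    nm_every: int = 20,
    nm_maxfev: int = 300,
    stall_generations: int = 30,
    stall_tol: float = 1e-8,
    de_F: Optional[float] = None,  # None: dithered in U(0.5, 1) per generation
    de_CR: float = 0.9,
    init: Optional[np.ndarray] = None,
    engine: str = "fast",
    sim_step: float = 0.02,
    sim_rtol: float = 1e-6,
    sim_atol: float = 1e-12,
    log_scale: bool = True,
    n_starts: int = 1,
) -> FitResult:
    """Fit free parameters by hybrid DE-style search + Nelder-Mead.

    ``ranges`` defines the free parameters (its keys) and their boxes; any
    parameter without a range is clamped at its ``base_spec`` value.  A full
    fit passes ranges for every name in ``free_parameter_names``.
    Deterministic given ``seed``; the incumbent objective is non-increasing
    over generations.

    With ``log_scale`` (default) the search runs in log coordinates for
    parameters with strictly positive lower bounds — rates and amplitudes
    span orders of magnitude and their objective valleys are multiplicative,
    so log space makes the population search far better conditioned.

    ``n_starts > 1`` splits the evaluation budget over independent seeded
    restarts and returns the best fit — the population search occasionally
    locks onto a secondary basin, and restarts are the standard remedy.
    """
    if n_starts > 1:
        start_rng = np.random.default_rng(seed)
        split = None if budget is None else max(budget // n_starts, 1)
        kwargs = dict(
            base_spec=base_spec, residual_scale=residual_scale, popsize=popsize,
            max_generations=max_generations, nm_every=nm_every,
            nm_maxfev=nm_maxfev, stall_generations=stall_generations,
            stall_tol=stall_tol, de_F=de_F, de_CR=de_CR, init=init,
            engine=engine, sim_step=sim_step, sim_rtol=sim_rtol,
            sim_atol=sim_atol, log_scale=log_scale, n_starts=1,
        )
        best = None
        total_evals = 0
        for _ in range(n_starts):
            candidate = fit(obs, model_class, variant, ranges,
                            seed=int(start_rng.integers(2**31)),
                            budget=split, **kwargs)
            total_evals += candidate.n_evals
            if best is None or candidate.mse < best.mse:
                best = candidate
        best.n_evals = total_evals
        best.seed = seed
        return best

    model_class, variant = ModelClass(model_class), Variant(variant)
    ranges = SearchRanges(ranges)
    ranges.validate()
    names = [n for n in free_parameter_names(model_class, variant) if n in ranges]
    if len(names) != len(ranges):
        extra = set(ranges) - set(names)
        raise ValueError(f"ranges contain non-free parameters: {sorted(extra)}")
    if base_spec is None:
        if set(names) != set(free_parameter_names(model_class, variant)):
            raise ValueError("restricted fits require base_spec for clamped parameters")
        base_spec = _default_base_spec(model_class, variant)
    builder = SpecBuilder(model_class, variant, names, base_spec)
    lo_nat, hi_nat = ranges.arrays(names)
    d = len(names)
    sim_kwargs = dict(h=sim_step) if engine == "fast" else dict(rtol=sim_rtol, atol=sim_atol)

    # optional log-coordinate search for strictly positive parameters
    logmask = (lo_nat > 0) if log_scale else np.zeros(d, dtype=bool)

    def to_search(x_nat):
        z = np.array(x_nat, dtype=float)
        z[logmask] = np.log(z[logmask])
        return z

    def to_natural(z):
        x = np.array(z, dtype=float)
        x[logmask] = np.exp(x[logmask])
        return x

    lo, hi = to_search(lo_nat), to_search(hi_nat)

    n_evals = 0

    def objective(z: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        x = np.clip(to_natural(np.clip(z, lo, hi)), lo_nat, hi_nat)
        try:
            spec = builder.build(x)
            spec.beta = solve_beta(spec.b0, spec.tau_b, spec.t0)
            spec = spec.with_constraint_applied()
            spec.validate()
        except (ValueError, InfeasibleInfluxError):
            return math.inf
        if not spec.postnatal.satisfies_dp_constraint():
            return math.inf  # death penalty on the DP feasibility constraint
        return mse_objective(spec, obs, residual_scale, engine=engine, **sim_kwargs)

    rng = np.random.default_rng(seed)
    pop = popsize if popsize is not None else min(15 * d, 600)
    pop = max(pop, 5)
    if budget is None:
        budget = pop * (max_generations + 1) + nm_maxfev * (max_generations // nm_every + 1)

    X = lo + rng.random((pop, d)) * (hi - lo)
    if init is not None:
        X[0] = np.clip(to_search(np.asarray(init, dtype=float)), lo, hi)
    fvals = np.array([objective(x) for x in X])

    best_i = int(np.argmin(fvals))
    best_x, best_f = X[best_i].copy(), float(fvals[best_i])
    trace = [best_f]

    def refine_nm(x0, f0, maxfev):
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-8, "fatol": 1e-10,
                     "adaptive": d >= 6},
        )
        xr = np.clip(res.x, lo, hi)
        return (xr, float(res.fun)) if res.fun < f0 else (x0, f0)

    gen = 0
    stall_anchor = best_f
    stall_count = 0
    while gen < max_generations and n_evals + pop <= budget:
        gen += 1
        # dithered mutation factor: re-drawn each generation, a standard
        # diversity device against premature convergence
        F_gen = rng.uniform(0.5, 1.0) if de_F is None else de_F
        for i in range(pop):
            r = rng.choice(pop, size=3, replace=False)
            while i in r:
                r = rng.choice(pop, size=3, replace=False)
            mutant = X[r[0]] + F_gen * (X[r[1]] - X[r[2]])
            cross = rng.random(d) < de_CR
            cross[rng.integers(d)] = True
            trial = np.clip(np.where(cross, mutant, X[i]), lo, hi)
            f_trial = objective(trial)
            if f_trial <= fvals[i]:
                X[i], fvals[i] = trial, f_trial
                if f_trial < best_f:
                    best_x, best_f = trial.copy(), f_trial
        if gen % nm_every == 0 and math.isfinite(best_f) and n_evals + nm_maxfev <= budget:
            best_x, best_f = refine_nm(best_x, best_f, nm_maxfev)
            worst = int(np.argmax(fvals))
            X[worst], fvals[worst] = best_x.copy(), best_f
        trace.append(best_f)
        if stall_anchor - best_f < stall_tol:
            stall_count += 1
            if stall_count >= stall_generations:
                break
        else:
            stall_anchor, stall_count = best_f, 0

    if math.isfinite(best_f) and n_evals < budget:
        best_x, best_f = refine_nm(best_x, best_f, min(nm_maxfev, budget - n_evals))
    trace.append(best_f)

    if not math.isfinite(best_f):
        raise RuntimeError("budget exhausted without a finite objective")

    from .model import ensure_beta

    best_nat = np.clip(to_natural(best_x), lo_nat, hi_nat)
    best_spec = ensure_beta(builder.build(best_nat)).with_constraint_applied()
    k = count_free_parameters(model_class, variant)
    n = len(obs)
    aic = aic_score(best_f, k, n) if best_f > 0 else None
    return FitResult(
        spec=best_spec,
        params={name: float(v) for name, v in zip(names, best_nat)},
        mse=best_f, aic=aic, k=k, n=n, n_evals=n_evals, seed=seed,
        trace=trace, names=names,
    )


# -- bootstrap ---------------------------------------------------------------


@dataclass
class BootstrapResult:
    fits: list
    names: list
    mean: dict
    ci_lower: dict
    ci_upper: dict
    master_seed: int
    incumbent: FitResult
    complete: bool = True

    @property
    def n_boot(self) -> int:
        return len(self.fits)

    def mean_spec(self) -> ModelSpec:
        """Model at the bootstrap-average parameters (the reference model
        used for downstream scenarios)."""
        builder = SpecBuilder(
            self.incumbent.spec.model_class,
            self.incumbent.spec.variant,
            self.names,
            self.incumbent.spec,
        )
        from .model import ensure_beta

        x = np.array([self.mean[n] for n in self.names])
        return ensure_beta(builder.build(x)).with_constraint_applied()

    def to_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "master_seed": self.master_seed,
            "mean": self.mean,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "incumbent": self.incumbent.to_dict(),
            "complete": self.complete,
        }


def bootstrap_fit(
    obs: ObservationSet,
    model_class,
    variant,
    ranges: SearchRanges,
    n_boot: int = 100,
    master_seed: int = 0,
    base_spec: Optional[ModelSpec] = None,
    n_prelim: int = 10,
    prelim_kwargs: Optional[dict] = None,
    refit_kwargs: Optional[dict] = None,
    retry_cap: int = 3,
    ci: tuple = (2.5, 97.5),
    **fit_kwargs,
) -> BootstrapResult:
    """Bootstrap re-estimation: percentile CIs over ``n_boot`` refits.

    A preliminary stage runs ``n_prelim`` independent fits and keeps the
    best as incumbent; each bootstrap iteration resamples replicates with
    replacement within (time, population) cells and refits starting from
    the incumbent.  Failed refits are retried with fresh derived seeds up
    to ``retry_cap`` times; persistent failures yield a partial result
    flagged ``complete=False``.  Fully reproducible from ``master_seed``.
    """
    import warnings

    if obs.n_replicates() < 2:
        warnings.warn("fewer than 2 replicates per cell: bootstrap resampling degenerates")
    rng = np.random.default_rng(master_seed)
    prelim_kwargs = {**fit_kwargs, **(prelim_kwargs or {})}
    refit_kwargs = {**fit_kwargs, **(refit_kwargs or {})}

    prelim = []
    for _ in range(max(n_prelim, 1)):
        seed = int(rng.integers(2**31))
        try:
            prelim.append(fit(obs, model_class, variant, ranges,
                              seed=seed, base_spec=base_spec, **prelim_kwargs))
        except RuntimeError:
            continue
    if not prelim:
        raise RuntimeError("all preliminary fits failed")
    incumbent = min(prelim, key=lambda r: r.mse)
    x0 = incumbent.vector()

    fits: list = []
    complete = True
    for _ in range(n_boot):
        resample_seed = int(rng.integers(2**31))
        fit_seed = int(rng.integers(2**31))
        sample = obs.resample(np.random.default_rng(resample_seed))
        result = None
        for attempt in range(retry_cap + 1):
            try:
                result = fit(sample, model_class, variant, ranges,
                             seed=fit_seed + attempt, base_spec=base_spec,
                             init=x0, **refit_kwargs)
                break
            except RuntimeError:
                continue
        if result is None:
            complete = False
            continue
        fits.append(result)

    matrix = np.array([r.vector() for r in fits])
    lo_q, hi_q = np.percentile(matrix, ci[0], axis=0), np.percentile(matrix, ci[1], axis=0)
    mean = matrix.mean(axis=0)
    names = incumbent.names
    return BootstrapResult(
        fits=fits,
        names=names,
        mean={n: float(v) for n, v in zip(names, mean)},
        ci_lower={n: float(v) for n, v in zip(names, lo_q)},
        ci_upper={n: float(v) for n, v in zip(names, hi_q)},
        master_seed=master_seed,
        incumbent=incumbent,
        complete=complete and len(fits) == n_boot,
    )
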