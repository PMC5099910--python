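# Methods

## Model structure and assumptions

The thymus is modeled as five well-mixed compartments: the four live
thymocyte populations DN, DP, SP4, SP8 and an apoptotic sink D. All sizes
are in units of 10^7 cells (one cell = 1e-7 units) and time runs on a
single absolute clock in days post-conception (dpc), with birth fixed at
19.5 dpc and the default horizon 730 days after birth (~2-year mouse
lifespan). Postnatal results are reported as `t - 19.5`.

Assumptions baked into the equations:

- **Conveyor flow.** Progenitors enter DN only; DN → DP transfer carries a
  fixed lag `tau_N` (the multi-day differentiation program); DP → SP4/SP8
  transfers are treated as instantaneous (their lag is much shorter);
  SP4/SP8 export (`s_04`, `s_08`) leaves the system — exported cells
  become peripheral T cells, not apoptotic ones.
- **Common death pathway.** Dead cells from every live compartment enter D
  and are degraded at a single rate `delta`. D is a bookkeeping device
  that decouples transfer from death rates during estimation; it is not a
  biological population.
- **Decreasing proliferation.** Per-capita proliferation decays
  exponentially in time. This is what produces involution: once the rate
  falls below the loss rates, every population declines toward the
  influx-supported steady state (or to zero if the influx is ablated).
  Model class M1 uses the decaying rates alone; M2 multiplies them by
  logistic density factors with carrying capacities `K_N` (DN) and `K`
  (the other three live populations jointly).
- **Stage switch at birth.** Prenatal and postnatal stages have separate
  parameter sets (variant V1); the state is continuous across birth but
  rates may jump ("shock of birth"). Variant V2 ties the three postnatal
  proliferation amplitudes to the prenatal stage (below).

### Proliferation forms and the V2 constraint

The prenatal rate is `rho(t) = c * b * exp(-b * (t - t0))`; the postnatal
rate is `rho(t) = c * exp(-b * t)` on the absolute clock. The asymmetric
postnatal form is chosen deliberately: under it, the V2 amplitude formula

    c_post = b_pre * c_pre * exp(b_pre * t0)

is *exactly* a continuity condition on the proliferation function at birth
whenever the decay rate is carried over unchanged (`b_post = b_pre`), and
the formula is dimensionally coherent (the postnatal amplitude absorbs the
1/day factor). No other reading we found makes the constraint a continuity
statement. A restart-at-birth alternative (`rho = c b exp(-b (t - 19.5))`)
remains available via `ModelSpec.postnatal_clock = "birth"` for users who
prefer symmetric forms; under it the V2 formula is applied verbatim but
does not imply continuity, so no continuity test is attached to it.

The shared SP amplitude `c_48` is paired with the SP4 decay rate `b_4` in
the V2 formula; one shared amplitude cannot satisfy the constraint for two
different SP decay rates simultaneously, so a convention was required.

### Progenitor influx

`b(t) = b0 / (1 + exp(-beta (t - tau_b)))` before birth. `beta` is never
estimated: it is solved in closed form from `b(t0) = 1e-7` (one progenitor
cell at onset), which requires `b0 > 2e-7` (plateau above two cells) and
`tau_b > t0`; anything else raises an explicit infeasibility error. After
birth the influx is either constant at `b0` or zero (ablation). The
delay convention for DN→DP transfer (outflow instantaneous, inflow
delayed) is configurable to the both-delayed alternative
(`delay_convention = "both_delayed"`).

Initial condition: all five compartments are zero at `t0` with identically
zero history — the thymus is seeded entirely through `b(t)`.

## Numerical solution

**Reference engine** (`thymodyn.dde.simulate`): method of steps with
adaptive RK45 (`scipy.integrate.solve_ivp`) inside windows no longer than
the current stage's delay, dense interpolants retained for continuous
evaluation, and a hard integration restart at birth so the rate jump never
falls inside a step. The delayed DN history is queried from a uniform fine
grid (default 0.005 day, refined below `tau_N/10`) built from the dense
windows; its linear-interpolation error is ~1e-5 relative on the stiffest
pinned dynamics, far below default tolerances elsewhere. Components in
(-1e-9·scale, 0) are clamped to zero; anything more negative, or
non-finite, raises a blow-up diagnostic carrying the failure time.

**Fitting engine** (`thymodyn.fastsim`): a numba-compiled classical RK4 on
a uniform grid (default 0.02 day, capped at `tau_N/4`, aligned so birth
lands on a node and each step's stage is fixed by its start time).
It agrees with the reference engine to ~6e-4 relative on the pinned ground
truth and runs two orders of magnitude faster — parameter estimation needs
tens of thousands of forward solves. Tests assert the two engines agree;
trajectories, milestones and scenarios always use the reference engine.

**Cross-check oracle** (`thymodyn.reference.euler_simulate`): deliberately
naive explicit Euler with an array ring buffer for the delay, sharing
nothing with the method-of-steps engine except the model definition. The
solver-correctness tests compare the two at h = 1e-3 day on random
moderate-rate instances (relative error < 1e-3); rates are kept moderate
there because explicit Euler's own truncation error, ~r²ht/2, would
otherwise dominate the comparison.

**Milestones.** Emergence is the first time a population reaches one cell
(1e-7 units; the threshold is configurable and the detection interpolates
linearly between solver grid points on the continuous solution).
Composition fractions exclude the apoptotic sink. The DN%/DP% crossing is
the first sign change of the fraction difference, linearly refined, with a
degeneracy flag when the curves coincide from the start. The ablation
difference table uses live populations only for the "Total thymocytes" row
by default (apoptotic inclusion is a switch), and flags — rather than
silently NaN-ing — cells with a zero denominator.

## Calibration

- **Objective.** Mean squared residual between log10-transformed observed
  and predicted counts in 10^7-cell units, floored at 1e-8 units. The log
  scale is the default because counts span four orders of magnitude across
  the design; linear and relative scales are selectable. Failed
  simulations score +inf.
- **Optimizer.** A population search in the differential-evolution family
  (rand/1/bin, binomial crossover CR = 0.9, mutation factor dithered in
  U(0.5, 1) per generation) over box constraints, with Nelder–Mead
  refinement of the incumbent every 20 generations and at termination.
  Positive-bounded parameters are searched in log coordinates — the
  objective valleys of rate/amplitude pairs are multiplicative and log
  space conditions them well. Defaults: population min(15·dim, 600), up to
  200 generations, convergence when the incumbent improves < 1e-8 over 30
  generations. `n_starts` splits the budget over independent restarts and
  keeps the best fit; restarts are the standard defense against a
  secondary basin the search occasionally locks onto. All settings are
  recorded in the fit result; everything is deterministic given the seed.
- **Derived quantities per evaluation.** `beta` is re-solved from
  `(b0, tau_b, t0)` at every objective call; under V2 the postnatal
  amplitudes are recomputed from the prenatal stage at every call; the
  postnatal feasibility constraint `s_N > d_P + s_4 + s_8` (which keeps DP
  above DN in late life) is enforced by a death penalty.
- **Scoring.** `AIC = n ln(MSE) + 2k` (the Gaussian least-squares form),
  with `k` the variant's full free-parameter count and `n` the number of
  observation records. `k` stays at the variant count even for restricted
  fits, so scores of the same variant remain comparable.
- **Bootstrap.** Case resampling: within each (time, population) cell the
  replicates are resampled with replacement; each of `n_boot` (default
  100) refits starts from the incumbent of a preliminary stage (default 10
  independent runs, best kept). Failed refits are retried with derived
  seeds up to a cap; persistent failures yield a partial result flagged
  incomplete. Percentile (2.5/97.5) intervals and per-parameter averages
  are reported; the averaged parameters define the reference model used
  for scenario analysis. All randomness flows from one master seed through
  `numpy.random.default_rng` child draws.

## Synthetic data generator

The generator emulates the staged experimental design the model is meant
for: prenatal samples at E17.5, E18.5, E19.5; postnatal samples at day 0
and every 5 days to day 50, plus day 80; four replicate animals per time
point (a placeholder — replicate counts per point are rarely reported;
recorded in the design file); all four live populations plus apoptotic
counts. Counts are model predictions times independent lognormal factors
with mean 1 and a configurable CV (default 10%; 5% in the low-noise
recovery experiments). Lognormal multiplicative noise was chosen over
additive Gaussian because counts are positive and span four orders of
magnitude; counts stay real-valued since flow-cytometry-derived totals at
the 10^6–10^8 scale are effectively continuous. The generator does not
emulate gating error structure, litter effects, day-night timing jitter,
or inter-animal correlation — so passing recovery tests demonstrate the
estimation machinery under the stated noise model, not robustness to real
cytometry artifacts.

The **pinned ground truth** is a fixed, documented parameter set (not a
fit to any data) chosen once so its simulation reproduces the qualitative
developmental arc reported for the mouse: DN emergence ~E10.5, DP ~3.2
days later, SP4/SP8 within a day of DP, DN%/DP% crossing ~1.7 days before
birth, postnatal expansion peaking at ~1.7×10^8 cells around six weeks,
then involution with DP% staying above DN% through late life; under
ablation, DN is the most affected population at six weeks (~10%), the
other live populations lose well under a few percent there, and every
population approaches full influx dependence by two years. The influx
plateau `b0 = 5e-4` (5,000 cells/day) keeps the postnatal influx small
against the birth pools, consistent with the small reported ablation
effects at peak activity. The V2 ground truth reuses the V1 prenatal stage
with postnatal decay rates near the prenatal ones — the only regime where
the derived amplitudes produce sane postnatal rates — which yields a
modest, early postnatal peak (the constrained variant genuinely fits the
arc less well, consistent with it being the disfavored variant).

## Parameter identifiability

A perturbation smoke test (+20% on each of the 39 M1.V1 free parameters on
dense noiseless data) shows every parameter strictly increases the
objective, but sensitivity spans seven orders of magnitude: prenatal
amplitudes and timing (`pre_c_N`, `pre_c_P`, `t0`, `pre_tau_N`) are
strongest; prenatal SP parameters and the postnatal delay (`post_tau_N`)
are weakly identifiable under the standard design (three prenatal time
points cannot pin the fetal growth curve's shape — the timing cluster
`t0 / pre_b_* / pre_tau_N` trades off along near-flat valleys at 5%
noise). The recovery experiments therefore target a practically
identifiable eight-parameter subset (prenatal DN amplitude plus the
postnatal proliferation pairs, SP amplitude pair, and degradation rate);
weak identifiability of the remainder is a documented property of the
design, not hidden.

## Default tunable parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `t0` | thymopoiesis onset, dpc | 10.3 | first progenitor ~E10.5 |
| `b0` | influx plateau, 10^7 cells/day | 5e-4 | small vs birth pools |
| `tau_b` | influx logistic midpoint, dpc | 14.0 | mid-gestation ramp |
| `tau_N` | DN→DP lag, days | 3.0 pre / 2.0 post | ~3-day differentiation |
| emergence threshold | one cell | 1e-7 units | smallest meaningful count |
| residual scale | log10, floor 1e-8 | — | counts span 4 decades |
| solver | RK45 rtol 1e-8 / atol 1e-14 | — | well below data noise |
| fit engine step | 0.02 day | — | error « 5% noise |
| checkpoints | postnatal days 42, 91, 182, 365, 548, 730 | — | 6 wk – 2 yr |

## Known limitations

- The model is deterministic; no demographic stochasticity or agent-level
  variability, no spatial/stromal structure, no peripheral T-cell
  compartment, no transplantation chimerism.
- Exact continuity of the proliferation function at birth under V2 holds
  only when the postnatal decay rates equal the prenatal ones; V2 as
  estimated constrains amplitudes, not rates.
- Published fit-quality values from real thymus data are not reproducible
  here: the underlying raw observations are not publicly deposited, so
  calibration targets are synthetic by construction and MSE/AIC values are
  comparable only within this package's study conditions.
- Explicit-Euler cross-checks are restricted to moderate-rate instances;
  on the stiffest fetal growth (rates ~4–5/day) the first-order oracle's
  own truncation error exceeds the comparison tolerance at h = 1e-3.
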