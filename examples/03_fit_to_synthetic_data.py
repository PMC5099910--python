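"""Calibrate model parameters to a noisy synthetic study.

A synthetic observation set is generated from the ground truth with 5%
multiplicative noise at the standard design (E17.5-E19.5 prenatally, every
5 postnatal days to day 50 plus day 80, 4 replicates).  Three postnatal
parameters are then re-estimated by the hybrid evolutionary + Nelder-Mead
fitter with everything else clamped.
"""

from thymodyn import SearchRanges, default_ground_truth, fit, simulate_observations
from thymodyn.synthetic import StudyDesign

spec = default_ground_truth("M1", "V1")
obs = simulate_observations(spec, StudyDesign(cv=0.05), seed=42)
print(f"Synthetic study: {len(obs)} records, populations {obs.populations}")

truth = {"post_c_P": 1.005, "post_b_P": 0.06, "post_delta": 0.3}
ranges = SearchRanges({k: (v / 3, v * 3) for k, v in truth.items()})
result = fit(obs, "M1", "V1", ranges, seed=0, base_spec=spec,
             popsize=12, max_generations=40, budget=900, nm_every=10, nm_maxfev=200)

print(f"MSE (log10 residuals) = {result.mse:.3e}, AIC = {result.aic:.1f}, "
      f"k = {result.k} free parameters, n = {result.n} records")
print("Recovered parameters (estimate / truth / relative error):")
for name, value in truth.items():
    est = result.params[name]
    print(f"  {name:11s} {est:8.4f} / {value:7.4f} / {(est - value) / value:+.1%}")
print("At 5% noise the estimates land within a few percent of the values")
print("that generated the data.")
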