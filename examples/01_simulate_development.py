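"""Simulate thymocyte development over a full mouse lifespan and report
the developmental milestones.

The pinned ground-truth model (M1.V1: exponentially decreasing
proliferation, stage-specific parameters) is integrated from the arrival
of the first fetal progenitor (~E10.3) to two years after birth.
"""

from thymodyn import default_ground_truth, milestone_report, simulate

spec = default_ground_truth("M1", "V1")
traj = simulate(spec)
report = milestone_report(traj)

print("Emergence times (days post-conception; E-stage before birth at 19.5):")
for pop, t in report.emergence.items():
    print(f"  {pop.value:4s}  E{t:.2f}")
print(f"DN -> DP delay: {report.dn_dp_delay:.2f} days "
      "(set by the DN->DP differentiation lag plus growth to one cell)")
print(f"DN% = DP% composition crossing: E{report.dn_dp_crossing.time:.2f} "
      "(DP overtakes DN shortly before birth)")
print(f"Peak total thymocytes: {report.peak_total * 1e7:.3g} cells "
      f"on postnatal day {report.peak_time - spec.birth_time:.1f} "
      "(expansion peaks within weeks, then the thymus involutes)")
end = traj(spec.horizon)
print(f"Total at 2 years: {end[:4].sum() * 1e7:.3g} cells "
      "(involuted but never empty)")
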