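"""In-silico progenitor knockout: what happens to the postnatal thymus if
bone-marrow progenitor influx stops at birth?

Two simulations share the prenatal segment and differ only after birth:
influx held constant at its birth plateau b0, versus set to zero.  The
table gives (with - without)/with * 100% per population at standard ages.
"""

from thymodyn import (
    compare_progenitor_ablation,
    default_ground_truth,
    percentage_difference_table,
)

spec = default_ground_truth("M1", "V1")
cmp = compare_progenitor_ablation(spec)
table = percentage_difference_table(cmp)

print("Percentage impact of ablating progenitor influx at birth:")
print(table.to_string(float_format=lambda v: f"{v:6.2f}"))
print()
print("Reading: small DP/SP4/SP8 differences in the first months mean the")
print("thymus develops quasi-normally without external progenitors while it")
print("is most active; DN, fed directly by the influx, is hit first, and by")
print("late life every population depends almost entirely on the influx.")
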