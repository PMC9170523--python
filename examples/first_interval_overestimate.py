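"""Why onset mortality is always overestimated, for any aging model.

A discrete life table makes the mechanism transparent.  Suppose half of all
individuals die in the first age interval and half in the second.  The real
first-interval mortality risk is 0.5.  An individual dying in interval i is
reported in each of its i intervals with probability 1/i, so the reported
first interval collects 0.5/1 + 0.5/2 = 0.75 of the mass: onset mortality
appears as 0.75 instead of 0.5.  This holds for any distribution with mass
beyond the first interval.
"""

from lastseen import discrete_hazards, reported_interval_fractions

lifespans = [0.5, 0.5, 1.5, 1.5]  # half die in interval 1, half in interval 2
table = discrete_hazards(lifespans, width=1.0)
reported = reported_interval_fractions(table.fractions)

print("interval  real fraction  real hazard  reported fraction")
for i, (f, h, fy) in enumerate(zip(table.fractions, table.hazards, reported), start=1):
    print(f"{i:8d}  {f:13.2f}  {h:11.2f}  {fy:17.2f}")

print()
print(
    f"first-interval mortality: real {table.hazards[0]:.2f} vs reported {reported[0]:.2f}\n"
    "Reported lifespans always inflate mortality at the onset of senescence,\n"
    "so the rise of mortality with age is flattened regardless of the model."
)
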