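"""How last-seen ages disguise aging: real vs reported mortality curves.

Builds a Weibull lifespan law with a decelerating increase in mortality
(shape c = 1.25) and prints the mortality risk of the real lifespan next to
that of the reported (last-seen) lifespan at a few ages.  The real risk
rises with age; the reported risk starts far too high and *declines* — the
signature of spurious "negligible senescence".
"""

from lastseen import ReportedLaw, Weibull

model = Weibull(m0=0.0, b=1.0, c=1.25)
law = ReportedLaw(model)

print("age    real hazard    reported hazard")
for age in (0.05, 0.1, 0.25, 0.5, 1.0):
    print(f"{age:4.2f}   {model.hazard(age):11.3f}    {law.hazard(age):15.3f}")

print()
print(
    "The real mortality risk increases with age (actuarial senescence),\n"
    "but the risk inferred from last-seen ages decreases: early mortality\n"
    "is overestimated because every long-lived individual can also be\n"
    "reported young, and late mortality is underestimated."
)
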