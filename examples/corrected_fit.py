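"""Recovering the true aging parameters from last-seen ages.

Simulates a cohort with strongly accelerating mortality (Weibull shape
c = 3), keeps only the reported (last-seen) ages, and compares the naive
Weibull fit with the corrected fit that maximizes the reported-lifespan
likelihood.  The naive fit caps out near 1.5; the corrected fit recovers
the true shape.
"""

from lastseen import Weibull, fit_reported_likelihood, fit_weibull_mle, make_cohort

true = Weibull(m0=0.0, b=1.0, c=3.0)
cohort = make_cohort(true, n=10_000, seed=7)

naive = fit_weibull_mle(cohort.reported)
corrected = fit_reported_likelihood(cohort.reported, "weibull")

print(f"true shape c                 : {true.c:.3f}")
print(f"naive fit to last-seen ages  : c = {naive.params['c']:.3f} (SE {naive.se['c']:.3f})")
print(f"corrected reported-likelihood: c = {corrected.params['c']:.3f} (SE {corrected.se['c']:.3f})")
print()
print("The naive estimate suggests mildly decelerating aging; the corrected")
print("likelihood, which models the uniform last-seen observation process,")
print("recovers the true accelerating-mortality shape from the same data.")
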