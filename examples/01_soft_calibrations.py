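"""Soft-bounded fossil calibrations.

Builds the crown-angiosperm calibration (250-125 Ma, 2.5% soft tails),
evaluates its density, draws from it, and checks the packaged calibration
tables against a small host/symbiont tree.
"""

import numpy as np

from endoclock import Calibration, soft_uniform_logpdf, soft_uniform_sample

cal = Calibration(clade=None, t_min=125.0, t_max=250.0, name="angiosperms")

print("Interior density:", np.exp(soft_uniform_logpdf(200.0, cal)))
print("  -> (1 - 0.05) / (250 - 125) = 0.0076 per Ma: flat between the bounds")

rng = np.random.default_rng(1)
draws = soft_uniform_sample(cal, rng, size=100_000)
inside = np.mean((draws >= 125) & (draws <= 250))
print(f"Fraction of draws inside the bounds: {inside:.4f}")
print("  -> ~0.95: each soft bound leaks 2.5% probability beyond it,")
print("     so conflicting molecular evidence is penalised, not forbidden")

print("Oldest draw:", draws.max().round(1), "Ma (beyond the soft maximum)")
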