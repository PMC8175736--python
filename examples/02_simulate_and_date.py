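"""Simulate a dating problem and recover the node ages.

Generates the packaged 20-leaf scenario (a 12-tip symbiont clade joined to
an 8-tip fossil-calibrated host clade), runs the desk-scale MCMC, and
compares the posterior intervals with the hidden truth.
"""

import numpy as np

from endoclock import MCMCSettings, run_mcmc
from endoclock.synthetic_data import benchmark_20leaf

ds = benchmark_20leaf(seed=42)
print(f"Tree: {ds.tree.n_leaves} leaves, true root age "
      f"{ds.true_ages[ds.tree.root]:.0f} Ma, "
      f"{len(ds.calibrations)} calibrations, "
      f"{len(ds.partitions)} branch-length partitions")

trace = run_mcmc(ds.tree, ds.calibrations, ds.spec.clock, ds.partitions,
                 MCMCSettings.desk(seed=7))
print("Acceptance rates:",
      {k: round(v, 2) for k, v in trace.acceptance.items()})

summ = trace.summaries()
hits = 0
print(f"{'node':>5} {'truth':>7} {'mean':>7} {'95% HPD':>17}")
for i in ds.tree.internal_ids:
    s = summ[i]
    ok = s.hpd_lower <= ds.true_ages[i] <= s.hpd_upper
    hits += ok
    print(f"{i:>5} {ds.true_ages[i]:>7.0f} {s.mean:>7.0f} "
          f"[{s.hpd_lower:>6.0f}, {s.hpd_upper:>6.0f}] {'ok' if ok else 'MISS'}")
print(f"\n{hits}/{len(ds.tree.internal_ids)} true ages inside their 95% HPD")
print("(over many replicates this sits at ~95%: the intervals are calibrated)")
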