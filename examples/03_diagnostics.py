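"""Dating diagnostics: infinite-sites plot, prior-vs-posterior check,
composite across sensitivity schemes.

A low infinite-sites slope means the remaining age uncertainty comes from
the fossil calibrations, not from finite sequence data.  Nodes whose
posterior matches the effective prior were not informed by the data.  The
composite pools several dating schemes into one conservative summary.
"""

from dataclasses import replace

import numpy as np

from endoclock import MCMCSettings, run_mcmc
from endoclock.diagnostics import (composite_posterior,
                                   infinite_sites_regression,
                                   prior_posterior_compare, DatingProblem,
                                   apply_scheme)
from endoclock.synthetic_data import benchmark_20leaf

ds = benchmark_20leaf(seed=42)
settings = MCMCSettings.desk(seed=3)

posterior = run_mcmc(ds.tree, ds.calibrations, ds.spec.clock, ds.partitions,
                     settings)
prior = run_mcmc(ds.tree, ds.calibrations, ds.spec.clock,
                 settings=replace(settings, prior_only=True))

slope, intercept, r2 = infinite_sites_regression(posterior.summaries())
print(f"Infinite-sites fit: width = {intercept:.0f} + {slope:.3f} * mean "
      f"(r^2 = {r2:.2f})")
print("  -> the slope measures calibration-induced uncertainty per Ma of age")

reports = prior_posterior_compare(prior, posterior)
n_inf = sum(r.informative for r in reports)
print(f"Informative nodes: {n_inf}/{len(reports)} "
      "(posterior clearly shifted away from the effective prior)")

# composite across the best-practiced scheme and two alternates
base = DatingProblem(tree=ds.tree, calibrations=ds.calibrations,
                     clock=ds.spec.clock, partitions=list(ds.partitions))
traces = []
for k, name in enumerate(("best", "SinglePartition", "IR")):
    p = apply_scheme(name, base)
    traces.append(run_mcmc(p.tree, p.calibrations, p.clock, p.partitions,
                           replace(settings, seed=settings.seed + k)))
comp = composite_posterior(traces)
root = ds.tree.root
print(f"Composite root age: {comp[root].mean:.0f} Ma "
      f"(95% HPD {comp[root].hpd_lower:.0f}-{comp[root].hpd_upper:.0f})")
print("  -> pooling schemes widens the interval: scheme choice is itself "
      "a source of uncertainty")
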