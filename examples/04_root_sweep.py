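"""Root-maximum sensitivity: endosymbiosis-style vs root-anchored calibration.

Two matched worlds share the same tree, rates and data.  In the first
(``mito_like``) internal host-clade nodes carry minimum AND maximum fossil
bounds; in the second (``cyano_like``) internal calibrations are minima
only and the root carries the sole maximum.  Sweeping the root maximum
shows how much each design leans on that (often arbitrary) choice.
"""

import numpy as np

from endoclock import MCMCSettings
from endoclock.diagnostics import root_sweep
from endoclock.synthetic_data import ScenarioSpec, matched_pair

spec = ScenarioSpec(seed=300)
mito, cyano = matched_pair(spec)
grid = np.array([1.2, 1.6, 2.0, 2.4]) * spec.root_age
clades = [i for i in mito.tree.internal_ids
          if i != mito.tree.root and i not in mito.host_node_ids][:4]
settings = MCMCSettings(burn_in=8000, sample_every=10, n_samples=800, seed=77)

for name, ds in (("mito-like", mito), ("cyano-like", cyano)):
    res = root_sweep(ds.tree, ds.calibrations, grid, ds.spec.clock,
                     ds.partitions, settings, clade_nodes=clades)
    print(f"{name:>11}: mean slope of posterior age vs root max = "
          f"{res.slopes.mean():.3f} Ma/Ma")
print("\nA smaller slope means the dates barely move when the root maximum")
print("is inflated: internal min+max calibrations (the endosymbiosis-style")
print("design) decouple the analysis from the root calibration.")
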