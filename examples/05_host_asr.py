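"""Ancestral host-lifestyle reconstruction with Bayes-factor model choice.

Simulates a binary animal/protist host character with strongly asymmetric
transition rates on a 100-tip tree, reconstructs the ancestral states, and
compares the free two-rate model against equal rates by stepping-stone
marginal likelihoods.
"""

import numpy as np

from endoclock.host_asr import (ExponentialRatePrior, Mk2Params,
                                log_bayes_factor, marginal_anc_states,
                                run_asr_mcmc)
from endoclock.synthetic_data import simulate_bd_tree, simulate_host_states

rng = np.random.default_rng(5)
tree = simulate_bd_tree(100, 2e-3, 0.0, 1800.0, rng)
L = float(np.nansum(tree.edge_lengths_from_ages()))
q_ap = 20.0 / L * 11.0 / 20.0      # ~20 transitions over the tree
params = Mk2Params(q_ap, 10 * q_ap)  # protist->animal 10x faster
chars = simulate_host_states(tree, params, rng)
n_a = sum(1 for s in chars.states.values() if s == "A")
print(f"Simulated tips: {n_a} animal-associated, {100 - n_a} protist-associated")

prior = ExponentialRatePrior(mean=20.0 / L)
res = run_asr_mcmc(tree, chars, prior=prior, seed=1, n_samples=1000)
ratio = np.mean(res.q_pa / res.q_ap)
print(f"Posterior mean q_PA/q_AP = {ratio:.1f} (simulated with 10)")

marg = res.marginals
print(f"Root P(animal-associated) = {marg[tree.root, 0]:.2f}")

bf = log_bayes_factor(tree, chars, seed=1, prior=prior)
print(f"logBF (2 x logML difference, free vs equal rates) = {bf:.1f}")
print("  -> positive favours rate asymmetry; >10 is 'very strong' on this")
print("     scale.  With only ~20 simulated transitions the attainable")
print("     evidence is modest; real data sets with more transitions give")
print("     much larger values.")
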