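"""Two-state host-lifestyle CTMC: pruning, marginals, MCMC, stepping stone."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from endoclock.host_asr import (ExponentialRatePrior, HostCharacterMatrix,
                                Mk2Params, beta_ladder, log_bayes_factor,
                                marginal_anc_states, pruning_loglik,
                                run_asr_mcmc, stepping_stone,
                                stepping_stone_logml, transition_matrix)
from endoclock.synthetic_data import simulate_bd_tree, simulate_host_states
from endoclock.treedata import parse_newick


class TestTransitionMatrix:
    def test_zero_time_identity(self):
        P = transition_matrix(Mk2Params(0.3, 0.6), 0.0)
        np.testing.assert_array_equal(P, np.eye(2))

    def test_long_time_stationary(self):
        p = Mk2Params(0.3, 0.6)
        P = transition_matrix(p, 1e6)
        pi = p.root_distribution()
        np.testing.assert_allclose(P, np.vstack([pi, pi]), atol=1e-12)

    def test_matches_matrix_exponential(self):
        q_ap, q_pa, t = 0.3, 0.6, 0.7
        Q = np.array([[-q_ap, q_ap], [q_pa, -q_pa]])
        P = transition_matrix(Mk2Params(q_ap, q_pa), t)
        np.testing.assert_allclose(P, expm(Q * t), atol=1e-10)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(Mk2Params(0.1, 0.1), -1.0)


def star_two_tips(eps=0.0):
    t = parse_newick(f"(A:{eps},B:{eps});")
    return t


class TestPruning:
    def test_two_tips_zero_branches_uniform_root(self):
        """Both tips state A on zero-length branches: likelihood = P(root=A)."""
        tree = star_two_tips(0.0)
        chars = HostCharacterMatrix({"A": "A", "B": "A"})
        params = Mk2Params(0.3, 0.6, root="uniform")
        assert np.exp(pruning_loglik(tree, chars, params)) == pytest.approx(0.5)

    def test_frozen_chain(self):
        tree = parse_newick("(A:1,B:2);")
        params = Mk2Params(0.0, 0.0, root="uniform")
        mono = HostCharacterMatrix({"A": "A", "B": "A"})
        poly = HostCharacterMatrix({"A": "A", "B": "P"})
        assert np.exp(pruning_loglik(tree, mono, params)) == pytest.approx(0.5)
        assert pruning_loglik(tree, poly, params) == -np.inf

    def test_matches_exhaustive_enumeration(self, rng):
        """Brute-force sum over ancestral assignments on 3- and 4-tip trees."""
        for newick in ("((A:0.2,B:0.3):0.4,C:0.5);",
                       "((A:0.2,B:0.3):0.1,(C:0.4,D:0.1):0.6);"):
            tree = parse_newick(newick)
            chars = HostCharacterMatrix({
                tree.labels[i]: ("A", "P", "?")[int(rng.integers(3))]
                for i in tree.leaf_ids})
            params = Mk2Params(0.4, 0.9)
            internals = tree.internal_ids
            el = tree.edge_lengths
            pi = params.root_distribution()
            tip_part = {"A": [1.0, 0.0], "P": [0.0, 1.0], "?": [1.0, 1.0]}
            total = 0.0
            for assign in itertools.product((0, 1), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                pr = pi[amap[tree.root]]
                for i in range(tree.n_nodes - 1):
                    P = transition_matrix(params, float(el[i]))
                    sp = amap[int(tree.parent[i])]
                    if tree.is_leaf(i):
                        pr *= float(P[sp] @ tip_part[chars[tree.labels[i]]])
                    else:
                        pr *= P[sp, amap[i]]
                total += pr
            assert pruning_loglik(tree, chars, params) == pytest.approx(
                np.log(total), abs=1e-10)

    def test_missing_tip_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="without states"):
            pruning_loglik(tree, HostCharacterMatrix({"A": "A"}),
                           Mk2Params(0.1, 0.1))

    def test_relabeling_invariance(self):
        """Swapping tips with identical states and branch lengths leaves the
        likelihood unchanged."""
        t1 = parse_newick("((A:0.2,B:0.2):0.3,C:0.5);")
        t2 = parse_newick("((B:0.2,A:0.2):0.3,C:0.5);")
        chars = HostCharacterMatrix({"A": "A", "B": "A", "C": "P"})
        params = Mk2Params(0.4, 0.8)
        assert pruning_loglik(t1, chars, params) == pytest.approx(
            pruning_loglik(t2, chars, params), rel=1e-12)


class TestMarginals:
    def test_rows_sum_to_one(self, rng):
        tree = simulate_bd_tree(12, 2e-3, 0, 1000, rng)
        chars = simulate_host_states(tree, Mk2Params(2e-3, 4e-3), rng)
        marg = marginal_anc_states(tree, chars, Mk2Params(2e-3, 4e-3))
        np.testing.assert_allclose(marg.sum(axis=1), 1.0, atol=1e-12)

    def test_all_tips_animal_pulls_root(self):
        tree = parse_newick("((A:0.5,B:0.5):0.5,C:1);")
        chars = HostCharacterMatrix({"A": "A", "B": "A", "C": "A"})
        marg = marginal_anc_states(tree, chars, Mk2Params(0.3, 0.3,
                                                          root="uniform"))
        assert marg[tree.root, 0] > 0.5

    def test_matches_exhaustive_enumeration(self, rng):
        tree = parse_newick("((A:0.2,B:0.3):0.1,(C:0.4,D:0.1):0.6);")
        chars = HostCharacterMatrix({"A": "A", "B": "P", "C": "?", "D": "P"})
        params = Mk2Params(0.5, 1.1)
        marg = marginal_anc_states(tree, chars, params)
        internals = tree.internal_ids
        el = tree.edge_lengths
        pi = params.root_distribution()
        tip_part = {"A": [1.0, 0.0], "P": [0.0, 1.0], "?": [1.0, 1.0]}
        joint = {}
        for assign in itertools.product((0, 1), repeat=len(internals)):
            amap = dict(zip(internals, assign))
            pr = pi[amap[tree.root]]
            for i in range(tree.n_nodes - 1):
                P = transition_matrix(params, float(el[i]))
                sp = amap[int(tree.parent[i])]
                if tree.is_leaf(i):
                    pr *= float(P[sp] @ tip_part[chars[tree.labels[i]]])
                else:
                    pr *= P[sp, amap[i]]
            joint[assign] = pr
        z = sum(joint.values())
        for k, node in enumerate(internals):
            p_a = sum(v for a, v in joint.items() if a[k] == 0) / z
            assert marg[node, 0] == pytest.approx(p_a, abs=1e-10)


class TestAsrMcmc:
    def test_prior_only_matches_exponential(self, rng):
        tree = simulate_bd_tree(10, 2e-3, 0, 1000, rng)
        chars = simulate_host_states(tree, Mk2Params(2e-3, 2e-3), rng)
        prior = ExponentialRatePrior(mean=0.005)
        res = run_asr_mcmc(tree, chars, prior=prior, prior_only=True,
                           n_samples=20000, burn_in=2000, sample_every=6,
                           seed=1, compute_marginals=False)
        ks = stats.kstest(res.q_ap, "expon", args=(0, 0.005))
        assert ks.statistic < 0.01

    def test_rate_ratio_recovery(self, rng):
        """10-fold asymmetry on a 200-tip tree: posterior ratio > 1."""
        hits = 0
        for seed in range(8):
            r = np.random.default_rng(seed)
            tree = simulate_bd_tree(200, 2e-3, 0, 1800, r)
            L = float(np.nansum(tree.edge_lengths_from_ages()))
            qa = 40.0 / L * 11.0 / 20.0
            chars = simulate_host_states(tree, Mk2Params(qa, 10 * qa), r)
            prior = ExponentialRatePrior(mean=40.0 / L)
            res = run_asr_mcmc(tree, chars, prior=prior, seed=seed,
                               n_samples=400, burn_in=400,
                               compute_marginals=False)
            hits += np.mean(res.q_pa / res.q_ap) > 1.0
        assert hits >= 7

    def test_fixed_seed_reproducible(self, rng):
        tree = simulate_bd_tree(10, 2e-3, 0, 1000, rng)
        chars = simulate_host_states(tree, Mk2Params(2e-3, 6e-3), rng)
        a = run_asr_mcmc(tree, chars, seed=5, n_samples=200, burn_in=200,
                         compute_marginals=False)
        b = run_asr_mcmc(tree, chars, seed=5, n_samples=200, burn_in=200,
                         compute_marginals=False)
        np.testing.assert_array_equal(a.q_ap, b.q_ap)

    def test_single_observed_state_warns(self, rng):
        tree = parse_newick("(A:1,B:1);")
        chars = HostCharacterMatrix({"A": "A", "B": "A"})
        with pytest.warns(UserWarning, match="identifiable"):
            run_asr_mcmc(tree, chars, n_samples=50, burn_in=50,
                         compute_marginals=False)


class TestSteppingStone:
    def test_beta_ladder_monotone_dense_near_zero(self):
        b = beta_ladder(32)
        assert b[0] == 0.0 and b[-1] == 1.0
        assert np.all(np.diff(b) > 0)
        assert np.sum(b < 0.1) > 16  # dense near the prior
        with pytest.raises(ValueError):
            beta_ladder(4)

    def test_beta_binomial_conjugate_oracle(self, rng):
        """Binomial likelihood + Beta(2,3) prior: analytic marginal."""
        from scipy.special import betaln, comb

        n, k = 30, 21
        a0, b0 = 2.0, 3.0

        def sample_prior(r):
            return r.beta(a0, b0)

        def loglik(p):
            return float(stats.binom.logpmf(k, n, p))

        def propose(p, r):
            q = np.clip(p + r.normal() * 0.15, 1e-9, 1 - 1e-9)
            dlp = stats.beta.logpdf(q, a0, b0) - stats.beta.logpdf(p, a0, b0)
            return q, dlp, 0.0

        est = stepping_stone(sample_prior, loglik, propose, K=32,
                             n_per_rung=400, burn_per_rung=100,
                             rng=np.random.default_rng(8))
        analytic = (np.log(comb(n, k))
                    + betaln(k + a0, n - k + b0) - betaln(a0, b0))
        assert est == pytest.approx(analytic, abs=0.05)

    def test_fixed_model_logml_equals_loglik(self, rng):
        """A model with no free parameters integrates to its likelihood."""
        tree = simulate_bd_tree(10, 2e-3, 0, 1000, rng)
        chars = simulate_host_states(tree, Mk2Params(2e-3, 4e-3), rng)
        fixed = Mk2Params(2e-3, 4e-3)
        ll = pruning_loglik(tree, chars, fixed)

        est = stepping_stone(lambda r: fixed,
                             lambda p: pruning_loglik(tree, chars, p),
                             lambda p, r: (p, 0.0, 0.0),
                             K=8, n_per_rung=20, burn_per_rung=5,
                             rng=np.random.default_rng(0))
        assert est == pytest.approx(ll, abs=1e-9)

    def test_self_comparison_near_zero(self, rng):
        tree = simulate_bd_tree(20, 2e-3, 0, 1000, rng)
        chars = simulate_host_states(tree, Mk2Params(2e-3, 4e-3), rng)
        a = stepping_stone_logml(tree, chars, model="free", seed=1,
                                 n_per_rung=200, burn_per_rung=100)
        b = stepping_stone_logml(tree, chars, model="free", seed=2,
                                 n_per_rung=200, burn_per_rung=100)
        assert 2 * abs(a - b) < 1.5  # Monte-Carlo error scale

    def test_variance_shrinks_with_more_rungs(self, rng):
        """Doubling K reduces the spread of repeated estimates."""
        tree = simulate_bd_tree(15, 2e-3, 0, 1000, rng)
        chars = simulate_host_states(tree, Mk2Params(3e-3, 6e-3), rng)

        def spread(K):
            vals = [stepping_stone_logml(tree, chars, model="free", K=K,
                                         n_per_rung=50, burn_per_rung=25,
                                         seed=s) for s in range(6)]
            return np.var(vals)

        assert spread(32) < spread(8) * 1.5  # allow noise, expect shrink

    def test_invalid_model_rejected(self, rng):
        tree = simulate_bd_tree(6, 2e-3, 0, 1000, rng)
        chars = simulate_host_states(tree, Mk2Params(1e-3, 1e-3), rng)
        with pytest.raises(ValueError):
            stepping_stone_logml(tree, chars, model="both")
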