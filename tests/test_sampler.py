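"""MCMC sampler, HPD/ESS summaries, convergence checks."""

import numpy as np
import pytest
from scipy import integrate, stats

from endoclock.calibration import Calibration, CalibrationSet, soft_uniform_logpdf
from endoclock.clock import ClockConfig, FixedPrior, GammaPrior
from endoclock.sampler import (MCMCSettings, ess, hpd, run_mcmc,
                               two_chain_check)
from endoclock.treedata import CladeSpec, parse_newick


class TestHpd:
    def test_constant_samples(self):
        lo, hi = hpd(np.full(100, 3.0), 0.95)
        assert (lo, hi) == (3.0, 3.0)

    def test_matches_exhaustive_window_scan(self, rng):
        x = rng.normal(size=1000)
        lo, hi = hpd(x, 0.95)
        xs = np.sort(x)
        k = int(np.ceil(0.95 * 1000))
        best = min((xs[j + k - 1] - xs[j], j) for j in range(1000 - k + 1))
        assert (lo, hi) == (xs[best[1]], xs[best[1] + k - 1])

    def test_contains_requested_mass(self, rng):
        x = rng.exponential(size=2000)
        lo, hi = hpd(x, 0.95)
        assert np.mean((x >= lo) & (x <= hi)) >= 0.95

    def test_insufficient_samples(self):
        with pytest.raises(ValueError):
            hpd([1.0], 0.95)


class TestEss:
    def test_iid_normals_near_n(self, rng):
        x = rng.normal(size=10**4)
        assert ess(x) == pytest.approx(10**4, rel=0.15)

    def test_ar1_chain_analytic(self, rng):
        """AR(1) with rho=0.5 has ESS = N (1-rho)/(1+rho) = N/3."""
        n, rho = 10**5, 0.5
        eps = rng.normal(size=n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        assert ess(x) == pytest.approx(n / 3, rel=0.1)

    def test_constant_chain_warns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert ess(np.ones(100)) == 0.0

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            ess(np.arange(5))


class TestTwoChainCheck:
    def test_identical_traces_pass(self):
        chains = {"a": np.arange(100.0), "b": np.ones(100)}
        report = two_chain_check(chains, chains, tol=0.01)
        assert report.passed and max(report.rel_diff.values()) == 0.0

    def test_shifted_parameter_flagged(self):
        a = {"x": np.full(100, 1000.0), "y": np.full(100, 10.0)}
        b = {"x": np.full(100, 1100.0), "y": np.full(100, 10.0)}
        report = two_chain_check(a, b, tol=0.05)
        assert report.failed == ["x"]

    def test_mismatched_parameters_rejected(self):
        with pytest.raises(ValueError):
            two_chain_check({"x": np.ones(10)}, {"y": np.ones(10)})

    def test_two_seeds_on_benchmark_agree(self, benchmark_dataset):
        from dataclasses import replace

        ds = benchmark_dataset
        settings = MCMCSettings.desk(seed=21)
        a = run_mcmc(ds.tree, ds.calibrations, ds.spec.clock, ds.partitions,
                     settings)
        b = run_mcmc(ds.tree, ds.calibrations, ds.spec.clock, ds.partitions,
                     replace(settings, seed=22))
        report = two_chain_check(a, b, tol=0.05)
        assert report.passed, report.failed
        assert report.correlation > 0.999


class TestPriorOnly:
    def test_root_marginal_matches_soft_uniform(self):
        """Prior-only chain on a single calibrated root reproduces the
        calibration density (KS < 0.01 at 2e4 samples)."""
        tree = parse_newick("(A:1,B:1);", dating=True)
        cal = Calibration(clade=None, t_min=1000, t_max=3000, name="root")
        trace = run_mcmc(tree, CalibrationSet([cal]), ClockConfig(),
                         settings=MCMCSettings(burn_in=20000, sample_every=10,
                                               n_samples=20000, seed=3,
                                               prior_only=True))
        x = np.sort(trace.node_ages(tree.root))
        grid = np.linspace(1.0, 8000.0, 2001)
        pdf = np.exp(soft_uniform_logpdf(grid, cal))
        cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0)
        cdf /= cdf[-1]
        emp = np.searchsorted(x, grid) / x.size
        assert np.max(np.abs(emp - cdf)) < 0.01

    def test_uncalibrated_node_between_neighbors(self, three_leaf_tree,
                                                 small_calset):
        """An uncalibrated node's prior mass lies between the bounds of its
        calibrated descendant and ancestor."""
        cals = CalibrationSet([
            Calibration(clade=None, t_min=1000, t_max=3000, name="root"),
            Calibration(clade=CladeSpec.of("A", "B"), t_min=450, t_max=509,
                        name="ab"),
        ])
        # 4-leaf tree: ((A,B),inner) with an uncalibrated node above AB
        tree = parse_newick("(((A:1,B:1):1,C:2):1,D:3);", dating=True)
        trace = run_mcmc(tree, cals, ClockConfig(),
                         settings=MCMCSettings.desk(seed=5, prior_only=True))
        ab = tree.mrca([tree.taxon_to_id["A"], tree.taxon_to_id["B"]])
        mid = int(tree.parent[ab])  # uncalibrated, sandwiched
        x = trace.node_ages(mid)
        # nearly all mass between the AB calibration's floor and the root cap
        assert np.mean((x > 450) & (x < 3000)) > 0.99

    def test_mixing_move_leaves_prior_invariant(self, three_leaf_tree,
                                                small_calset):
        """Scaling moves must preserve the stationary distribution: chains
        with and without them agree (two-sample KS within its 99% critical
        band at these sizes)."""
        kw = dict(burn_in=20000, sample_every=10, n_samples=10000,
                  prior_only=True)
        a = run_mcmc(three_leaf_tree, small_calset, ClockConfig(),
                     settings=MCMCSettings(seed=1, **kw))
        b = run_mcmc(three_leaf_tree, small_calset, ClockConfig(),
                     settings=MCMCSettings(seed=2, disable_scaling_moves=True,
                                           **kw))
        for k in range(a.ages.shape[1]):
            assert stats.ks_2samp(a.ages[:, k], b.ages[:, k]).pvalue > 0.01


class TestPosterior:
    def test_identical_seeds_identical_traces(self, benchmark_dataset):
        ds = benchmark_dataset
        s = MCMCSettings.desk(seed=33)
        a = run_mcmc(ds.tree, ds.calibrations, ds.spec.clock, ds.partitions, s)
        b = run_mcmc(ds.tree, ds.calibrations, ds.spec.clock, ds.partitions, s)
        np.testing.assert_array_equal(a.ages, b.ages)
        np.testing.assert_array_equal(a.mu, b.mu)

    def test_every_sample_respects_ordering(self, benchmark_trace,
                                            benchmark_dataset):
        tr = benchmark_trace
        tree = benchmark_dataset.tree
        col = {i: k for k, i in enumerate(tr.node_ids)}
        for i in range(tree.n_nodes - 1):
            p = int(tree.parent[i])
            child = tr.ages[:, col[i]] if i in col else np.zeros(tr.n_samples)
            assert np.all(tr.ages[:, col[p]] > child)

    def test_mu_recovery_within_two_sd(self, benchmark_dataset,
                                       benchmark_trace):
        ds, tr = benchmark_dataset, benchmark_trace
        post_mean, post_sd = tr.mu.mean(), tr.mu.std()
        assert abs(post_mean - ds.true_mu) < 2.5 * post_sd

    def test_partitions_required_without_prior_only(self, three_leaf_tree,
                                                    small_calset):
        with pytest.raises(ValueError, match="partitions"):
            run_mcmc(three_leaf_tree, small_calset, ClockConfig(),
                     settings=MCMCSettings.desk(seed=0))

    def test_trace_tsv_round_trip(self, benchmark_trace, tmp_path):
        import pandas as pd

        path = tmp_path / "trace.tsv"
        benchmark_trace.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == benchmark_trace.n_samples
        assert f"age_{benchmark_trace.node_ids[0]}" in df.columns

    def test_ir_clock_runs(self, benchmark_dataset):
        from dataclasses import replace

        ds = benchmark_dataset
        clock = replace(ds.spec.clock, model="IR",
                        sigma2_prior=GammaPrior(2.0, 0.3))
        tr = run_mcmc(ds.tree, ds.calibrations, clock, ds.partitions,
                      MCMCSettings(burn_in=5000, sample_every=5,
                                   n_samples=500, seed=9))
        assert np.isfinite(tr.log_posterior).all()

    def test_fixed_hyperpriors_not_sampled(self, three_leaf_tree,
                                           small_calset):
        clock = ClockConfig(mu_prior=FixedPrior(2e-4),
                            sigma2_prior=FixedPrior(5e-4))
        tr = run_mcmc(three_leaf_tree, small_calset, clock,
                      settings=MCMCSettings.desk(seed=4, prior_only=True))
        assert np.all(tr.mu == 2e-4) and np.all(tr.sigma2 == 5e-4)

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            MCMCSettings(burn_in=0)
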