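"""Dating diagnostics: infinite-sites fit, prior/posterior comparison,
composites, root sweep, scheme registry."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from endoclock.calibration import Calibration, CalibrationSet
from endoclock.clock import ClockConfig
from endoclock.diagnostics import (DatingProblem, SCHEMES, apply_scheme,
                                   composite_posterior,
                                   infinite_sites_regression,
                                   prior_posterior_compare, root_sweep)
from endoclock.sampler import MCMCSettings, NodeSummary, hpd, run_mcmc


def make_summaries(means, widths):
    return [NodeSummary(i, m, m - w / 2, m + w / 2)
            for i, (m, w) in enumerate(zip(means, widths))]


class TestInfiniteSites:
    def test_exact_line(self):
        means = np.array([100.0, 500.0, 1500.0, 2400.0])
        slope, intercept, r2 = infinite_sites_regression(
            make_summaries(means, 0.3 * means))
        assert slope == pytest.approx(0.3)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_constant_widths_zero_slope(self):
        means = np.array([100.0, 500.0, 1500.0])
        slope, _, _ = infinite_sites_regression(
            make_summaries(means, np.full(3, 50.0)))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        means = rng.uniform(100, 2000, 50)
        widths = rng.uniform(10, 500, 50)
        slope, intercept, r2 = infinite_sites_regression(
            make_summaries(means, widths))
        X = np.column_stack([np.ones(50), means])
        beta = np.linalg.solve(X.T @ X, X.T @ widths)
        assert intercept == pytest.approx(beta[0], rel=1e-9)
        assert slope == pytest.approx(beta[1], rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            infinite_sites_regression(make_summaries([5.0, 5.0, 5.0],
                                                     [1, 2, 3]))
        with pytest.raises(ValueError):
            infinite_sites_regression(make_summaries([1.0, 2.0], [1, 1]))


class FakeTrace:
    """Minimal stand-in exposing the PosteriorTrace age interface."""

    def __init__(self, node_ids, ages):
        self.node_ids = list(node_ids)
        self.ages = np.asarray(ages, dtype=float)
        self.n_samples = self.ages.shape[0]

    def node_ages(self, i):
        return self.ages[:, self.node_ids.index(i)]


class TestPriorPosteriorCompare:
    def test_identical_traces_uninformative(self, benchmark_trace):
        reports = prior_posterior_compare(benchmark_trace, benchmark_trace)
        assert all(not r.informative for r in reports)
        assert all(r.ks_statistic == 0 for r in reports)

    def test_shifted_posterior_flagged_informative(self, rng):
        prior = FakeTrace([0, 1], rng.normal(1000, 100, size=(4000, 2)))
        shifted = FakeTrace([0, 1], prior.ages + 50.0)  # half a prior SD
        reports = prior_posterior_compare(prior, shifted)
        assert all(r.informative for r in reports)
        assert all(abs(r.mean_shift - 50.0) < 1e-9 for r in reports)

    def test_mismatched_nodes_rejected(self, rng):
        a = FakeTrace([0], rng.normal(size=(100, 1)))
        b = FakeTrace([1], rng.normal(size=(100, 1)))
        with pytest.raises(ValueError):
            prior_posterior_compare(a, b)

    def test_empty_trace_rejected(self):
        a = FakeTrace([0], np.empty((0, 1)))
        with pytest.raises(ValueError):
            prior_posterior_compare(a, a)


class TestComposite:
    def test_identical_traces_equal_individual(self, rng):
        ages = rng.normal(1000, 80, size=(3000, 2))
        t = FakeTrace([3, 7], ages)
        comp = composite_posterior([t, t, t])
        lo, hi = hpd(np.concatenate([ages[:, 0]] * 3), 0.95)
        assert comp[3].mean == pytest.approx(ages[:, 0].mean())
        assert (comp[3].hpd_lower, comp[3].hpd_upper) == (lo, hi)

    def test_two_point_masses_average(self):
        a = FakeTrace([0], np.full((1000, 1), 1000.0))
        b = FakeTrace([0], np.full((1000, 1), 2000.0))
        comp = composite_posterior([a, b])
        assert comp[0].mean == pytest.approx(1500.0)

    def test_pooled_hpd_matches_concatenation(self, rng):
        xa = rng.normal(800, 60, size=(2000, 1))
        xb = rng.normal(1100, 60, size=(2000, 1))
        comp = composite_posterior([FakeTrace([0], xa), FakeTrace([0], xb)])
        lo, hi = hpd(np.concatenate([xa[:, 0], xb[:, 0]]), 0.95)
        assert (comp[0].hpd_lower, comp[0].hpd_upper) == (lo, hi)

    def test_missing_node_rejected(self, rng):
        a = FakeTrace([0, 1], rng.normal(size=(100, 2)))
        b = FakeTrace([0], rng.normal(size=(100, 1)))
        with pytest.raises(ValueError, match="missing"):
            composite_posterior([a, b], node_ids=[0, 1])

    def test_pooled_size_conservation(self, rng):
        """n_analyses x resample_size samples enter each pooled summary."""
        sizes = [500, 1000, 1500]
        traces = [FakeTrace([0], rng.normal(size=(s, 1))) for s in sizes]
        pooled = []
        comp = composite_posterior(traces, resample_size=500,
                                   rng=np.random.default_rng(1))
        # reproduce the pooling manually with the same rng
        rng2 = np.random.default_rng(1)
        for t in traces:
            x = t.node_ages(0)
            if x.size != 500:
                x = rng2.choice(x, size=500, replace=True)
            pooled.append(x)
        pooled = np.concatenate(pooled)
        assert pooled.size == 1500
        assert comp[0].mean == pytest.approx(pooled.mean())


class TestSchemes:
    def _problem(self, benchmark_dataset):
        ds = benchmark_dataset
        return DatingProblem(tree=ds.tree, calibrations=ds.calibrations,
                             clock=ds.spec.clock,
                             partitions=list(ds.partitions))

    def test_registry_names(self):
        assert {"best", "Phan", "Max-1", "Max-2", "SinglePartition", "IR",
                "Sigma"} == set(SCHEMES)

    def test_phan_drops_proterozoic_minima(self, benchmark_dataset):
        ds = benchmark_dataset
        cals = [Calibration(clade=None, t_min=1000, t_max=3000, name="root")]
        for k, cal in enumerate(c for c in ds.calibrations
                                if c.name != "root"):
            # force one Phanerozoic and one Proterozoic minimum
            cals.append(replace(cal, t_min=450.0 if k == 0 else 1100.0,
                                t_max=max(cal.t_max or 2000.0, 1500.0)))
        p = self._problem(ds).replace(calibrations=CalibrationSet(cals))
        out = apply_scheme("Phan", p)
        names = {c.name for c in out.calibrations}
        assert len(out.calibrations) == 2  # root + the Phanerozoic point
        for cal in out.calibrations:
            assert cal.name == "root" or cal.t_min <= 541.0

    def test_single_partition_merges(self, benchmark_dataset):
        p = self._problem(benchmark_dataset)
        out = apply_scheme("SinglePartition", p)
        assert len(out.partitions) == 1

    def test_ir_switches_clock(self, benchmark_dataset):
        out = apply_scheme("IR", self._problem(benchmark_dataset))
        assert out.clock.model == "IR"

    def test_sigma_inflates_prior(self, benchmark_dataset):
        p = self._problem(benchmark_dataset)
        out = apply_scheme("Sigma", p)
        assert out.clock.sigma2_prior.mean > p.clock.sigma2_prior.mean

    def test_max_schemes_strip_tagged_maxima(self, benchmark_dataset):
        ds = benchmark_dataset
        tagged = []
        for cal in ds.calibrations:
            if cal.name == "cal0":
                tagged.append(replace(cal, tags=frozenset({"controversial-max"})))
            else:
                tagged.append(cal)
        p = self._problem(ds).replace(calibrations=CalibrationSet(tagged))
        out = apply_scheme("Max-1", p)
        c0 = next(c for c in out.calibrations if c.name == "cal0")
        assert c0.min_only

    def test_unknown_scheme(self, benchmark_dataset):
        with pytest.raises(KeyError):
            apply_scheme("Nope", self._problem(benchmark_dataset))


class TestRootSweep:
    def test_single_grid_point_rejected(self, benchmark_dataset):
        ds = benchmark_dataset
        with pytest.raises(ValueError):
            root_sweep(ds.tree, ds.calibrations, [3000.0], ds.spec.clock,
                       ds.partitions, MCMCSettings.desk(seed=0))

    def test_non_increasing_grid_rejected(self, benchmark_dataset):
        ds = benchmark_dataset
        with pytest.raises(ValueError):
            root_sweep(ds.tree, ds.calibrations, [3000.0, 2500.0],
                       ds.spec.clock, ds.partitions,
                       MCMCSettings.desk(seed=0))

    def test_sweep_reproducible_and_shaped(self, benchmark_dataset):
        ds = benchmark_dataset
        grid = [2500.0, 3200.0, 3900.0]
        settings = MCMCSettings(burn_in=4000, sample_every=5, n_samples=400,
                                seed=17)
        clades = [i for i in ds.tree.internal_ids if i != ds.tree.root][:3]
        a = root_sweep(ds.tree, ds.calibrations, grid, ds.spec.clock,
                       ds.partitions, settings, clade_nodes=clades)
        b = root_sweep(ds.tree, ds.calibrations, grid, ds.spec.clock,
                       ds.partitions, settings, clade_nodes=clades)
        np.testing.assert_array_equal(a.mean_ages, b.mean_ages)
        assert a.mean_ages.shape == (3, 3)
        assert a.slopes.shape == (3,)
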