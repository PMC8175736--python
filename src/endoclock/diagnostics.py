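"""Analysis-level dating diagnostics and experiments.

* **Infinite-sites regression** — with unlimited sequence data the posterior
  uncertainty of every node age is driven purely by the calibrations, and
  the 95% HPD width becomes a linear function of the posterior mean age; the
  fitted slope measures the calibration-induced (irreducible) uncertainty,
  lower = more precise dating.
* **Prior-vs-posterior comparison** — the effective prior (a likelihood-free
  chain) against the posterior, per node; nodes whose posterior barely moves
  are flagged as uninformative.
* **Composite posteriors** — pooling of the age samples from several dating
  schemes with equal per-analysis weight, summarised by mean and HPD.
* **Root-maximum sweep** — re-dating under a grid of root maximum ages; the
  slope of posterior mean age against the root maximum measures how much the
  analysis leans on the (often arbitrary) root calibration.

A small registry of named sensitivity schemes (``Phan``, ``Max-1``,
``Max-2``, ``SinglePartition``, ``IR``, ``Sigma``) mirrors the usual
perturbations of a best-practiced dating design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .calibration import CalibrationSet
from .clock import ClockConfig, sigma_large_preset
from .likelihood import PartitionData, merge_partitions
from .sampler import (MCMCSettings, NodeSummary, PosteriorTrace, hpd,
                      run_mcmc, two_chain_check)
from .treedata import TimeTree

__all__ = [
    "infinite_sites_regression",
    "prior_posterior_compare",
    "composite_posterior",
    "root_sweep",
    "SweepResult",
    "DatingProblem",
    "SCHEMES",
    "apply_scheme",
    "NodeSummary",
]

#: boundary of the Phanerozoic eon, Ma; the "Phanerozoic fossils only"
#: sensitivity scheme keeps calibrations whose minimum bound is younger
PHANEROZOIC_MA = 541.0


def infinite_sites_regression(summaries) -> tuple[float, float, float]:
    """OLS of 95% HPD width on posterior mean age; returns (slope,
    intercept, r^2)."""
    if isinstance(summaries, dict):
        summaries = list(summaries.values())
    if len(summaries) < 3:
        raise ValueError("need at least 3 node summaries")
    means = np.array([s.mean for s in summaries])
    widths = np.array([s.hpd_width for s in summaries])
    if np.allclose(means, means[0]):
        raise ValueError("degenerate regression: all posterior means equal")
    res = stats.linregress(means, widths)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass
class NodeDivergence:
    """Prior/posterior divergence for one node."""

    node_id: int
    ks_statistic: float
    mean_shift: float  # posterior mean - prior mean, Ma
    informative: bool


def prior_posterior_compare(prior_trace: PosteriorTrace,
                            posterior_trace: PosteriorTrace,
                            ks_threshold: float = 0.1):
    """Per-node comparison of the effective prior with the posterior.

    Nodes where the posterior is indistinguishable from the prior
    (KS statistic below ``ks_threshold``) are flagged as uninformative:
    for them the data add nothing beyond the calibrations.
    """
    if prior_trace.node_ids != posterior_trace.node_ids:
        raise ValueError("traces cover different node sets")
    if prior_trace.n_samples == 0 or posterior_trace.n_samples == 0:
        raise ValueError("empty trace")
    out = []
    for k, i in enumerate(prior_trace.node_ids):
        a = prior_trace.ages[:, k]
        b = posterior_trace.ages[:, k]
        ks = float(stats.ks_2samp(a, b).statistic)
        out.append(NodeDivergence(
            node_id=i, ks_statistic=ks,
            mean_shift=float(b.mean() - a.mean()),
            informative=ks >= ks_threshold,
        ))
    return out


def composite_posterior(traces, node_ids=None, mass: float = 0.95,
                        resample_size: int | None = None,
                        rng: np.random.Generator | None = None):
    """Pool age samples from several analyses with equal weight per analysis.

    Each trace contributes ``resample_size`` samples (default: the smallest
    trace size; traces already at that size contribute all their samples, so
    identical equal-sized traces reproduce the single-trace summary
    exactly).  Returns node id -> :class:`NodeSummary` of the pooled sample.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to pool")
    if node_ids is None:
        node_ids = traces[0].node_ids
    for t in traces:
        for i in node_ids:
            if i not in t.node_ids:
                raise ValueError(f"node {i} missing from a trace")
    size = resample_size or min(t.n_samples for t in traces)
    rng = rng or np.random.default_rng(0)
    out = {}
    for i in node_ids:
        pooled = []
        for t in traces:
            x = t.node_ages(i)
            if x.size != size:
                x = rng.choice(x, size=size, replace=True)
            pooled.append(x)
        pooled = np.concatenate(pooled)
        lo, hi = hpd(pooled, mass)
        out[i] = NodeSummary(i, float(pooled.mean()), lo, hi)
    return out


# ------------------------------------------------------------------ schemes
@dataclass
class DatingProblem:
    """One dating analysis: tree, calibrations, clock config, partitions."""

    tree: TimeTree
    calibrations: CalibrationSet
    clock: ClockConfig
    partitions: list[PartitionData]

    def replace(self, **kw) -> "DatingProblem":
        cur = dict(tree=self.tree, calibrations=self.calibrations,
                   clock=self.clock, partitions=self.partitions)
        cur.update(kw)
        return DatingProblem(**cur)


def _drop_maxima(calset: CalibrationSet, tag: str) -> CalibrationSet:
    out = []
    for cal in calset:
        if cal.name != "root" and not cal.min_only and tag in cal.tags:
            out.append(replace(cal, t_max=None))
        else:
            out.append(cal)
    return CalibrationSet(out)


def _scheme_best(p: DatingProblem) -> DatingProblem:
    return p


def _scheme_phan(p: DatingProblem) -> DatingProblem:
    """Keep only calibration points with Phanerozoic minima (plus the root)."""
    kept = [c for c in p.calibrations
            if c.name == "root" or c.t_min <= PHANEROZOIC_MA]
    if len(kept) < 2:
        raise ValueError("Phan scheme removed every internal calibration")
    return p.replace(calibrations=CalibrationSet(kept))


def _scheme_max1(p: DatingProblem) -> DatingProblem:
    """Remove maximum constraints tagged as controversial."""
    return p.replace(calibrations=_drop_maxima(p.calibrations, "controversial-max"))


def _scheme_max2(p: DatingProblem) -> DatingProblem:
    """Remove maxima set from the oldest-eukaryote horizon."""
    return p.replace(calibrations=_drop_maxima(p.calibrations, "eukaryote-max"))


def _scheme_single_partition(p: DatingProblem) -> DatingProblem:
    return p.replace(partitions=[merge_partitions(p.partitions)])


def _scheme_ir(p: DatingProblem) -> DatingProblem:
    return p.replace(clock=replace(p.clock, model="IR"))


def _scheme_sigma(p: DatingProblem) -> DatingProblem:
    return p.replace(clock=sigma_large_preset(p.clock))


#: named sensitivity schemes; ``best`` is the unmodified analysis
SCHEMES = {
    "best": _scheme_best,
    "Phan": _scheme_phan,
    "Max-1": _scheme_max1,
    "Max-2": _scheme_max2,
    "SinglePartition": _scheme_single_partition,
    "IR": _scheme_ir,
    "Sigma": _scheme_sigma,
}


def apply_scheme(name: str, problem: DatingProblem) -> DatingProblem:
    if name not in SCHEMES:
        raise KeyError(f"unknown scheme {name!r}; choose from {sorted(SCHEMES)}")
    return SCHEMES[name](problem)


# --------------------------------------------------------------- root sweep
@dataclass
class SweepResult:
    """Posterior mean ages across a grid of root maximum ages."""

    grid: np.ndarray  # root maximum ages, Ma, strictly increasing
    clade_nodes: list[int]
    mean_ages: np.ndarray  # (len(grid), len(clade_nodes))
    slopes: np.ndarray  # per clade: d(mean age)/d(root max)

    def slope_of(self, node_id: int) -> float:
        return float(self.slopes[self.clade_nodes.index(node_id)])


def root_sweep(tree: TimeTree, calibrations: CalibrationSet, grid,
               clock: ClockConfig, partitions, settings: MCMCSettings,
               clade_nodes=None, check_convergence: bool = False,
               convergence_tol: float = 0.05) -> SweepResult:
    """Re-date under successively larger root maximum ages.

    The internal calibrations are held fixed; only the root calibration's
    ``t_max`` walks along ``grid``.  Every run shares the seed policy of
    ``settings`` (same seed per grid point, so differences are attributable
    to the calibration change).  With ``check_convergence`` a second chain
    (seed + 1) is run per grid point and compared; disagreement raises.
    Returns per-clade OLS slopes of posterior mean age against root maximum.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("root sweep needs at least 2 grid points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if clade_nodes is None:
        clade_nodes = [i for i in tree.internal_ids if i != tree.root]
    means = np.zeros((grid.size, len(clade_nodes)))
    for g, root_max in enumerate(grid):
        cals = []
        for cal in calibrations:
            cals.append(cal.with_root_max(float(root_max))
                        if cal.name == "root" else cal)
        calset = CalibrationSet(cals)
        trace = run_mcmc(tree, calset, clock, partitions, settings)
        if check_convergence:
            trace_b = run_mcmc(tree, calset, clock, partitions,
                               replace(settings, seed=settings.seed + 1))
            report = two_chain_check(trace, trace_b, tol=convergence_tol)
            if not report.passed:
                raise RuntimeError(
                    f"root sweep: chains disagree at root max {root_max:.0f} "
                    f"Ma on {report.failed[:3]}"
                )
        for c, node in enumerate(clade_nodes):
            means[g, c] = trace.node_ages(node).mean()
    slopes = np.array([
        stats.linregress(grid, means[:, c]).slope
        for c in range(len(clade_nodes))
    ])
    return SweepResult(grid=grid, clade_nodes=list(clade_nodes),
                       mean_ages=means, slopes=slopes)
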