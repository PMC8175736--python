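"""Metropolis-within-Gibbs MCMC over node ages, rates and hyperparameters.

The joint model sampled here is

* soft-bounded uniform calibration densities on the calibrated nodes, with
  uncalibrated internal node ages conditionally uniform given the tree's
  age ordering (order-statistics prior);
* a relaxed-clock prior on rates (autocorrelated geometric Brownian or
  independent log-normal, see :mod:`endoclock.clock`) with gamma
  hyperpriors on the mean rate ``mu`` and the variance parameter
  ``sigma2``;
* the approximate quadratic likelihood on branch lengths
  (:mod:`endoclock.likelihood`), or no likelihood at all in prior-only
  mode, which exposes the *effective prior* on node ages for comparison
  with the posterior.

Also here: HPD intervals (shortest contiguous window), autocorrelation
effective sample size, and the two-independent-chains convergence check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _mcmc_kernel as K
from .calibration import Calibration, CalibrationSet, _tail_params
from .clock import ClockConfig, FixedPrior
from .likelihood import PartitionData
from .treedata import TimeTree

__all__ = [
    "MCMCSettings",
    "PosteriorTrace",
    "run_mcmc",
    "hpd",
    "ess",
    "two_chain_check",
    "TwoChainReport",
]


@dataclass(frozen=True)
class MCMCSettings:
    """Chain settings.

    The defaults reproduce the study-scale run (burn-in 200,000 iterations,
    one sample every 100, 20,000 samples); :meth:`desk` is a fast preset for
    tests and experiments.  One iteration is a full sweep over every age,
    rate and hyperparameter plus one whole-tree scaling move.
    """

    burn_in: int = 200_000
    sample_every: int = 100
    n_samples: int = 20_000
    seed: int = 0
    prior_only: bool = False
    tune_interval: int = 200
    #: diagnostic switch: drop the whole-tree and subtree scaling moves
    #: (used to verify they leave the stationary distribution unchanged)
    disable_scaling_moves: bool = False

    def __post_init__(self):
        if min(self.burn_in, self.sample_every, self.n_samples,
               self.tune_interval) <= 0:
            raise ValueError("all chain counts must be positive")

    @staticmethod
    def desk(seed: int = 0, prior_only: bool = False, **kw) -> "MCMCSettings":
        """Desk-scale preset: burn-in 20,000, 2,000 samples every 10 sweeps."""
        kw.setdefault("burn_in", 20_000)
        kw.setdefault("sample_every", 10)
        kw.setdefault("n_samples", 2_000)
        return MCMCSettings(seed=seed, prior_only=prior_only, **kw)

    @staticmethod
    def paper(seed: int = 0, **kw) -> "MCMCSettings":
        return MCMCSettings(seed=seed, **kw)


@dataclass
class NodeSummary:
    """Posterior summary of one node's age (mean and HPD bounds, Ma)."""

    node_id: int
    mean: float
    hpd_lower: float
    hpd_upper: float

    @property
    def hpd_width(self) -> float:
        return self.hpd_upper - self.hpd_lower


@dataclass
class PosteriorTrace:
    """Sampled ages, rates and hyperparameters from one chain."""

    node_ids: list[int]  # internal node ids, matching age columns
    ages: np.ndarray  # (n_samples, n_internal), Ma
    log_rates: np.ndarray  # (n_samples, n_nodes); IR: branch slots only
    mu: np.ndarray
    sigma2: np.ndarray
    log_posterior: np.ndarray
    acceptance: dict
    seed: int
    settings: MCMCSettings
    clock_model: str = "AR"

    @property
    def n_samples(self) -> int:
        return self.ages.shape[0]

    def node_ages(self, node_id: int) -> np.ndarray:
        return self.ages[:, self.node_ids.index(node_id)]

    def parameters(self) -> dict[str, np.ndarray]:
        """Named scalar chains: node ages plus hyperparameters."""
        out = {f"age_{i}": self.ages[:, k] for k, i in enumerate(self.node_ids)}
        out["mu"] = self.mu
        out["sigma2"] = self.sigma2
        return out

    def summaries(self, mass: float = 0.95) -> dict[int, NodeSummary]:
        out = {}
        for k, i in enumerate(self.node_ids):
            lo, hi = hpd(self.ages[:, k], mass)
            out[i] = NodeSummary(i, float(self.ages[:, k].mean()), lo, hi)
        return out

    def to_tsv(self, path) -> None:
        import pandas as pd

        cols = {f"age_{i}": self.ages[:, k] for k, i in enumerate(self.node_ids)}
        cols["mu"] = self.mu
        cols["sigma2"] = self.sigma2
        cols["log_posterior"] = self.log_posterior
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                                  float_format="%.10g")


def _cal_arrays(tree: TimeTree, by_node: dict[int, Calibration]):
    n = tree.n_nodes
    ct = np.zeros(n, dtype=np.int64)
    tmin = np.zeros(n)
    tmax = np.zeros(n)
    logh = np.zeros(n)
    thl = np.zeros(n)
    lam = np.zeros(n)
    for i, cal in by_node.items():
        ct[i] = 2 if cal.min_only else 1
        tmin[i] = cal.t_min
        tmax[i] = np.inf if cal.min_only else cal.t_max
        lh, th, lm = _tail_params(cal)
        logh[i] = lh
        thl[i] = th
        lam[i] = lm
    return ct, tmin, tmax, logh, thl, lam


def _initial_ages(tree: TimeTree, by_node: dict[int, Calibration]) -> np.ndarray:
    """Feasible starting chronogram: calibration midpoints propagated through
    the age ordering."""
    n = tree.n_nodes
    # subtree height in "steps" gives a strictly ordered skeleton
    h = np.zeros(n, dtype=int)
    for i in range(n):
        if tree.children[i]:
            h[i] = 1 + max(h[c] for c in tree.children[i])
    root_cal = by_node[tree.root]
    root_mid = 0.5 * (root_cal.t_min + root_cal.t_max)
    ages = np.zeros(n)
    ages[tree.root] = root_mid
    for i in tree.preorder():
        if i == tree.root or not tree.children[i]:
            continue
        p = int(tree.parent[i])
        ages[i] = ages[p] * h[i] / (h[i] + 1.0)
    # pull calibrated nodes toward their interval midpoints, a few sweeps
    for _ in range(8):
        for i in tree.preorder():
            if i == tree.root or not tree.children[i]:
                continue
            p = int(tree.parent[i])
            lo = max(ages[c] for c in tree.children[i])
            hi = ages[p]
            if hi - lo <= 0:
                raise ValueError("infeasible starting state: empty age window")
            cal = by_node.get(i)
            if cal is not None:
                mid = cal.t_min * 1.5 if cal.min_only else 0.5 * (cal.t_min + cal.t_max)
            else:
                mid = ages[i]
            pad = 0.05 * (hi - lo)
            ages[i] = min(max(mid, lo + pad), hi - pad)
    return ages


def run_mcmc(
    tree: TimeTree,
    calibrations: CalibrationSet,
    clock: ClockConfig | None = None,
    partitions=None,
    settings: MCMCSettings | None = None,
) -> PosteriorTrace:
    """Sample the dating posterior (or, in prior-only mode, the effective prior).

    ``partitions`` is a :class:`PartitionData` or list thereof; it is ignored
    (and may be None) when ``settings.prior_only`` is set.
    """
    clock = clock or ClockConfig()
    settings = settings or MCMCSettings()
    by_node = calibrations.resolve(tree)
    n = tree.n_nodes
    nb = n - 1

    if isinstance(partitions, PartitionData):
        partitions = [partitions]
    if not settings.prior_only:
        if not partitions:
            raise ValueError("partitions are required unless prior_only is set")
        for p in partitions:
            p.validate_against(tree)
        P = len(partitions)
        bhat = np.stack([p.b_hat for p in partitions])
        grad = np.stack([p.gradient for p in partitions])
        hess = np.stack([p.hessian for p in partitions])
    else:
        P = 1
        bhat = np.zeros((1, nb))
        grad = np.zeros((1, nb))
        hess = np.zeros((1, nb, nb))

    # flatten children lists to CSR
    child_ptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        child_ptr[i + 1] = child_ptr[i] + len(tree.children[i])
    child_idx = np.zeros(child_ptr[-1], dtype=np.int64)
    for i in range(n):
        child_idx[child_ptr[i]:child_ptr[i + 1]] = tree.children[i]

    internal_ids = np.array(tree.internal_ids, dtype=np.int64)
    cal_arr = _cal_arrays(tree, by_node)

    # subtree membership (descendants including self) for the scaling moves
    desc: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):  # post-order: children before parents
        desc[i] = [i]
        for c in tree.children[i]:
            desc[i].extend(desc[c])
    sub_ptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        sub_ptr[i + 1] = sub_ptr[i] + len(desc[i])
    sub_idx = np.zeros(sub_ptr[-1], dtype=np.int64)
    n_sub_internal = np.zeros(n, dtype=np.int64)
    for i in range(n):
        sub_idx[sub_ptr[i]:sub_ptr[i + 1]] = desc[i]
        n_sub_internal[i] = sum(1 for j in desc[i] if tree.children[j])

    mu0 = clock.mu_prior.value if isinstance(clock.mu_prior, FixedPrior) else clock.mu_prior.mean
    s20 = clock.sigma2_prior.value if isinstance(clock.sigma2_prior, FixedPrior) else clock.sigma2_prior.mean
    if s20 <= 0:
        raise ValueError("sigma2 must be positive for MCMC")
    mu_fixed = 1 if isinstance(clock.mu_prior, FixedPrior) else 0
    s2_fixed = 1 if isinstance(clock.sigma2_prior, FixedPrior) else 0
    mu_shape = 0.0 if mu_fixed else clock.mu_prior.shape
    mu_scale = 1.0 if mu_fixed else clock.mu_prior.scale
    s2_shape = 0.0 if s2_fixed else clock.sigma2_prior.shape
    s2_scale = 1.0 if s2_fixed else clock.sigma2_prior.scale

    ages = _initial_ages(tree, by_node)
    lr = np.full(n, np.log(mu0))

    m_int = internal_ids.size
    S = settings.n_samples
    out_ages = np.zeros((S, m_int))
    out_lr = np.zeros((S, n))
    out_mu = np.zeros(S)
    out_s2 = np.zeros(S)
    out_lp = np.zeros(S)
    acc = np.zeros(7, dtype=np.int64)
    prop = np.zeros(7, dtype=np.int64)

    scale_age = np.maximum(1.0, 0.05 * ages.copy())
    scale_rate = np.full(n, 0.3)
    scale_mix = np.full(n, 0.2)
    scale_other = np.array([0.3, 0.3, 0.2])

    status = K.run_kernel(
        tree.parent, child_ptr, child_idx, internal_ids,
        sub_ptr, sub_idx, n_sub_internal,
        *cal_arr,
        0 if clock.model == "AR" else 1,
        1 if clock.branch_rate == "geometric" else 0,
        clock.root_var_time,
        mu_fixed, mu_shape, mu_scale,
        s2_fixed, s2_shape, s2_scale,
        bhat, grad, hess,
        1 if settings.prior_only else 0,
        1 if settings.disable_scaling_moves else 0,
        ages, lr, mu0, s20,
        settings.burn_in, settings.sample_every, settings.n_samples,
        settings.tune_interval, settings.seed,
        scale_age, scale_rate, scale_mix, scale_other,
        out_ages, out_lr, out_mu, out_s2, out_lp,
        acc, prop,
    )
    if status == 1:
        raise ValueError("infeasible starting state: non-finite initial posterior")
    if status == 2:
        raise FloatingPointError("NaN posterior encountered during sampling")

    # every stored sample must satisfy the age ordering
    col_of = {int(i): k for k, i in enumerate(internal_ids)}
    for i in range(n - 1):
        p = int(tree.parent[i])
        child_ages = out_ages[:, col_of[i]] if i in col_of else 0.0
        if np.any(out_ages[:, col_of[p]] <= child_ages):
            raise AssertionError("sampled ages violate tree ordering")

    names = ["age", "root_age", "rates", "mu", "sigma2", "mixing", "subtree"]
    acceptance = {
        nm: (float(acc[k] / prop[k]) if prop[k] else np.nan)
        for k, nm in enumerate(names)
    }
    return PosteriorTrace(
        node_ids=[int(i) for i in internal_ids],
        ages=out_ages,
        log_rates=out_lr,
        mu=out_mu,
        sigma2=out_s2,
        log_posterior=out_lp,
        acceptance=acceptance,
        seed=settings.seed,
        settings=settings,
        clock_model=clock.model,
    )


# ----------------------------------------------------------------- summaries
def hpd(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * N)`` samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    if k < 2:
        k = 2
    widths = x[k - 1:] - x[: n - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


def ess(chain) -> float:
    """Effective sample size ``N / (1 + 2 sum rho_k)``.

    Autocorrelations are summed up to (excluding) the first non-positive
    term.  A constant chain has no information and is reported as 0 with a
    warning.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("chain too short for ESS")
    v = x.var()
    if v == 0:
        warnings.warn("constant chain: ESS undefined, reported as 0")
        return 0.0
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (v * n)
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


@dataclass
class TwoChainReport:
    """Per-parameter agreement between two independent chains."""

    rel_diff: dict[str, float]
    failed: list[str]
    correlation: float
    tol: float

    @property
    def passed(self) -> bool:
        return not self.failed


def two_chain_check(trace_a, trace_b, tol: float = 0.02) -> TwoChainReport:
    """Compare posterior means from two independent chains.

    ``trace_a``/``trace_b`` may be :class:`PosteriorTrace` objects or plain
    name -> chain dicts.  The relative difference of means is taken against
    the mean magnitude of the pair; parameters exceeding ``tol`` fail.
    """
    pa = trace_a.parameters() if hasattr(trace_a, "parameters") else dict(trace_a)
    pb = trace_b.parameters() if hasattr(trace_b, "parameters") else dict(trace_b)
    if set(pa) != set(pb):
        raise ValueError("traces cover different parameter sets")
    rel = {}
    ma, mb = [], []
    for name in pa:
        a = float(np.mean(pa[name]))
        b = float(np.mean(pb[name]))
        ma.append(a)
        mb.append(b)
        denom = 0.5 * (abs(a) + abs(b))
        rel[name] = abs(a - b) / denom if denom > 0 else 0.0
    failed = sorted(name for name, r in rel.items() if r > tol)
    corr = float(np.corrcoef(ma, mb)[0, 1]) if len(ma) > 1 else 1.0
    return TwoChainReport(rel_diff=rel, failed=failed, correlation=corr, tol=tol)
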