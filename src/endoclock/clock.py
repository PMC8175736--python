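"""Among-branch substitution-rate models.

Two relaxed-clock models are provided:

* **AR** (autocorrelated, geometric Brownian motion): each node carries a
  log-rate; a child's log-rate is a Brownian step from its parent with
  variance ``sigma2 * dt`` (``dt`` the branch duration in Ma) and drift
  ``-sigma2 * dt / 2``, so the child's *rate* is a martingale given the
  parent's.  The rate assigned to a branch is by default the arithmetic mean
  of its endpoint node rates (a geometric-mean variant is switchable).

* **IR** (independent log-normal rates): each branch's log-rate is drawn iid
  from ``Normal(log mu - sigma2/2, sigma2)`` so that the mean branch rate is
  exactly ``mu``.

``mu`` is in substitutions/site/Ma; under AR, ``sigma2`` is the per-Ma
diffusion variance of the log-rate, under IR the (dimensionless) variance of
the log-rate.  The root node's log-rate prior is log-normal centred on
``mu`` with variance ``sigma2 * root_var_time`` (AR only), a choice the
underlying theory leaves open; ``root_var_time`` defaults to 500 Ma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .treedata import TimeTree

__all__ = [
    "ClockParams",
    "ClockConfig",
    "GammaPrior",
    "FixedPrior",
    "BranchRates",
    "simulate_rates",
    "log_prior_rates",
    "sample_hyperpriors",
    "sigma_large_preset",
]

DEFAULT_ROOT_VAR_TIME = 500.0  # Ma


@dataclass(frozen=True)
class ClockParams:
    """Concrete rate-model parameters (model, mean rate, rate variance)."""

    model: str  # "AR" | "IR"
    mu: float
    sigma2: float
    root_var_time: float = DEFAULT_ROOT_VAR_TIME
    branch_rate: str = "arithmetic"  # AR branch rate from endpoint node rates

    def __post_init__(self):
        if self.model not in ("AR", "IR"):
            raise ValueError("model must be 'AR' or 'IR'")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if self.branch_rate not in ("arithmetic", "geometric"):
            raise ValueError("branch_rate must be 'arithmetic' or 'geometric'")


@dataclass(frozen=True)
class GammaPrior:
    """Gamma hyperprior parameterised by shape and mean (scale = mean/shape)."""

    shape: float
    mean: float

    def __post_init__(self):
        if self.shape <= 0 or self.mean <= 0:
            raise ValueError("gamma shape and mean must be positive")

    @property
    def scale(self) -> float:
        return self.mean / self.shape

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.shape, self.scale))

    def logpdf(self, x: float) -> float:
        return float(stats.gamma.logpdf(x, self.shape, scale=self.scale))


@dataclass(frozen=True)
class FixedPrior:
    """Degenerate (point-mass) hyperprior; the parameter is not sampled."""

    value: float

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("fixed hyperparameter must be positive")

    def sample(self, rng) -> float:
        return self.value

    def logpdf(self, x) -> float:
        return 0.0


@dataclass(frozen=True)
class ClockConfig:
    """Rate model plus hyperpriors for ``mu`` and ``sigma2``.

    Defaults suit trees a few thousand Ma deep with branch lengths of order
    0.1 substitutions/site: mean rate 2e-4 /site/Ma and moderate rate
    variation.  The ``sigma-large`` sensitivity preset multiplies the
    ``sigma2`` prior mean by 5 (see :func:`sigma_large_preset`).
    """

    model: str = "AR"
    mu_prior: GammaPrior | FixedPrior = field(
        default_factory=lambda: GammaPrior(2.0, 2e-4)
    )
    sigma2_prior: GammaPrior | FixedPrior = field(
        default_factory=lambda: GammaPrior(2.0, 5e-4)
    )
    root_var_time: float = DEFAULT_ROOT_VAR_TIME
    branch_rate: str = "arithmetic"

    def params(self, mu: float, sigma2: float) -> ClockParams:
        return ClockParams(
            self.model, mu, sigma2, self.root_var_time, self.branch_rate
        )


def sigma_large_preset(config: ClockConfig, factor: float = 5.0) -> ClockConfig:
    """The larger-rate-variation sensitivity scheme: inflate the sigma2 prior mean."""
    sp = config.sigma2_prior
    if isinstance(sp, FixedPrior):
        sp = FixedPrior(sp.value * factor)
    else:
        sp = GammaPrior(sp.shape, sp.mean * factor)
    return ClockConfig(config.model, config.mu_prior, sp, config.root_var_time,
                       config.branch_rate)


def sample_hyperpriors(config: ClockConfig, rng: np.random.Generator):
    """Draw ``(mu, sigma2)`` from the configured hyperpriors."""
    return config.mu_prior.sample(rng), config.sigma2_prior.sample(rng)


@dataclass
class BranchRates:
    """Rates produced by a clock model on a fixed chronogram.

    ``branch_rates`` is indexed by child node id (length ``n_nodes - 1``).
    Under AR, ``node_log_rates`` (length ``n_nodes``) holds the primitive
    per-node log-rates from which branch rates derive; it is ``None`` for IR.
    """

    branch_rates: np.ndarray
    node_log_rates: np.ndarray | None = None


def _ar_branch_rate(lr_child, lr_parent, mode: str):
    if mode == "geometric":
        return np.exp(0.5 * (lr_child + lr_parent))
    return 0.5 * (np.exp(lr_child) + np.exp(lr_parent))


def simulate_rates(tree: TimeTree, params: ClockParams, rng: np.random.Generator) -> BranchRates:
    """Simulate per-branch rates under the selected relaxed-clock model."""
    if tree.ages is None:
        raise ValueError("rate simulation requires a dated tree")
    n = tree.n_nodes
    if params.model == "IR":
        if params.sigma2 == 0.0:
            rates = np.full(n - 1, params.mu)
        else:
            lr = rng.normal(
                np.log(params.mu) - params.sigma2 / 2.0,
                np.sqrt(params.sigma2),
                size=n - 1,
            )
            rates = np.exp(lr)
        return BranchRates(branch_rates=rates)
    # AR: Brownian walk of node log-rates from the root
    lr = np.empty(n)
    s2 = params.sigma2
    v0 = s2 * params.root_var_time
    lr[tree.root] = (
        np.log(params.mu)
        if v0 == 0.0
        else rng.normal(np.log(params.mu) - v0 / 2.0, np.sqrt(v0))
    )
    for i in tree.preorder():
        if i == tree.root:
            continue
        dt = tree.ages[int(tree.parent[i])] - tree.ages[i]
        if s2 == 0.0:
            lr[i] = lr[int(tree.parent[i])]
        else:
            lr[i] = rng.normal(lr[int(tree.parent[i])] - s2 * dt / 2.0,
                               np.sqrt(s2 * dt))
    if s2 == 0.0 and v0 == 0.0:
        return BranchRates(branch_rates=np.full(n - 1, params.mu),
                           node_log_rates=lr)
    branch = np.empty(n - 1)
    for i in range(n - 1):
        branch[i] = _ar_branch_rate(lr[i], lr[int(tree.parent[i])], params.branch_rate)
    return BranchRates(branch_rates=branch, node_log_rates=lr)


def _norm_logpdf(x, mean, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def log_prior_rates(tree: TimeTree, rates: BranchRates, params: ClockParams) -> float:
    """Joint log density of the rates under the clock model.

    The density is over the *rates* (not log-rates), i.e. it includes the
    ``1/r`` Jacobian of the log transform.  Under AR the primitive variables
    are the per-node rates; under IR the per-branch rates.
    """
    if tree.ages is None:
        raise ValueError("requires a dated tree")
    s2 = params.sigma2
    if params.model == "IR":
        r = np.asarray(rates.branch_rates, dtype=float)
        if np.any(r <= 0):
            raise ValueError("rates must be positive")
        if s2 == 0.0:
            return 0.0 if np.allclose(r, params.mu) else -np.inf
        lr = np.log(r)
        lp = _norm_logpdf(lr, np.log(params.mu) - s2 / 2.0, s2)
        return float(np.sum(lp) - np.sum(lr))
    if rates.node_log_rates is None:
        raise ValueError("AR prior requires per-node log-rates")
    lr = np.asarray(rates.node_log_rates, dtype=float)
    v0 = s2 * params.root_var_time
    if s2 == 0.0:
        ok = np.allclose(np.exp(lr), params.mu)
        return 0.0 if ok else -np.inf
    lp = _norm_logpdf(lr[tree.root], np.log(params.mu) - v0 / 2.0, v0)
    for i in range(tree.n_nodes - 1):
        p = int(tree.parent[i])
        dt = tree.ages[p] - tree.ages[i]
        lp += _norm_logpdf(lr[i], lr[p] - s2 * dt / 2.0, s2 * dt)
    return float(lp - np.sum(lr))
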