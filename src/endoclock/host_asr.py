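"""Two-state CTMC ancestral host-lifestyle reconstruction.

Symbiont lineages are scored as animal-associated (``A``) or
protist-associated (``P``); ``?`` marks tips with unknown hosts.  The
character evolves on a fixed tree (branch lengths taken as given, no clock
assumption) under an asymmetric two-state continuous-time Markov chain with
rates ``q_AP`` (animal -> protist) and ``q_PA`` (protist -> animal).

Provided here: the closed-form transition matrix, Felsenstein pruning
likelihood, up-down marginal ancestral state probabilities, a Metropolis
sampler for the rates under exponential priors, and stepping-stone
estimation of the marginal likelihood for Bayes-factor comparison of the
free two-rate model against the equal-rates model.  The Bayes factor is
reported on the ``2 x (logML_1 - logML_0)`` scale, on which values above 10
count as very strong evidence; conventions differ between software, so note
the factor of two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .treedata import TimeTree

__all__ = [
    "HostCharacterMatrix",
    "Mk2Params",
    "transition_matrix",
    "pruning_loglik",
    "marginal_anc_states",
    "run_asr_mcmc",
    "stepping_stone_logml",
    "log_bayes_factor",
    "AsrResult",
]

STATES = ("A", "P")
_PARTIALS = {"A": np.array([1.0, 0.0]), "P": np.array([0.0, 1.0]),
             "?": np.array([1.0, 1.0])}


class HostCharacterMatrix:
    """Tip label -> host state in {A, P, ?}."""

    def __init__(self, states: dict):
        bad = {s for s in states.values() if s not in ("A", "P", "?")}
        if bad:
            raise ValueError(f"invalid states: {sorted(bad)}")
        self.states = dict(states)

    def __getitem__(self, tip):
        return self.states[tip]

    def __len__(self):
        return len(self.states)

    def validate_against(self, tree: TimeTree, warn: bool = True) -> None:
        missing = [tree.labels[i] for i in tree.leaf_ids
                   if tree.labels[i] not in self.states]
        if missing:
            raise ValueError(f"tips without states: {missing[:5]} ...")
        observed = {s for s in self.states.values() if s != "?"}
        if warn and observed != {"A", "P"}:
            warnings.warn(
                "only one observed state: transition rates are weakly "
                "identifiable"
            )


@dataclass(frozen=True)
class Mk2Params:
    """Rates of the asymmetric two-state chain, per unit branch length.

    ``root`` is ``"stationary"`` (default: the stationary distribution of
    the rate matrix) or ``"uniform"``.
    """

    q_ap: float
    q_pa: float
    root: str = "stationary"

    def __post_init__(self):
        if self.q_ap < 0 or self.q_pa < 0:
            raise ValueError("rates must be non-negative")
        if self.root not in ("stationary", "uniform"):
            raise ValueError("root must be 'stationary' or 'uniform'")

    def root_distribution(self) -> np.ndarray:
        if self.root == "uniform":
            return np.array([0.5, 0.5])
        q = self.q_ap + self.q_pa
        if q == 0:
            return np.array([0.5, 0.5])
        return np.array([self.q_pa / q, self.q_ap / q])


def transition_matrix(params: Mk2Params, t: float) -> np.ndarray:
    """Closed-form ``exp(Q t)`` for the two-state chain; rows sum to 1."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    q = params.q_ap + params.q_pa
    if q == 0 or t == 0:
        return np.eye(2)
    pi_a = params.q_pa / q
    pi_p = params.q_ap / q
    e = np.exp(-q * t)
    return np.array([
        [pi_a + pi_p * e, pi_p * (1.0 - e)],
        [pi_a * (1.0 - e), pi_p + pi_a * e],
    ])


def _edge_lengths(tree: TimeTree) -> np.ndarray:
    el = tree.edge_lengths
    if el is None:
        el = tree.edge_lengths_from_ages()
    return el


def _partials(tree: TimeTree, chars: HostCharacterMatrix,
              params: Mk2Params):
    """Post-order conditional likelihoods with log scaling.

    Returns (L, log_scale, trans) where ``L[i]`` is the scaled partial at
    node i and ``trans[i]`` the transition matrix over the branch above i.
    """
    el = _edge_lengths(tree)
    n = tree.n_nodes
    L = np.zeros((n, 2))
    log_scale = 0.0
    trans = [None] * n
    for i in range(n):
        if tree.is_leaf(i):
            L[i] = _PARTIALS[chars[tree.labels[i]]]
        else:
            part = np.ones(2)
            for c in tree.children[i]:
                part = part * (trans[c] @ L[c])
            m = part.max()
            if m <= 0:
                return None, -np.inf, trans
            L[i] = part / m
            log_scale += np.log(m)
        if i != tree.root:
            trans[i] = transition_matrix(params, float(el[i]))
    return L, log_scale, trans


def pruning_loglik(tree: TimeTree, chars: HostCharacterMatrix,
                   params: Mk2Params) -> float:
    """Felsenstein pruning log-likelihood of the tip states."""
    chars.validate_against(tree, warn=False)
    L, log_scale, _ = _partials(tree, chars, params)
    if L is None:
        return -np.inf
    lik = float(params.root_distribution() @ L[tree.root])
    if lik <= 0:
        return -np.inf
    return np.log(lik) + log_scale


def marginal_anc_states(tree: TimeTree, chars: HostCharacterMatrix,
                        params: Mk2Params) -> np.ndarray:
    """Marginal probability of each state at every node (n_nodes x 2).

    Up-down algorithm: post-order partials combined with pre-order messages
    from the rest of the tree; each row sums to 1.
    """
    chars.validate_against(tree, warn=False)
    L, log_scale, trans = _partials(tree, chars, params)
    if L is None:
        raise ValueError("data have zero likelihood under these parameters")
    n = tree.n_nodes
    D = np.zeros((n, 2))  # message from above (prior x rest of tree)
    D[tree.root] = params.root_distribution()
    for i in tree.preorder():
        for c in tree.children[i]:
            # siblings' contribution, excluding c
            sib = D[i].copy()
            for s in tree.children[i]:
                if s != c:
                    sib = sib * (trans[s] @ L[s])
            D[c] = trans[c].T @ sib
    marg = D * L
    marg /= marg.sum(axis=1, keepdims=True)
    return marg


# ------------------------------------------------------------------- priors
@dataclass(frozen=True)
class ExponentialRatePrior:
    """Independent exponential priors on the transition rates.

    The default mean is chosen so that the prior expects about two
    transitions over the whole tree (``mean = 2 / total tree length``); pass
    an explicit mean to override.
    """

    mean: float

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("prior mean must be positive")

    def logpdf(self, q: float) -> float:
        return -np.log(self.mean) - q / self.mean

    def sample(self, rng) -> float:
        return float(rng.exponential(self.mean))


def default_rate_prior(tree: TimeTree, expected_transitions: float = 2.0):
    el = _edge_lengths(tree)
    total = float(np.nansum(el))
    return ExponentialRatePrior(mean=expected_transitions / total)


@dataclass
class AsrResult:
    """MCMC output: rate trace and posterior-mean node marginals."""

    q_ap: np.ndarray
    q_pa: np.ndarray
    log_lik: np.ndarray
    marginals: np.ndarray | None  # (n_nodes, 2), averaged over the posterior
    acceptance: float
    seed: int


def run_asr_mcmc(tree: TimeTree, chars: HostCharacterMatrix,
                 prior: ExponentialRatePrior | None = None,
                 n_samples: int = 2000, burn_in: int = 1000,
                 sample_every: int = 5, seed: int = 0,
                 prior_only: bool = False, model: str = "free",
                 compute_marginals: bool = True) -> AsrResult:
    """Metropolis sampling of ``(q_AP, q_PA)`` under exponential priors.

    ``model="equal_rates"`` ties the two rates.  Marginal ancestral state
    probabilities are averaged over the sampled rate posterior.
    """
    chars.validate_against(tree)
    prior = prior or default_rate_prior(tree)
    rng = np.random.default_rng(seed)
    free = model == "free"

    def loglik(q):
        if prior_only:
            return 0.0
        p = Mk2Params(q[0], q[1] if free else q[0])
        return pruning_loglik(tree, chars, p)

    k = 2 if free else 1
    logq = np.log(np.full(k, prior.mean))
    cur_ll = loglik(np.exp(logq))
    cur_lp = sum(prior.logpdf(v) + np.log(v) for v in np.exp(logq))
    # note: log-scale walk; prior density + Jacobian folded into cur_lp
    out_q = np.zeros((n_samples, k))
    out_ll = np.zeros(n_samples)
    marg_sum = np.zeros((tree.n_nodes, 2))
    n_marg = 0
    acc = 0
    total = burn_in + n_samples * sample_every
    step = 0.6
    for it in range(total):
        j = it % k
        prop = logq.copy()
        prop[j] += rng.normal() * step
        q = np.exp(prop)
        new_ll = loglik(q)
        new_lp = sum(prior.logpdf(v) + np.log(v) for v in q)
        if np.log(rng.random()) < (new_ll + new_lp) - (cur_ll + cur_lp):
            logq, cur_ll, cur_lp = prop, new_ll, new_lp
            acc += 1
        if it < burn_in and (it + 1) % 200 == 0:
            rate = acc / (it + 1.0)
            step = float(np.clip(step * np.exp(rate - 0.3), 0.05, 3.0))
        if it >= burn_in and (it - burn_in + 1) % sample_every == 0:
            s = (it - burn_in + 1) // sample_every - 1
            out_q[s] = np.exp(logq)
            out_ll[s] = cur_ll
            if compute_marginals and not prior_only and s % 20 == 0:
                qv = np.exp(logq)
                p = Mk2Params(qv[0], qv[1] if free else qv[0])
                marg_sum += marginal_anc_states(tree, chars, p)
                n_marg += 1
    q_ap = out_q[:, 0]
    q_pa = out_q[:, 1] if free else out_q[:, 0]
    marg = marg_sum / n_marg if n_marg else None
    return AsrResult(q_ap=q_ap, q_pa=q_pa, log_lik=out_ll, marginals=marg,
                     acceptance=acc / total, seed=seed)


# ----------------------------------------------------------- stepping stone
def beta_ladder(K: int, alpha: float = 0.3) -> np.ndarray:
    """K+1 inverse-temperatures 0 = b_0 < ... < b_K = 1, Beta(alpha, 1)
    quantile spacing (dense near the prior)."""
    if K < 8:
        raise ValueError("need at least 8 stepping-stone rungs")
    return (np.arange(K + 1) / K) ** (1.0 / alpha)


def stepping_stone(sample_prior, loglik, propose, K: int = 32,
                   n_per_rung: int = 100, burn_per_rung: int = 100,
                   alpha: float = 0.3, rng=None) -> float:
    """Generic stepping-stone estimate of ``log integral lik * prior``.

    ``sample_prior(rng)`` draws an exact prior sample, ``loglik(x)`` the
    log-likelihood, and ``propose(x, rng)`` returns ``(x', log_prior_ratio,
    log_hastings)`` for the within-rung Metropolis updates.  Chains are
    warm-started rung to rung.
    """
    rng = rng or np.random.default_rng()
    betas = beta_ladder(K, alpha)
    if np.any(np.diff(betas) <= 0):
        raise ValueError("beta ladder must be strictly increasing")
    x = sample_prior(rng)
    ll = loglik(x)
    logml = 0.0
    for k in range(K):
        beta = betas[k]
        lls = np.empty(n_per_rung)
        for m in range(burn_per_rung + n_per_rung):
            if beta == 0.0:
                # exact iid draws from the prior
                x = sample_prior(rng)
                ll = loglik(x)
            else:
                xp, dlp, dlh = propose(x, rng)
                llp = loglik(xp)
                if np.log(rng.random()) < beta * (llp - ll) + dlp + dlh:
                    x, ll = xp, llp
            if m >= burn_per_rung:
                lls[m - burn_per_rung] = ll
        dbeta = betas[k + 1] - beta
        mx = lls.max()
        logml += dbeta * mx + np.log(np.mean(np.exp(dbeta * (lls - mx))))
    return float(logml)


def stepping_stone_logml(tree: TimeTree, chars: HostCharacterMatrix,
                         model: str = "free", K: int = 32,
                         prior: ExponentialRatePrior | None = None,
                         n_per_rung: int = 100, burn_per_rung: int = 100,
                         seed: int = 0) -> float:
    """Stepping-stone log marginal likelihood of the Mk2 model.

    ``model`` is ``"free"`` (independent q_AP, q_PA) or ``"equal_rates"``.
    """
    if model not in ("free", "equal_rates"):
        raise ValueError("model must be 'free' or 'equal_rates'")
    chars.validate_against(tree, warn=False)
    prior = prior or default_rate_prior(tree)
    k = 2 if model == "free" else 1
    rng = np.random.default_rng(seed)

    def sample_prior(r):
        return np.array([prior.sample(r) for _ in range(k)])

    def loglik(q):
        p = Mk2Params(q[0], q[1] if k == 2 else q[0])
        return pruning_loglik(tree, chars, p)

    def propose(q, r):
        j = int(r.integers(k))
        out = q.copy()
        out[j] = q[j] * np.exp(r.normal() * 0.7)
        # log-scale walk: Hastings term is the Jacobian ratio
        dlp = prior.logpdf(out[j]) - prior.logpdf(q[j])
        dlh = np.log(out[j]) - np.log(q[j])
        return out, dlp, dlh

    return stepping_stone(sample_prior, loglik, propose, K=K,
                          n_per_rung=n_per_rung,
                          burn_per_rung=burn_per_rung, rng=rng)


def log_bayes_factor(tree: TimeTree, chars: HostCharacterMatrix,
                     K: int = 32, seed: int = 0, **kw) -> float:
    """``logBF = 2 (logML_free - logML_equal)``; > 10 is very strong."""
    lml_free = stepping_stone_logml(tree, chars, model="free", K=K,
                                    seed=seed, **kw)
    lml_equal = stepping_stone_logml(tree, chars, model="equal_rates", K=K,
                                     seed=seed + 1, **kw)
    return 2.0 * (lml_free - lml_equal)
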