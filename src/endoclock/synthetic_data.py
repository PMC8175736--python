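"""Generators for every input the dating and ASR pipelines consume.

The scenarios emulate the structure of an endosymbiosis-dated tree: a
calibration-poor *symbiont* clade (the bacteria) joined at the root to a
calibration-rich *host-analog* clade (the mitochondrial/eukaryote lineages
whose fossils carry the temporal information).  Two calibration placements
reproduce the central design contrast:

* ``mito_like`` — internal host-clade nodes carry both minimum and maximum
  bounds (eukaryote fossils provide both), plus a broad root bracket;
* ``cyano_like`` — internal calibrations carry minimum bounds only and the
  root carries the sole maximum, the traditional situation with
  cyanobacteria-style fossils.

Matched scenario pairs share the tree, rates and noise exactly (same
sub-seed) and differ only in calibration placement, so any difference in
root-sensitivity is attributable to the placement.

Branch-length "estimates" are Gaussian noise around the true expected
branch lengths with a diagonal covariance; the matching
:class:`~endoclock.likelihood.PartitionData` carries ``H = -Sigma^{-1}``
and zero gradient, which makes the quadratic approximate likelihood exact
and isolates sampler behaviour from sequence-likelihood machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import Calibration, CalibrationSet
from .clock import BranchRates, ClockConfig, sample_hyperpriors, simulate_rates
from .likelihood import PartitionData, expected_branch_lengths
from .host_asr import HostCharacterMatrix, Mk2Params, transition_matrix
from .sampler import MCMCSettings, run_mcmc
from .treedata import CladeSpec, TimeTree

__all__ = [
    "ScenarioSpec",
    "SyntheticDataset",
    "simulate_bd_tree",
    "simulate_dataset",
    "simulate_host_states",
    "draw_prior_predictive",
    "benchmark_20leaf",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A stated synthetic world for one dating experiment.

    Defaults describe a 20-leaf scenario on the depth scale of the study's
    trees: a 12-tip symbiont clade and an 8-tip host-analog clade joined at
    a ~1800 Ma root, moderate autocorrelated rate variation around
    2e-4 substitutions/site/Ma, and 10% relative noise on branch-length
    estimates.
    """

    n_symbiont: int = 12
    n_host: int = 8
    root_age: float = 1800.0  # Ma
    birth: float = 2e-3  # per Ma
    death: float = 0.0
    clock: ClockConfig = field(default_factory=ClockConfig)
    noise_cv: float = 0.10
    n_partitions: int = 2
    n_internal_cals: int = 4  # host-clade calibrations (3-5 in the design)
    placement: str = "mito_like"
    seed: int = 0

    def __post_init__(self):
        if self.n_symbiont < 2 or self.n_host < 2:
            raise ValueError("each clade needs at least 2 tips")
        if self.root_age <= 0 or self.birth <= self.death or self.death < 0:
            raise ValueError("need root_age > 0 and birth > death >= 0")
        if self.placement not in ("mito_like", "cyano_like"):
            raise ValueError("placement must be 'mito_like' or 'cyano_like'")


# --------------------------------------------------------------- birth-death
def _conditioned_node_ages(n_inner: int, birth: float, death: float,
                           root_age: float, rng: np.random.Generator):
    """Ages of the non-root internal nodes of a reconstructed birth-death
    tree conditioned on the root age: iid draws with CDF
    ``G(x)/G(T)`` where ``G(x) = (1 - e^{-rx}) / (birth - death e^{-rx})``
    and ``r = birth - death`` (truncated exponential in the pure-birth
    case)."""
    if n_inner == 0:
        return np.empty(0)
    r = birth - death
    u = rng.random(n_inner)
    gT = (1.0 - np.exp(-r * root_age)) / (birth - death * np.exp(-r * root_age))
    y = u * gT
    # invert G: e^{-rx} = (1 - y*birth) / (1 - y*death)
    x = -np.log((1.0 - y * birth) / (1.0 - y * death)) / r
    return x


def simulate_bd_tree(n_tips: int, birth: float, death: float, root_age: float,
                     rng: np.random.Generator, label_prefix: str = "t") -> TimeTree:
    """Ultrametric chronogram from a reconstructed birth-death process,
    conditioned on the number of extant tips and the root age (Ma)."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth <= death or death < 0:
        raise ValueError("need birth > death >= 0")
    node_ages = np.sort(
        _conditioned_node_ages(n_tips - 2, birth, death, root_age, rng)
    )[::-1]
    # build downward: start with two root lineages; at each (descending)
    # branching age split a uniformly chosen open lineage
    children: list[list[int]] = []
    ages: list[float] = []

    def new_node(age):
        children.append([])
        ages.append(age)
        return len(ages) - 1

    root = new_node(root_age)
    open_lineages = [new_node(np.nan), new_node(np.nan)]
    children[root] = list(open_lineages)
    for a in node_ages:
        k = int(rng.integers(len(open_lineages)))
        node = open_lineages.pop(k)
        ages[node] = a
        kids = [new_node(np.nan), new_node(np.nan)]
        children[node] = kids
        open_lineages.extend(kids)
    for node in open_lineages:
        ages[node] = 0.0
    return _assemble(children, ages, root, label_prefix, rng)


def _assemble(children, ages, root, label_prefix, rng) -> TimeTree:
    """Re-index an ad-hoc node list into a post-ordered TimeTree."""
    order = []
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
        else:
            stack.append((node, True))
            for c in reversed(children[node]):
                stack.append((c, False))
    index = {node: i for i, node in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=np.int64)
    labels = {}
    leaf_no = 0
    new_ages = np.zeros(n)
    for node in order:
        i = index[node]
        new_ages[i] = ages[node]
        for c in children[node]:
            parent[index[c]] = i
        if not children[node]:
            labels[i] = f"{label_prefix}{leaf_no}"
            leaf_no += 1
    return TimeTree(parent, labels, ages=new_ages)


def _join_clades(host: TimeTree, symb: TimeTree, root_age: float) -> TimeTree:
    """Two chronograms joined under a new root at ``root_age``."""
    children = []
    ages = []

    def import_tree(tree, offset_labels):
        base = len(ages)
        for i in range(tree.n_nodes):
            ages.append(tree.ages[i])
            children.append([base + c for c in tree.children[i]])
        return base + tree.root

    rh = import_tree(host, None)
    rs = import_tree(symb, None)
    root = len(ages)
    ages.append(root_age)
    children.append([rh, rs])
    # labels must survive: rebuild via _assemble-like pass keeping names
    order = []
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
        else:
            stack.append((node, True))
            for c in reversed(children[node]):
                stack.append((c, False))
    index = {node: i for i, node in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=np.int64)
    labels = {}
    new_ages = np.zeros(n)
    host_n = host.n_nodes
    for node in order:
        i = index[node]
        new_ages[i] = ages[node]
        for c in children[node]:
            parent[index[c]] = i
        if not children[node]:
            if node < host_n:
                labels[i] = host.labels[node]
            else:
                labels[i] = symb.labels[node - host_n]
    return TimeTree(parent, labels, ages=new_ages)


# ------------------------------------------------------------------ datasets
@dataclass
class SyntheticDataset:
    """One generated dating problem with its hidden truth."""

    spec: ScenarioSpec
    tree: TimeTree  # topology; `true_ages` is the hidden chronogram
    true_ages: np.ndarray
    true_rates: BranchRates
    true_mu: float
    true_sigma2: float
    partitions: list[PartitionData]
    calibrations: CalibrationSet
    host_node_ids: list[int]  # internal nodes of the host-analog clade

    @property
    def internal_ids(self):
        return self.tree.internal_ids


def _clade_spec_for(tree: TimeTree, node: int, name: str) -> CladeSpec:
    leaves = sorted(tree.labels[i] for i in tree.clade_leaf_ids(node))
    return CladeSpec(frozenset(leaves), group="crown", name=name)


def _bracket(rng, true_age):
    lo = true_age * rng.uniform(0.6, 0.9)
    hi = true_age * rng.uniform(1.1, 1.6)
    return lo, hi


def simulate_dataset(spec: ScenarioSpec) -> SyntheticDataset:
    """Generate a full dating problem from a :class:`ScenarioSpec`.

    The calibration brackets are built around the true node ages (loose,
    min = truth x U(0.6, 0.9), max = truth x U(1.1, 1.6)), so every
    generated interval contains its node's truth.  Under ``cyano_like``
    placement the internal maxima are dropped and only the root keeps one.
    """
    rng = np.random.default_rng(spec.seed)
    host_crown = spec.root_age * rng.uniform(0.75, 0.9)
    symb_crown = spec.root_age * rng.uniform(0.75, 0.9)
    host = simulate_bd_tree(spec.n_host, spec.birth, spec.death, host_crown,
                            rng, label_prefix="host")
    symb = simulate_bd_tree(spec.n_symbiont, spec.birth, spec.death,
                            symb_crown, rng, label_prefix="symb")
    tree = _join_clades(host, symb, spec.root_age)
    true_ages = tree.ages.copy()

    # host-analog internal nodes = internal nodes whose leaves are all hosts
    host_nodes = [
        i for i in tree.internal_ids
        if all(tree.labels[l].startswith("host") for l in tree.clade_leaf_ids(i))
    ]

    mu, sigma2 = sample_hyperpriors(spec.clock, rng)
    params = spec.clock.params(mu, sigma2)
    rates = simulate_rates(tree, params, rng)
    b_true = expected_branch_lengths(tree, rates)

    partitions = []
    for k in range(spec.n_partitions):
        sd = np.maximum(spec.noise_cv * b_true, 1e-8)
        b_hat = b_true + rng.normal(0.0, sd)
        H = np.diag(-1.0 / sd**2)
        partitions.append(
            PartitionData(b_hat=b_hat, gradient=np.zeros_like(b_true),
                          hessian=H, n_sites=5000, name=f"part{k}")
        )

    # calibrations: root bracket + internal host-clade nodes
    k_int = min(spec.n_internal_cals, len(host_nodes))
    chosen = sorted(
        rng.choice(len(host_nodes), size=k_int, replace=False).tolist()
    )
    cal_nodes = [host_nodes[j] for j in chosen]
    cals = []
    lo, hi = _bracket(rng, spec.root_age)
    cals.append(Calibration(clade=None, t_min=lo, t_max=hi, name="root"))
    for j, node in enumerate(cal_nodes):
        lo, hi = _bracket(rng, true_ages[node])
        if spec.placement == "cyano_like":
            hi = None
        cals.append(
            Calibration(
                clade=_clade_spec_for(tree, node, f"cal{j}"),
                t_min=lo, t_max=hi, name=f"cal{j}",
            )
        )
    calset = CalibrationSet(cals)
    # generator/validator closure: the emitted problem must pass its own checks
    calset.resolve(tree)
    return SyntheticDataset(
        spec=spec, tree=tree, true_ages=true_ages, true_rates=rates,
        true_mu=mu, true_sigma2=sigma2, partitions=partitions,
        calibrations=calset, host_node_ids=host_nodes,
    )


def matched_pair(spec: ScenarioSpec) -> tuple[SyntheticDataset, SyntheticDataset]:
    """The same world under mito-like and cyano-like calibration placement.

    Tree, rates, noise and calibration nodes/minima are identical (same
    seed); only the presence of internal maxima differs.
    """
    a = simulate_dataset(replace(spec, placement="mito_like"))
    b = simulate_dataset(replace(spec, placement="cyano_like"))
    return a, b


# --------------------------------------------------------- prior-predictive
def draw_prior_predictive(dataset: SyntheticDataset, seed: int,
                          noise_sd: np.ndarray | None = None,
                          prior_settings: MCMCSettings | None = None):
    """Redraw the hidden truth of ``dataset`` from the sampler's own prior.

    For calibration-coverage experiments the truth must come from exactly
    the prior the sampler assumes: node ages from the joint calibration /
    order-statistics prior (obtained from a short prior-only chain),
    hyperparameters from their gamma hyperpriors, rates from the clock
    model, and branch-length estimates as Gaussian noise with a covariance
    that does not depend on the drawn truth (``noise_sd``, fixed per
    scenario).  Returns a new :class:`SyntheticDataset` sharing topology and
    calibrations.
    """
    rng = np.random.default_rng(seed)
    tree = dataset.tree
    settings = prior_settings or MCMCSettings(
        burn_in=4000, sample_every=20, n_samples=50,
        seed=int(rng.integers(2**31 - 1)), prior_only=True,
    )
    prior_trace = run_mcmc(tree, dataset.calibrations, dataset.spec.clock,
                           settings=settings)
    ages = tree.ages.copy() if tree.ages is not None else np.zeros(tree.n_nodes)
    ages[:] = 0.0
    pick = int(rng.integers(prior_trace.n_samples))
    for k, i in enumerate(prior_trace.node_ids):
        ages[i] = prior_trace.ages[pick, k]
    dated = TimeTree(tree.parent.copy(), tree.labels, ages=ages)

    clock = dataset.spec.clock
    mu, sigma2 = sample_hyperpriors(clock, rng)
    rates = simulate_rates(dated, clock.params(mu, sigma2), rng)
    b_true = expected_branch_lengths(dated, rates)
    if noise_sd is None:
        root_cal = dataset.calibrations.root_calibration()
        t_ref = 0.25 * (root_cal.t_min + root_cal.t_max) / 2.0
        mu_ref = (clock.mu_prior.value if hasattr(clock.mu_prior, "value")
                  else clock.mu_prior.mean)
        noise_sd = np.full(b_true.size, dataset.spec.noise_cv * mu_ref * t_ref)
    partitions = []
    for k in range(dataset.spec.n_partitions):
        b_hat = b_true + rng.normal(0.0, noise_sd)
        H = np.diag(-1.0 / noise_sd**2)
        partitions.append(
            PartitionData(b_hat=b_hat, gradient=np.zeros_like(b_true),
                          hessian=H, n_sites=5000, name=f"part{k}")
        )
    return SyntheticDataset(
        spec=dataset.spec, tree=dated, true_ages=ages, true_rates=rates,
        true_mu=mu, true_sigma2=sigma2, partitions=partitions,
        calibrations=dataset.calibrations, host_node_ids=dataset.host_node_ids,
    )


# ---------------------------------------------------------------- benchmark
def benchmark_20leaf(seed: int = 42) -> SyntheticDataset:
    """The packaged 20-leaf benchmark: AR clock, 3 calibrations (root + 2
    internal), two partitions.  Deterministic for a given seed."""
    spec = ScenarioSpec(n_symbiont=12, n_host=8, n_internal_cals=2, seed=seed)
    return simulate_dataset(spec)


# -------------------------------------------------------------- host states
def simulate_host_states(tree: TimeTree, params: Mk2Params,
                         rng: np.random.Generator) -> HostCharacterMatrix:
    """Evolve a binary host character down the tree.

    The root state is drawn from the stationary distribution of the rate
    matrix (or the uniform/root distribution configured on ``params``) and
    children evolve by the exact 2-state transition probabilities over their
    branch lengths.
    """
    el = tree.edge_lengths
    if el is None:
        el = tree.edge_lengths_from_ages()
    states = np.zeros(tree.n_nodes, dtype=np.int64)
    pi = params.root_distribution()
    states[tree.root] = rng.choice(2, p=pi)
    for i in tree.preorder():
        if i == tree.root:
            continue
        P = transition_matrix(params, float(el[i]))
        states[i] = rng.choice(2, p=P[states[int(tree.parent[i])]])
    chars = {
        tree.labels[i]: ("A" if states[i] == 0 else "P")
        for i in tree.leaf_ids
    }
    return HostCharacterMatrix(chars)
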