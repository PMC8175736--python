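"""Approximate likelihood on branch lengths, plus an exact Poisson oracle.

Dating MCMC does not need the full sequence likelihood at every step: a
second-order Taylor expansion of the log-likelihood around the maximum
likelihood branch-length estimates ``b_hat`` is an excellent surrogate for
data sets with many sites.  A :class:`PartitionData` carries the sufficient
statistics of that expansion for one alignment partition — ``b_hat``, the
gradient and the Hessian (curvature) — and the approximate log-likelihood of
a dated, rate-annotated tree is

    ``g' (b - b_hat) + 1/2 (b - b_hat)' H (b - b_hat)``

summed over partitions (the constant is dropped).  Branch lengths ``b`` come
from the rate-times-duration identity.  The expansion is on the plain
branch-length scale.

The Poisson mode (per-branch substitution counts with ``counts ~
Poisson(sites * b)``) is an exact small-scale stand-in for a full
substitution-model likelihood, used as an independent oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clock import BranchRates
from .treedata import TimeTree

__all__ = [
    "PartitionData",
    "expected_branch_lengths",
    "approx_loglik",
    "poisson_loglik",
    "merge_partitions",
    "save_partitions",
    "load_partitions",
]


@dataclass
class PartitionData:
    """Second-order branch-length summary statistics for one partition.

    ``b_hat``, ``gradient``: length ``n_branches``; ``hessian``: symmetric
    ``n_branches x n_branches`` (negative definite for data simulated as
    Gaussian noise on branch lengths).  Branch index = child node id.
    """

    b_hat: np.ndarray
    gradient: np.ndarray
    hessian: np.ndarray
    n_sites: int = 0
    name: str = ""

    def __post_init__(self):
        self.b_hat = np.asarray(self.b_hat, dtype=float)
        self.gradient = np.asarray(self.gradient, dtype=float)
        self.hessian = np.asarray(self.hessian, dtype=float)
        nb = self.b_hat.size
        if self.gradient.size != nb or self.hessian.shape != (nb, nb):
            raise ValueError("PartitionData dimensions disagree")
        if not np.allclose(self.hessian, self.hessian.T, atol=1e-8):
            raise ValueError("Hessian must be symmetric")

    @property
    def n_branches(self) -> int:
        return self.b_hat.size

    def validate_against(self, tree: TimeTree) -> None:
        if self.n_branches != tree.n_nodes - 1:
            raise ValueError(
                f"partition has {self.n_branches} branches, tree has "
                f"{tree.n_nodes - 1}"
            )


def expected_branch_lengths(tree: TimeTree, rates) -> np.ndarray:
    """Per-branch expected substitutions/site: rate times duration."""
    r = rates.branch_rates if isinstance(rates, BranchRates) else np.asarray(rates, float)
    d = tree.durations()
    if r.shape != d.shape:
        raise ValueError("rates and branch durations differ in length")
    return r * d


def approx_loglik(tree: TimeTree, rates, partitions) -> float:
    """Second-order approximate log-likelihood (relative; constant dropped)."""
    if isinstance(partitions, PartitionData):
        partitions = [partitions]
    b = expected_branch_lengths(tree, rates)
    if np.any(b < 0):
        raise ValueError("negative branch lengths")
    total = 0.0
    for part in partitions:
        part.validate_against(tree)
        d = b - part.b_hat
        total += float(part.gradient @ d + 0.5 * d @ part.hessian @ d)
    if not np.isfinite(total):
        raise ValueError("non-finite approximate log-likelihood")
    return total


def poisson_loglik(tree: TimeTree, rates, counts, n_sites: int) -> float:
    """Exact log-likelihood of per-branch substitution counts.

    ``counts[j] ~ Poisson(n_sites * b_j)`` independently per branch.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    b = expected_branch_lengths(tree, rates)
    if counts.shape != b.shape:
        raise ValueError("counts and branches differ in length")
    return float(np.sum(stats.poisson.logpmf(counts, n_sites * b)))


def merge_partitions(partitions) -> PartitionData:
    """Combine partitions into a single-partition equivalent.

    The quadratic expansions add; the merged centre is the precision-weighted
    combination ``b_hat = (sum -H_p)^-1 sum (-H_p b_hat_p + g_p)`` with
    ``H = sum H_p`` and zero gradient, which reproduces the summed expansion
    up to a constant.
    """
    parts = list(partitions)
    if not parts:
        raise ValueError("no partitions to merge")
    nb = parts[0].n_branches
    H = np.zeros((nb, nb))
    v = np.zeros(nb)
    sites = 0
    for p in parts:
        if p.n_branches != nb:
            raise ValueError("partitions disagree on branch count")
        H += p.hessian
        v += -p.hessian @ p.b_hat + p.gradient
        sites += p.n_sites
    b_hat = np.linalg.solve(-H, v)
    return PartitionData(b_hat=b_hat, gradient=np.zeros(nb), hessian=H,
                         n_sites=sites, name="merged")


# ------------------------------------------------------------------ file IO
def save_partitions(partitions, outdir) -> None:
    """Write partitions as TSV (branch id, b_hat, gradient) plus a dense
    Hessian matrix file per partition and a JSON manifest binding them."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, p in enumerate(partitions):
        stem = p.name or f"part{k}"
        pd.DataFrame({
            "branch_id": np.arange(p.n_branches),
            "b_hat": p.b_hat,
            "gradient": p.gradient,
        }).to_csv(outdir / f"{stem}.tsv", sep="\t", index=False,
                  float_format="%.12g")
        np.savetxt(outdir / f"{stem}.hessian.tsv", p.hessian,
                   delimiter="\t", fmt="%.12g")
        entries.append({"name": stem, "stats": f"{stem}.tsv",
                        "hessian": f"{stem}.hessian.tsv",
                        "n_sites": int(p.n_sites),
                        "n_branches": int(p.n_branches)})
    (outdir / "partitions.json").write_text(
        json.dumps({"partitions": entries}, indent=2) + "\n")


def load_partitions(outdir) -> list:
    """Read partitions written by :func:`save_partitions`."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    manifest = json.loads((outdir / "partitions.json").read_text())
    out = []
    for entry in manifest["partitions"]:
        df = pd.read_csv(outdir / entry["stats"], sep="\t")
        H = np.loadtxt(outdir / entry["hessian"], delimiter="\t")
        out.append(PartitionData(
            b_hat=df["b_hat"].to_numpy(),
            gradient=df["gradient"].to_numpy(),
            hessian=np.atleast_2d(H), n_sites=entry["n_sites"],
            name=entry["name"]))
    return out
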