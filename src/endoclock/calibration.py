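"""Soft-bounded uniform fossil-calibration priors.

A calibration constrains a node's age to an interval ``[t_min, t_max]`` in
Ma, with uniform density inside and *soft* bounds: a small probability mass
(2.5% per side by default) lies beyond each bound, so that data conflicting
with a bound are penalised rather than assigned zero probability.  The tail
shapes follow the construction used by approximate-likelihood dating
software: a power-form density on ``(0, t_min)`` and an exponential-form
density on ``(t_max, inf)``, each with its parameter fixed by continuity of
the density at the bound.  Minimum-only calibrations (a fossil gives a hard
floor but no ceiling) are supported as an improper flat density above
``t_min`` with the same soft power tail below; they are proper only jointly
with a root calibration that carries a finite maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .treedata import CladeSpec, TimeTree, resolve_clade

__all__ = [
    "Calibration",
    "CalibrationSet",
    "soft_uniform_logpdf",
    "soft_uniform_sample",
    "check_consistency",
    "load_calibrations_tsv",
    "packaged_calibrations",
]


@dataclass(frozen=True)
class Calibration:
    """A soft-bounded uniform age calibration on a clade.

    ``t_max=None`` declares a minimum-only bound.  ``p_lower``/``p_upper``
    are the soft-tail probability masses (set to 0 for hard bounds).
    ``tags`` mark calibrations for sensitivity schemes (e.g. which maxima are
    considered controversial).
    """

    clade: CladeSpec | None
    t_min: float
    t_max: float | None
    p_lower: float = 0.025
    p_upper: float = 0.025
    name: str = ""
    tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.t_min <= 0:
            raise ValueError("t_min must be positive")
        if self.t_max is not None and self.t_max <= self.t_min:
            raise ValueError("t_max must exceed t_min")
        if self.p_lower < 0 or self.p_upper < 0:
            raise ValueError("tail probabilities must be non-negative")
        if self.p_lower + self.p_upper >= 1:
            raise ValueError("tail probabilities must sum to less than 1")

    @property
    def min_only(self) -> bool:
        return self.t_max is None

    # interior density height (per Ma) for a proper min–max calibration
    @property
    def interior_density(self) -> float:
        if self.min_only:
            raise ValueError("minimum-only calibration has no proper interior density")
        return (1.0 - self.p_lower - self.p_upper) / (self.t_max - self.t_min)

    def with_root_max(self, t_max: float) -> "Calibration":
        return replace(self, t_max=t_max)


def _tail_params(cal: Calibration):
    """(log interior height, lower power theta, upper exponential lambda)."""
    if cal.min_only:
        # flat (height 1) above t_min; power tail below carrying mass
        # t_min * p/(1-p) relative to a unit-height interior
        theta = (1.0 - cal.p_lower) / cal.p_lower if cal.p_lower > 0 else np.inf
        return 0.0, theta, np.nan
    h = cal.interior_density
    theta = h * cal.t_min / cal.p_lower if cal.p_lower > 0 else np.inf
    lam = h / cal.p_upper if cal.p_upper > 0 else np.inf
    return np.log(h), theta, lam


def soft_uniform_logpdf(t, cal: Calibration):
    """Log density (per Ma) of the soft-bounded uniform calibration at ``t``.

    For a proper calibration the density integrates to 1 on ``(0, inf)``:
    mass ``p_lower`` below ``t_min``, ``1 - p_lower - p_upper`` inside, and
    ``p_upper`` above ``t_max``, with the density continuous at both bounds.
    For a minimum-only calibration the (unnormalised) log density is 0 above
    ``t_min`` with the soft power tail below.
    """
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    scalar = np.ndim(t) == 0
    if np.any(arr <= 0):
        raise ValueError("ages must be positive")
    logh, theta, lam = _tail_params(cal)
    out = np.full(arr.shape, -np.inf)
    below = arr < cal.t_min
    if np.isfinite(theta):
        out[below] = logh + (theta - 1.0) * np.log(arr[below] / cal.t_min)
    if cal.min_only:
        out[~below] = 0.0
        return float(out[0]) if scalar else out
    above = arr > cal.t_max
    inside = ~below & ~above
    out[inside] = logh
    if np.isfinite(lam):
        out[above] = logh - lam * (arr[above] - cal.t_max)
    return float(out[0]) if scalar else out


def soft_uniform_sample(cal: Calibration, rng: np.random.Generator, size=None):
    """Exact draws from the soft-bounded uniform density (inverse CDF by region)."""
    if cal.min_only:
        raise ValueError("cannot sample a minimum-only (improper) calibration")
    n = 1 if size is None else int(np.prod(size))
    u = rng.random(n)
    _, theta, lam = _tail_params(cal)
    out = np.empty(n)
    pl, pu = cal.p_lower, cal.p_upper
    lower = u < pl
    upper = u >= 1.0 - pu
    mid = ~lower & ~upper
    if pl > 0:
        # CDF on (0, t_min): pl * (t/t_min)^theta
        out[lower] = cal.t_min * (u[lower] / pl) ** (1.0 / theta)
    out[mid] = cal.t_min + (cal.t_max - cal.t_min) * (u[mid] - pl) / (1.0 - pl - pu)
    if pu > 0:
        # survival on (t_max, inf): pu * exp(-lam (t - t_max))
        out[upper] = cal.t_max - np.log((1.0 - u[upper]) / pu) / lam
    if size is None:
        return float(out[0])
    return out.reshape(size)


class CalibrationSet:
    """An ordered collection of calibrations; the root must be calibrated.

    The root calibration is identified by ``name == "root"`` or by resolving
    to the root node of a given tree; it must carry a finite maximum so that
    the joint age prior is proper even when internal calibrations are
    minimum-only.
    """

    def __init__(self, calibrations):
        self.calibrations: list[Calibration] = list(calibrations)
        if not self.calibrations:
            raise ValueError("a calibration set requires a root calibration")

    def __iter__(self):
        return iter(self.calibrations)

    def __len__(self):
        return len(self.calibrations)

    def root_calibration(self) -> Calibration:
        for cal in self.calibrations:
            if cal.name == "root":
                return cal
        raise ValueError("no calibration named 'root' in the set")

    def resolve(self, tree: TimeTree) -> dict[int, Calibration]:
        """Map node id -> calibration; the root node must be covered."""
        out: dict[int, Calibration] = {}
        for cal in self.calibrations:
            if cal.name == "root" and cal.clade is None:
                node = tree.root
            else:
                node = resolve_clade(tree, cal.clade)
            if node in out:
                raise ValueError(f"node {node} carries more than one calibration")
            out[node] = cal
        if tree.root not in out:
            raise ValueError("the root node must be calibrated")
        if out[tree.root].min_only:
            raise ValueError("the root calibration must carry a finite maximum")
        return out

    def with_scheme(self, calibrations) -> "CalibrationSet":
        return CalibrationSet(calibrations)


def check_consistency(calset: CalibrationSet, tree: TimeTree) -> list[str]:
    """Flag descendant/ancestor calibration pairs with disjoint hard support.

    A calibrated descendant whose ``t_min`` exceeds a calibrated ancestor's
    ``t_max`` is impossible under hard bounds; with soft tails the joint
    density stays positive, so these are returned as warnings rather than
    raised.
    """
    by_node = calset.resolve(tree)
    violations = []
    for node, cal in by_node.items():
        i = int(tree.parent[node])
        while i != -1:
            anc = by_node.get(i)
            if anc is not None and not anc.min_only and cal.t_min > anc.t_max:
                violations.append(
                    f"calibration {cal.name or node} (t_min={cal.t_min}) conflicts "
                    f"with ancestor {anc.name or i} (t_max={anc.t_max})"
                )
            i = int(tree.parent[i])
    return violations


# ------------------------------------------------------------------- fixtures
def load_calibrations_tsv(source) -> CalibrationSet:
    """Read a calibration table.

    Columns: ``clade_name``, ``taxa`` (semicolon-separated leaf labels),
    ``group`` (crown/total), ``t_min``, ``t_max`` (empty for minimum-only),
    ``p_lower``, ``p_upper``.
    """
    df = pd.read_csv(source, sep="\t", comment="#")
    cals = []
    for _, row in df.iterrows():
        raw = row["taxa"]
        taxa = [] if pd.isna(raw) else [t for t in str(raw).split(";") if t]
        name = str(row["clade_name"])
        if taxa:
            clade = CladeSpec(frozenset(taxa), group=row["group"], name=name)
        elif name == "root":
            clade = None  # resolves to the root node directly
        else:
            raise ValueError(f"calibration {name!r} lists no taxa")
        t_max = row.get("t_max")
        t_max = None if pd.isna(t_max) else float(t_max)
        cals.append(
            Calibration(
                clade=clade,
                t_min=float(row["t_min"]),
                t_max=t_max,
                p_lower=float(row.get("p_lower", 0.025)),
                p_upper=float(row.get("p_upper", 0.025)),
                name=name,
            )
        )
    return CalibrationSet(cals)


def save_calibrations_tsv(calset: CalibrationSet, path) -> None:
    """Write a calibration table in the format :func:`load_calibrations_tsv`
    reads (empty ``t_max`` marks a minimum-only bound)."""
    rows = []
    for cal in calset:
        taxa = ";".join(sorted(cal.clade.taxa)) if cal.clade else ""
        rows.append({
            "clade_name": cal.name or (cal.clade.name if cal.clade else ""),
            "taxa": taxa,
            "group": cal.clade.group if cal.clade else "crown",
            "t_min": cal.t_min,
            "t_max": "" if cal.min_only else cal.t_max,
            "p_lower": cal.p_lower,
            "p_upper": cal.p_upper,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def packaged_calibrations(dataset: str = "mito") -> CalibrationSet:
    """The study-style calibration tables shipped with the package.

    ``dataset`` is ``"mito"`` (four Archaeplastida points + root bracket
    3000–1000 Ma) or ``"nuclear"`` (six additional eukaryotic points).
    """
    fname = {
        "mito": "calibrations_mito_encoded.tsv",
        "nuclear": "calibrations_nuclear_encoded.tsv",
    }.get(dataset)
    if fname is None:
        raise ValueError("dataset must be 'mito' or 'nuclear'")
    with resources.files("endoclock").joinpath("data", fname).open() as fh:
        return load_calibrations_tsv(fh)
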