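"""Tree and sequence data model.

The central container is :class:`TimeTree`, a rooted tree whose nodes carry
stable post-order integer ids.  All downstream tables (calibrations, branch
length statistics, posterior traces) key on these ids, so the id assignment is
part of the package contract: a node's id is its position in a left-to-right
post-order traversal of the input topology, which puts every child before its
parent and the root last.  Branches are identified by their child node, so a
tree with ``n`` nodes has branches ``0 .. n-2``.

Node ages are in Ma (million years before present); extant leaves sit at age
zero.  Trees read from Newick carry edge lengths instead, which can be
converted to ages when the tree is ultrametric.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from importlib import resources

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "CladeSpec",
    "Alignment",
    "parse_newick",
    "resolve_clade",
    "write_annotated_tree",
    "read_annotated_tree",
    "recode_alignment",
    "read_fasta",
    "write_fasta",
]

#: strict tolerance for parent-older-than-child checks, in Ma
AGE_EPSILON = 1e-9


class TimeTree:
    """Rooted tree with post-order integer node ids.

    Parameters
    ----------
    parent:
        Integer array of length ``n_nodes``; ``parent[i]`` is the id of the
        parent of node ``i`` and ``-1`` for the root (always id ``n_nodes-1``).
    labels:
        Mapping of leaf node id to taxon name.
    edge_lengths:
        Optional per-node length of the branch above the node (``nan`` for the
        root).
    ages:
        Optional per-node ages in Ma; leaves must be at age 0.
    """

    def __init__(self, parent, labels, edge_lengths=None, ages=None):
        self.parent = np.asarray(parent, dtype=np.int64)
        n = self.parent.size
        if n < 2:
            raise ValueError("a tree needs at least two nodes")
        if np.count_nonzero(self.parent < 0) != 1 or self.parent[n - 1] != -1:
            raise ValueError("exactly one root is required, with id n_nodes-1")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n - 1):
            p = int(self.parent[i])
            if not (i < p < n):
                raise ValueError("node ids must be post-ordered (child < parent)")
            self.children[p].append(i)
        self.labels = dict(labels)
        self.taxon_to_id = {name: i for i, name in self.labels.items()}
        if len(self.taxon_to_id) != len(self.labels):
            raise ValueError("duplicate leaf labels")
        for i in range(n):
            if not self.children[i] and i not in self.labels:
                raise ValueError(f"leaf node {i} has no label")
        self.edge_lengths = None if edge_lengths is None else np.asarray(
            edge_lengths, dtype=float
        )
        self.ages = None
        if ages is not None:
            self.set_ages(ages)

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return self.parent.size - 1

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaf_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def internal_ids(self) -> list[int]:
        """Internal node ids (including the root), in post-order."""
        return [i for i in range(self.n_nodes) if self.children[i]]

    def preorder(self):
        """Node ids, parents before children."""
        stack = [self.root]
        while stack:
            i = stack.pop()
            yield i
            stack.extend(reversed(self.children[i]))

    # ------------------------------------------------------------------- ages
    def set_ages(self, ages) -> None:
        ages = np.asarray(ages, dtype=float)
        if ages.size != self.n_nodes:
            raise ValueError("ages must cover every node")
        if np.any(ages < 0):
            raise ValueError("ages must be non-negative")
        for i in self.leaf_ids:
            if abs(ages[i]) > AGE_EPSILON:
                raise ValueError("all leaves must be at age 0 (extant sampling)")
        for i in range(self.n_nodes - 1):
            if ages[int(self.parent[i])] - ages[i] <= AGE_EPSILON:
                raise ValueError(
                    f"age(parent) must exceed age(child) for node {i} "
                    "(zero-duration branches are not allowed in a chronogram)"
                )
        self.ages = ages

    def ages_from_edge_lengths(self, tol: float = 1e-6):
        """Interpret edge lengths as time and recover node ages.

        Requires the tree to be ultrametric to relative tolerance ``tol``.
        """
        if self.edge_lengths is None:
            raise ValueError("tree has no edge lengths")
        depth = np.zeros(self.n_nodes)
        for i in self.preorder():
            if i != self.root:
                depth[i] = depth[int(self.parent[i])] + self.edge_lengths[i]
        height = depth.max()
        leaf_depths = depth[self.leaf_ids]
        if np.max(np.abs(leaf_depths - height)) > tol * max(height, 1.0):
            raise ValueError("tree is not ultrametric; cannot assign ages")
        ages = height - depth
        ages[self.leaf_ids] = 0.0
        self.set_ages(ages)
        return self.ages

    def durations(self) -> np.ndarray:
        """Branch durations in Ma, indexed by child node id (length n-1)."""
        if self.ages is None:
            raise ValueError("tree has no ages")
        idx = np.arange(self.n_nodes - 1)
        return self.ages[self.parent[idx]] - self.ages[idx]

    def edge_lengths_from_ages(self) -> np.ndarray:
        d = self.durations()
        return np.concatenate([d, [np.nan]])

    # ------------------------------------------------------------------- MRCA
    def mrca(self, node_ids) -> int:
        """Most recent common ancestor of a set of node ids."""
        ids = list(node_ids)
        if not ids:
            raise ValueError("empty node set")
        ancestors = set()
        i = ids[0]
        while i != -1:
            ancestors.add(i)
            i = int(self.parent[i])
        best = self.root
        for j in ids[1:]:
            i = j
            while i not in ancestors:
                i = int(self.parent[i])
            # restrict to ancestors of all seen so far
            keep = set()
            k = i
            while k != -1:
                keep.add(k)
                k = int(self.parent[k])
            ancestors &= keep
        # the MRCA is the minimum (deepest, post-order) surviving ancestor
        return min(ancestors)

    def clade_leaf_ids(self, node: int) -> set[int]:
        out = set()
        stack = [node]
        while stack:
            i = stack.pop()
            if self.is_leaf(i):
                out.add(i)
            stack.extend(self.children[i])
        return out

    # ------------------------------------------------------------------ write
    def newick(self, lengths: str = "auto", digits: int = 12) -> str:
        """Serialize to Newick.

        ``lengths`` is one of ``auto`` (ages if present, else stored edge
        lengths, else none), ``ages``, ``edges`` or ``none``.
        """
        if lengths == "auto":
            lengths = "ages" if self.ages is not None else (
                "edges" if self.edge_lengths is not None else "none"
            )
        if lengths == "ages":
            el = self.edge_lengths_from_ages()
        elif lengths == "edges":
            el = self.edge_lengths
            if el is None:
                raise ValueError("tree has no edge lengths")
        else:
            el = None

        def fmt(i: int) -> str:
            if self.is_leaf(i):
                s = _quote_label(self.labels[i])
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[i]) + ")"
            if el is not None and i != self.root:
                s += f":{el[i]:.{digits}g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<TimeTree {self.n_leaves} leaves, {self.n_nodes} nodes"
            + (", dated" if self.ages is not None else "")
            + ">"
        )


def _quote_label(name: str) -> str:
    if re.search(r"[\s()\[\]{}:;,'\"]", name):
        return "'" + name.replace("'", "''") + "'"
    return name


# ---------------------------------------------------------------------- parse
def _from_dendropy(dtree: dendropy.Tree) -> tuple[TimeTree, dict]:
    order = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=np.int64)
    labels = {}
    lengths = np.full(n, np.nan)
    any_len = False
    meta = {}
    for i, nd in enumerate(order):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is not None:
                lengths[i] = float(nd.edge.length)
                any_len = True
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise ValueError("unlabeled leaf in input tree")
            labels[i] = nd.taxon.label
        if nd.annotations:
            meta[i] = {a.name: a.value for a in nd.annotations}
    tree = TimeTree(parent, labels, edge_lengths=lengths if any_len else None)
    return tree, meta


def parse_newick(text: str, dating: bool = False) -> TimeTree:
    """Parse a Newick string into a :class:`TimeTree` topology.

    Branch lengths are preserved when present.  With ``dating=True`` the tree
    must be usable as a rooted chronogram scaffold: an explicitly unrooted
    tree or a basal polytomy is rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise ValueError(f"malformed Newick: {exc}") from exc
    if dating:
        if dtree.is_rooted is False:
            raise ValueError("unrooted tree rejected in dating mode")
        if len(dtree.seed_node.child_nodes()) != 2:
            raise ValueError("basal polytomy rejected in dating mode")
    tree, _ = _from_dendropy(dtree)
    return tree


# ---------------------------------------------------------------------- clade
@dataclass(frozen=True)
class CladeSpec:
    """A clade named by a set of leaf labels.

    ``group`` is ``crown`` (the MRCA of the named taxa) or ``total`` (the
    stem: the MRCA's parent node, whose subtending branch carries the clade's
    extinct stem lineage).
    """

    taxa: frozenset[str]
    group: str = "crown"
    name: str = ""

    def __post_init__(self):
        if not self.taxa:
            raise ValueError("CladeSpec needs at least one taxon")
        if self.group not in ("crown", "total"):
            raise ValueError("group must be 'crown' or 'total'")

    @staticmethod
    def of(*taxa: str, group: str = "crown", name: str = "") -> "CladeSpec":
        return CladeSpec(frozenset(taxa), group=group, name=name)


def resolve_clade(tree: TimeTree, spec: CladeSpec) -> int:
    """Resolve a :class:`CladeSpec` to a node id on ``tree``."""
    ids = []
    for name in spec.taxa:
        if name not in tree.taxon_to_id:
            raise KeyError(f"taxon {name!r} not found in tree")
        ids.append(tree.taxon_to_id[name])
    node = tree.mrca(ids)
    if spec.group == "total":
        if node == tree.root:
            raise ValueError("total-group calibration on the root MRCA is undefined")
        node = int(tree.parent[node])
    return node


# ------------------------------------------------------------ annotated trees
def write_annotated_tree(tree: TimeTree, summary: dict[int, tuple]) -> str:
    """Write a NEXUS tree block with per-node age summaries.

    ``summary`` maps every internal node id to ``(mean, hpd_lower,
    hpd_upper)`` in Ma.  Branch lengths are written from the summary means so
    the file re-parses into the summarized chronogram; metadata comments in
    figtree style carry the mean and the 95% HPD bounds.
    """
    for i in tree.internal_ids:
        if i not in summary:
            raise ValueError(f"missing summary for internal node {i}")
        mean, lo, hi = summary[i]
        if not (lo <= mean <= hi):
            raise ValueError(
                f"node {i}: HPD bounds ({lo}, {hi}) must bracket the mean {mean}"
            )
    means = np.zeros(tree.n_nodes)
    for i, (mean, _, _) in summary.items():
        means[i] = mean

    def fmt(i: int) -> str:
        if tree.is_leaf(i):
            s = _quote_label(tree.labels[i])
        else:
            mean, lo, hi = summary[i]
            s = "(" + ",".join(fmt(c) for c in tree.children[i]) + ")"
            s += f"[&age_mean={mean:.10g},age_hpd_lower={lo:.10g},age_hpd_upper={hi:.10g}]"
        if i != tree.root:
            s += f":{means[int(tree.parent[i])] - means[i]:.10g}"
        return s

    lines = [
        "#NEXUS",
        "BEGIN TREES;",
        f"    TREE dated = [&R] {fmt(tree.root)};",
        "END;",
    ]
    return "\n".join(lines) + "\n"


def read_annotated_tree(text: str) -> tuple[TimeTree, dict[int, tuple]]:
    """Parse a NEXUS file written by :func:`write_annotated_tree`.

    Returns the tree (with ages recovered from the annotated means) and the
    node-id -> ``(mean, lower, upper)`` summary table.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="nexus",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed NEXUS: {exc}") from exc
    tree, meta = _from_dendropy(dtree)
    summary = {}
    ages = np.zeros(tree.n_nodes)
    for i in tree.internal_ids:
        md = meta.get(i, {})
        try:
            mean = float(md["age_mean"])
            lo = float(md["age_hpd_lower"])
            hi = float(md["age_hpd_upper"])
        except KeyError as exc:
            raise ValueError(f"node {i} lacks age annotations") from exc
        summary[i] = (mean, lo, hi)
        ages[i] = mean
    tree.set_ages(ages)
    return tree, summary


# ------------------------------------------------------------------ alignment
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
RECODED_ALPHABET = set("ACGT")


@dataclass
class Alignment:
    """Ordered aligned records with a declared alphabet.

    ``alphabet`` is ``"amino-acid"`` or ``"recoded-4-state"``; gap ``-`` and
    ambiguity ``X`` are always permitted.
    """

    names: list[str]
    seqs: list[str]
    alphabet: str = "amino-acid"

    def __post_init__(self):
        if len(self.names) != len(self.seqs):
            raise ValueError("names and sequences differ in count")
        if len({len(s) for s in self.seqs} | {0} if not self.seqs else {len(s) for s in self.seqs}) > 1:
            raise ValueError("all sequences must have equal length")
        allowed = (AA_ALPHABET if self.alphabet == "amino-acid" else RECODED_ALPHABET)
        allowed = allowed | {"-", "X"}
        for name, s in zip(self.names, self.seqs):
            bad = set(s.upper()) - allowed
            if bad:
                raise ValueError(f"{name}: characters {sorted(bad)} outside alphabet")

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0


def read_fasta(source, alphabet: str = "amino-acid") -> Alignment:
    from Bio import SeqIO

    handle = io.StringIO(source) if isinstance(source, str) and "\n" in source else source
    names, seqs = [], []
    for rec in SeqIO.parse(handle, "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return Alignment(names, seqs, alphabet)


def write_fasta(aln: Alignment, handle) -> None:
    own = isinstance(handle, (str,))
    fh = open(handle, "w") if own else handle
    try:
        for name, s in zip(aln.names, aln.seqs):
            fh.write(f">{name}\n{s}\n")
    finally:
        if own:
            fh.close()


def _load_recode_table(scheme: str) -> dict[str, str]:
    fname = {"sr4": "recode_sr4.tsv", "dayhoff4": "recode_dayhoff4.tsv"}.get(
        scheme.lower()
    )
    if fname is None:
        raise ValueError(f"unknown recoding scheme {scheme!r}")
    table = {}
    text = resources.files("endoclock").joinpath("data", fname).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        residue, code = line.split("\t")
        table[residue] = code
    return table


def recode_alignment(
    aln: Alignment, scheme: str = "dayhoff4", on_unknown: str = "error"
) -> Alignment:
    """Collapse the 20 amino acids to 4 characters.

    Deep bacterial phylogenies suffer from compositional heterogeneity;
    recoding to four physicochemical groups (written as nucleotide symbols)
    reduces it.  ``scheme`` is ``dayhoff4`` or ``sr4``; the group tables ship
    as data files.  Gaps and ``X`` pass through; a residue absent from the
    table raises (``on_unknown="error"``) or is masked to ``X``.
    """
    if aln.alphabet != "amino-acid":
        raise ValueError("recoding expects an amino-acid alignment")
    table = _load_recode_table(scheme)
    out = []
    for name, s in zip(aln.names, aln.seqs):
        chars = []
        for c in s.upper():
            if c in ("-", "X"):
                chars.append(c)
            elif c in table:
                chars.append(table[c])
            elif on_unknown == "mask":
                chars.append("X")
            else:
                raise ValueError(f"{name}: residue {c!r} not in {scheme} table")
        out.append("".join(chars))
    return Alignment(list(aln.names), out, alphabet="recoded-4-state")
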