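"""Rooted phylogenies and posterior tree samples.

Trees are stored in a compact array form (parent pointers, branch lengths,
tip labels) that the likelihood and mapping code can traverse cheaply.
Parsing and serialisation of Newick/NEXUS go through dendropy; the array
form is the canonical in-memory representation.

All trees are rooted.  Branch lengths are in the time units of the input
(millions of years for the study system this package was built around).
Polytomies are preserved.  Unrooted input is rejected rather than silently
re-rooted, because crown/stem node identity depends on the root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeSample",
    "CladeDefinition",
    "CladeNodes",
    "TreeError",
    "parse_newick",
    "write_newick",
    "read_tree_sample",
    "write_tree_sample",
    "relabel_and_prune",
    "clade_nodes",
]


class TreeError(ValueError):
    """Raised for malformed trees, labels, or tree samples."""


class PhyloTree:
    """A rooted tree with branch lengths and unique tip labels.

    Nodes are integer ids ``0 .. n_nodes-1`` assigned in deterministic
    preorder (input order).  The root is node 0 and has no branch length
    contribution (``blen[0]`` is 0 by convention).
    """

    __slots__ = ("parent", "blen", "children", "label", "_postorder", "_ntips", "_levels")

    def __init__(
        self,
        parent: np.ndarray,
        blen: np.ndarray,
        label: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        self.label = list(label)
        n = len(self.parent)
        if n == 0:
            raise TreeError("empty tree")
        if (self.parent == -1).sum() != 1 or self.parent[0] != -1:
            raise TreeError("tree must have exactly one root at node 0")
        if np.any(self.blen < 0):
            raise TreeError("negative branch lengths are not allowed")
        kids: list[list[int]] = [[] for _ in range(n)]
        for v in range(1, n):
            p = int(self.parent[v])
            if not 0 <= p < n:
                raise TreeError(f"node {v} has invalid parent {p}")
            kids[p].append(v)
        self.children = [tuple(c) for c in kids]
        tips = [v for v in range(n) if not self.children[v]]
        self._ntips = len(tips)
        labs = [self.label[v] for v in tips]
        if any(l is None for l in labs):
            raise TreeError("every tip must carry a label")
        if len(set(labs)) != len(labs):
            dups = sorted({l for l in labs if labs.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dups}")
        for v in range(n):
            if self.children[v] and len(self.children[v]) < 2 and v != 0:
                raise TreeError(f"internal node {v} is a unifurcation")
        if self.children[0] and len(self.children[0]) < 2:
            raise TreeError("root is a unifurcation")
        self._postorder = None
        self._levels = None

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return self._ntips

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    @property
    def tip_indices(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.children[v]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.label[v] for v in self.tip_indices]

    def postorder(self) -> np.ndarray:
        """Node ids in post-order (children before parents); cached."""
        if self._postorder is None:
            order: list[int] = []
            stack = [0]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    def levels(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Internal nodes grouped by height for vectorised post-order passes.

        Returns, per ascending height, ``(nodes, child_ids, starts)``
        where ``child_ids`` concatenates the children of all ``nodes`` at
        that height, grouped per parent, and ``starts`` marks the start of
        each parent's group (usable with ``np.multiply.reduceat``).  All
        children of a level's nodes lie in strictly lower levels, so
        partial likelihoods can be computed one level at a time with
        array operations.
        """
        if self._levels is None:
            height = np.zeros(self.n_nodes, dtype=np.int64)
            for v in self.postorder():
                if self.children[v]:
                    height[v] = 1 + max(height[c] for c in self.children[v])
            levels = []
            for h in range(1, int(height.max()) + 1):
                nodes = np.flatnonzero(height == h)
                child_ids, starts = [], []
                for v in nodes:
                    starts.append(len(child_ids))
                    child_ids.extend(self.children[v])
                levels.append(
                    (nodes, np.array(child_ids, dtype=np.int64),
                     np.array(starts, dtype=np.int64))
                )
            self._levels = levels
        return self._levels

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (sum of branch lengths)."""
        d = np.zeros(self.n_nodes)
        for v in self.postorder()[::-1]:
            if v:
                d[v] = d[self.parent[v]] + self.blen[v]
        return d

    def mrca(self, nodes: Iterable[int]) -> int:
        """Most recent common ancestor of a set of node ids."""
        nodes = list(nodes)
        if not nodes:
            raise TreeError("mrca of empty node set")
        anc = self._ancestor_chain(nodes[0])
        common = set(anc)
        for v in nodes[1:]:
            common &= set(self._ancestor_chain(v))
        for a in anc:  # chain is ordered node -> root; first common is MRCA
            if a in common:
                return a
        raise AssertionError("root must be a common ancestor")

    def _ancestor_chain(self, v: int) -> list[int]:
        chain = [v]
        while self.parent[chain[-1]] != -1:
            chain.append(int(self.parent[chain[-1]]))
        return chain

    def subtree_tips(self, v: int) -> set[str]:
        """Labels of all tips below (and including) node ``v``."""
        out: set[str] = set()
        stack = [v]
        while stack:
            u = stack.pop()
            if self.children[u]:
                stack.extend(self.children[u])
            else:
                out.add(self.label[u])
        return out

    def tip_index(self, label: str) -> int:
        for v in self.tip_indices:
            if self.label[v] == label:
                return v
        raise TreeError(f"tip label not found: {label!r}")

    def patristic_distance(self, a: str, b: str) -> float:
        """Path length between two tips (test oracle helper)."""
        ia, ib = self.tip_index(a), self.tip_index(b)
        d = self.depths()
        m = self.mrca([ia, ib])
        return float(d[ia] + d[ib] - 2 * d[m])

    # -- conversion ----------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        seed = tree.seed_node
        index: dict[int, int] = {}
        parent, blen, label = [], [], []
        for i, nd in enumerate(tree.preorder_node_iter()):
            index[id(nd)] = i
            parent.append(-1 if nd is seed else index[id(nd.parent_node)])
            bl = nd.edge.length
            blen.append(0.0 if (nd is seed or bl is None) else float(bl))
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            label.append(lab)
        return cls(np.array(parent), np.array(blen), label)

    def to_newick(self, sig_digits: int = 10) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{sig_digits}g}"

        parts: dict[int, str] = {}
        for v in self.postorder():
            if self.is_tip(v):
                s = _quote_label(self.label[v])
            else:
                s = "(" + ",".join(parts.pop(c) for c in self.children[v]) + ")"
                if self.label[v]:
                    s += _quote_label(self.label[v])
            if v != 0:
                s += ":" + fmt(self.blen[v])
            parts[v] = s
        return parts[0] + ";"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return (
            np.array_equal(self.parent, other.parent)
            and np.allclose(self.blen, other.blen, rtol=0, atol=0)
            and self.label == other.label
        )

    def __repr__(self) -> str:
        return f"<PhyloTree {self.n_tips} tips, {self.n_nodes} nodes>"


def _quote_label(lab: str) -> str:
    if any(c in lab for c in "(),:;[]' \t\n"):
        return "'" + lab.replace("'", "''") + "'"
    return lab


@dataclass
class TreeSample:
    """An ordered posterior sample of trees with shared tip set."""

    trees: list[PhyloTree]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self.trees[0].tip_labels)


@dataclass(frozen=True)
class CladeDefinition:
    """A named clade given as a set of tip labels."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise TreeError(f"clade {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass(frozen=True)
class CladeNodes:
    """Crown/stem node ids of a clade on one tree.

    crown is the MRCA of the clade members present as tips; stem is its
    parent, or None when the crown is the root.  ``monophyletic`` is true
    when the crown subtree contains exactly the present members.
    """

    clade_name: str
    crown: int
    stem: int | None
    monophyletic: bool
    n_members_present: int
    degenerate: bool = False  # single member present


# ---------------------------------------------------------------------------
# parsing / writing


def parse_newick(text: str) -> PhyloTree:
    """Parse one rooted Newick string into a :class:`PhyloTree`."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="default-rooted",
        )
    except Exception as exc:  # dendropy errors carry line/column context
        raise TreeError(f"malformed newick: {exc}") from exc
    return PhyloTree.from_dendropy(dtree)


def write_newick(tree: PhyloTree, sig_digits: int = 10) -> str:
    return tree.to_newick(sig_digits=sig_digits)


def read_tree_sample(
    paths: str | Sequence[str],
    schema: str = "newick",
    burnin: float = 0.0,
    thin: int = 1,
) -> TreeSample:
    """Read a posterior tree sample from one or more files.

    ``burnin`` is the fraction of initial trees dropped *per file* (the
    study applied 25% burnin to each of two independent runs before
    pooling).  ``thin`` keeps every ``thin``-th post-burnin tree; the
    default keeps all, since how the study thinned to its 300 trees is
    not recorded.
    """
    if isinstance(paths, (str, bytes)) or not isinstance(paths, (list, tuple)):
        paths = [paths]
    if not 0 <= burnin < 1:
        raise TreeError(f"burnin must be in [0, 1): {burnin}")
    if thin < 1:
        raise TreeError("thin must be >= 1")
    trees: list[PhyloTree] = []
    for path in paths:
        try:
            tl = dendropy.TreeList.get(
                path=str(path),
                schema=schema,
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
                rooting="default-rooted",
            )
        except Exception as exc:
            raise TreeError(f"cannot read tree file {path}: {exc}") from exc
        if len(tl) == 0:
            raise TreeError(f"no trees in {path}")
        drop = math.floor(burnin * len(tl))
        kept = [PhyloTree.from_dendropy(t) for t in tl[drop::thin]]
        trees.extend(kept)
    universe = set(trees[0].tip_labels)
    for i, t in enumerate(trees[1:], start=1):
        tips = set(t.tip_labels)
        if tips != universe:
            diff = sorted(tips.symmetric_difference(universe))
            raise TreeError(
                f"tree {i} tip set differs from tree 0; symmetric difference: {diff}"
            )
    return TreeSample(
        trees,
        provenance={
            "paths": [str(p) for p in paths],
            "schema": schema,
            "burnin": burnin,
            "thin": thin,
        },
    )


def write_tree_sample(sample: TreeSample, path: str, sig_digits: int = 10) -> None:
    with open(path, "w") as fh:
        for t in sample:
            fh.write(t.to_newick(sig_digits=sig_digits) + "\n")


# ---------------------------------------------------------------------------
# relabel / prune


def relabel_and_prune(
    tree: PhyloTree,
    keep: Iterable[str],
    mapping: Mapping[str, str] | None = None,
) -> PhyloTree:
    """Relabel tips, keep a subset, and suppress resulting unifurcations.

    Branch lengths along suppressed paths are summed, so patristic
    distances among kept tips are preserved.  A root left with a single
    child collapses into that child (which becomes the new root).
    """
    mapping = dict(mapping or {})
    newlab = list(tree.label)
    seen: dict[str, int] = {}
    for v in tree.tip_indices:
        lab = mapping.get(tree.label[v], tree.label[v])
        if lab in seen:
            raise TreeError(f"relabel mapping collides two tips onto {lab!r}")
        seen[lab] = v
        newlab[v] = lab
    keep = set(keep)
    missing = keep - set(seen)
    if missing:
        raise TreeError(f"keep labels not present as tips: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeError("at least 2 tips must be kept")

    # number of kept tips below each node
    nkeep = np.zeros(tree.n_nodes, dtype=int)
    for v in tree.postorder():
        if tree.is_tip(v):
            nkeep[v] = int(newlab[v] in keep)
        else:
            nkeep[v] = sum(nkeep[c] for c in tree.children[v])

    # rebuild bottom-up: each surviving node maps to (parent-slot list) of
    # (accumulated branch length, subtree spec); specs are nested tuples
    built: dict[int, tuple[float, dict]] = {}
    for v in tree.postorder():
        if nkeep[v] == 0:
            continue
        if tree.is_tip(v):
            built[v] = (tree.blen[v], {"label": newlab[v], "children": []})
            continue
        kids = [built.pop(c) for c in tree.children[v] if nkeep[c] > 0]
        if len(kids) == 1:  # unifurcation: splice through, summing lengths
            bl, spec = kids[0]
            built[v] = (tree.blen[v] + bl, spec)
        else:
            built[v] = (
                tree.blen[v],
                {"label": None, "children": kids},
            )

    _, rootspec = built[0]
    parent, blen, label = [], [], []

    def emit(spec: dict, parent_id: int, edge_len: float) -> None:
        my = len(parent)
        parent.append(parent_id)
        blen.append(edge_len if parent_id != -1 else 0.0)
        label.append(spec["label"])
        for bl, child in spec["children"]:
            emit(child, my, bl)

    emit(rootspec, -1, 0.0)
    return PhyloTree(np.array(parent), np.array(blen), label)


def clade_nodes(tree: PhyloTree, clade: CladeDefinition) -> CladeNodes:
    """Locate the crown (MRCA of present members) and stem nodes of a clade."""
    present = [v for v in tree.tip_indices if tree.label[v] in clade.members]
    if not present:
        raise TreeError(f"no members of clade {clade.name!r} present on tree")
    degenerate = len(present) == 1
    crown = present[0] if degenerate else tree.mrca(present)
    stem = int(tree.parent[crown]) if tree.parent[crown] != -1 else None
    below = tree.subtree_tips(crown)
    mono = below == {tree.label[v] for v in present}
    return CladeNodes(
        clade_name=clade.name,
        crown=int(crown),
        stem=stem,
        monophyletic=bool(mono),
        n_members_present=len(present),
        degenerate=degenerate,
    )
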