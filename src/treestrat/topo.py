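"""Topology comparison of per-gene phylogeny estimates.

This module holds the tree container (:class:`PhyloTree`), split/cluster
extraction, and the two topology-only distances used to build the per-gene
distance matrices: the Robinson-Foulds distance (symmetric difference of
splits or clusters) and a matching-based distance (minimum-weight perfect
matching between the two split systems, solved with the Hungarian
algorithm).  Branch lengths and support values survive parsing but are never
consulted by the metrics: all comparisons are purely topological, which is
what the downstream consensus logic relies on (distance zero iff identical
topology).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "NewickError",
    "DuplicateLeafError",
    "LeafSetError",
    "TooFewLeavesError",
    "TreeNode",
    "PhyloTree",
    "split_system",
    "rf_distance",
    "matching_distance",
    "distance_matrix",
    "DistanceMatrix",
]


class NewickError(ValueError):
    """Malformed Newick string (unbalanced parentheses, stray tokens...)."""


class DuplicateLeafError(NewickError):
    """Two leaves in one tree carry the same label."""


class LeafSetError(ValueError):
    """Two trees being compared do not share the same leaf label set."""


class TooFewLeavesError(ValueError):
    """Tree too small to carry any nontrivial split/cluster."""


class TreeNode:
    """One node of a phylogeny: children, optional label and branch length."""

    __slots__ = ("label", "length", "children")

    def __init__(self, label: str | None = None, length: float | None = None,
                 children: list["TreeNode"] | None = None):
        self.label = label
        self.length = length
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted-representation phylogenetic tree with unique leaf labels.

    Whether the tree is *interpreted* as rooted or unrooted is decided by the
    metric functions: a root of degree two signals a rooted tree, otherwise
    the root is a basal polytomy of an unrooted tree.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [n.label for n in self._iter_nodes() if n.is_leaf]
        if any(l is None or l == "" for l in labels):
            raise NewickError("tree contains an unlabelled leaf")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise DuplicateLeafError(
                f"duplicate leaf label(s): {', '.join(sorted(dupes))}")
        self._leaves = tuple(labels)

    def _iter_nodes(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def leaves(self) -> tuple[str, ...]:
        """Leaf labels in traversal (Newick) order."""
        return self._leaves

    @property
    def leaf_set(self) -> frozenset[str]:
        return frozenset(self._leaves)

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def has_bifurcating_root(self) -> bool:
        return len(self.root.children) == 2

    # -- Newick ------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a single Newick tree from *text* (trailing ';' optional)."""
        s = text.strip()
        if s.endswith(";"):
            s = s[:-1]
        if not s:
            raise NewickError("empty Newick string")
        pos = 0

        def skip_ws() -> None:
            nonlocal pos
            while pos < len(s) and s[pos].isspace():
                pos += 1

        def read_label() -> str:
            nonlocal pos
            skip_ws()
            if pos < len(s) and s[pos] == "'":
                end = s.find("'", pos + 1)
                if end < 0:
                    raise NewickError("unterminated quoted label")
                lab = s[pos + 1:end]
                pos = end + 1
                return lab
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            return s[start:pos].strip()

        def parse_node() -> TreeNode:
            nonlocal pos
            node = TreeNode()
            skip_ws()
            if pos < len(s) and s[pos] == "(":
                pos += 1
                while True:
                    node.children.append(parse_node())
                    skip_ws()
                    if pos >= len(s):
                        raise NewickError("unbalanced parentheses")
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
                    raise NewickError(
                        f"unexpected character {s[pos]!r} at position {pos}")
            label = read_label()
            node.label = label or None
            skip_ws()
            if pos < len(s) and s[pos] == ":":
                pos += 1
                start = pos
                while pos < len(s) and s[pos] not in "(),:;":
                    pos += 1
                try:
                    node.length = float(s[start:pos])
                except ValueError as exc:
                    raise NewickError(
                        f"bad branch length {s[start:pos]!r}") from exc
            return node

        root = parse_node()
        skip_ws()
        if pos != len(s):
            raise NewickError(
                f"trailing characters after tree: {s[pos:]!r}")
        if root.is_leaf:
            raise NewickError("tree has a single node")
        return cls(root)

    def to_newick(self, lengths: bool = True) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                out = node.label or ""
            else:
                out = "(" + ",".join(render(c) for c in node.children) + ")"
                if node.label:
                    out += node.label
            if lengths and node.length is not None:
                out += f":{node.length:g}"
            return out

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.to_newick(lengths=False)!r})"


def _resolve_mode(mode: str, *trees: PhyloTree) -> str:
    if mode not in ("auto", "rooted", "unrooted"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "auto":
        return mode
    return "rooted" if all(t.has_bifurcating_root for t in trees) else "unrooted"


def split_system(tree: PhyloTree, mode: str = "auto") -> frozenset[frozenset[str]]:
    """Nontrivial splits (unrooted) or clusters (rooted) of *tree*.

    Unrooted splits are canonicalised as the bipartition side that does not
    contain the lexicographically smallest leaf, so equal topologies always
    yield equal systems regardless of root placement.  Trivial entries
    (singleton or near-full sides, full set) are excluded.
    """
    mode = _resolve_mode(mode, tree)
    n = tree.n_leaves
    if (mode == "unrooted" and n < 3) or (mode == "rooted" and n < 2):
        raise TooFewLeavesError(
            f"{n} leaves is too few for a {mode} split system")
    leaf_set = tree.leaf_set
    ref = min(leaf_set)

    clades: list[frozenset[str]] = []

    def collect(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset((node.label,))
        below = frozenset().union(*(collect(c) for c in node.children))
        if node is not tree.root:
            clades.append(below)
        return below

    collect(tree.root)

    out: set[frozenset[str]] = set()
    for clade in clades:
        if mode == "rooted":
            if 2 <= len(clade) < n:
                out.add(clade)
        else:
            side = leaf_set - clade if ref in clade else clade
            if 2 <= len(side) <= n - 2:
                out.add(side)
    return frozenset(out)


def _check_leaf_sets(t1: PhyloTree, t2: PhyloTree) -> None:
    if t1.leaf_set != t2.leaf_set:
        only1 = sorted(t1.leaf_set - t2.leaf_set)
        only2 = sorted(t2.leaf_set - t1.leaf_set)
        raise LeafSetError(
            "trees have different leaf sets; "
            f"only in first: {only1}; only in second: {only2}")


def rf_distance(t1: PhyloTree, t2: PhyloTree, mode: str = "auto",
                normalized: bool = False) -> int | float:
    """Robinson-Foulds distance: |S1 xor S2| over split/cluster systems.

    With ``normalized=True`` the raw count is divided by ``|S1| + |S2|``
    (the maximum attainable for these two trees), yielding a value in [0, 1].
    """
    _check_leaf_sets(t1, t2)
    mode = _resolve_mode(mode, t1, t2)
    s1 = split_system(t1, mode)
    s2 = split_system(t2, mode)
    raw = len(s1 ^ s2)
    if not normalized:
        return raw
    denom = len(s1) + len(s2)
    return raw / denom if denom else 0.0


def _pair_weight(a: frozenset[str], b: frozenset[str], leaf_set: frozenset[str],
                 mode: str) -> int:
    if mode == "rooted":
        return len(a ^ b)
    # unrooted: a split may be matched in either orientation
    return min(len(a ^ b), len((leaf_set - a) ^ b))


def matching_distance(t1: PhyloTree, t2: PhyloTree, mode: str = "auto") -> int:
    """Matching-based topology distance between two trees.

    The two split (or cluster) systems are padded to equal size with null
    entries; the weight between two entries is the smallest symmetric
    difference over orientations, and the weight of matching an entry
    ``A|B`` to a null entry is ``min(|A|, |B|)``.  The returned value is the
    total weight of the minimum-weight perfect matching.  It is zero exactly
    when the two systems are equal.
    """
    _check_leaf_sets(t1, t2)
    mode = _resolve_mode(mode, t1, t2)
    leaf_set = t1.leaf_set
    n = len(leaf_set)
    s1 = sorted(split_system(t1, mode), key=sorted)
    s2 = sorted(split_system(t2, mode), key=sorted)
    k = max(len(s1), len(s2))
    if k == 0:
        return 0
    cost = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            if i < len(s1) and j < len(s2):
                cost[i, j] = _pair_weight(s1[i], s2[j], leaf_set, mode)
            elif i < len(s1):
                cost[i, j] = min(len(s1[i]), n - len(s1[i]))
            elif j < len(s2):
                cost[i, j] = min(len(s2[j]), n - len(s2[j]))
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric per-gene matrix of pairwise tree distances.

    labels are rendered strategy identifiers; values is a square array with a
    zero diagonal.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix must be square over its labels")
        if v.size and (not np.allclose(v, v.T) or np.any(np.diag(v) != 0)):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "values", v)

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in distance matrix") from None

    def __getitem__(self, pair: tuple[str, str]):
        i, j = (self.index(l) for l in pair)
        return self.values[i, j]

    def zero_partners(self, label: str) -> tuple[str, ...]:
        """Labels at distance zero from *label*, excluding itself."""
        i = self.index(label)
        return tuple(l for j, l in enumerate(self.labels)
                     if j != i and self.values[i, j] == 0)

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in keep]
        return DistanceMatrix(tuple(keep), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "strategy"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy())


def distance_matrix(trees: Sequence[tuple[str, PhyloTree]],
                    metric: str = "matching", mode: str = "auto") -> DistanceMatrix:
    """Full pairwise distance matrix over labelled trees of one gene."""
    if len(trees) < 2:
        raise ValueError("need at least two trees for a distance matrix")
    if metric == "rf":
        fn = rf_distance
    elif metric == "matching":
        fn = matching_distance
    else:
        raise ValueError(f"unknown metric {metric!r}")
    labels = tuple(lab for lab, _ in trees)
    ref_lab, ref_tree = trees[0]
    for lab, t in trees[1:]:
        if t.leaf_set != ref_tree.leaf_set:
            raise LeafSetError(
                f"tree {lab!r} has a different leaf set from {ref_lab!r}")
    m = len(trees)
    vals = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            d = fn(trees[i][1], trees[j][1], mode=mode)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals)
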