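"""Rooted phylogenetic trees.

Two flavours are used throughout the package: plain gene trees whose branch
lengths are expected substitutions per codon site, and dated (ultrametric)
species trees whose branch lengths are millions of years.  Both are stored
in a flat preorder-indexed array representation that the pruning algorithms
consume directly; Newick reading is delegated to dendropy.
"""

from __future__ import annotations

import io
from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "DatedTree", "parse_newick", "write_newick"]


class PhyloTree:
    """A rooted tree with named leaves and non-negative branch lengths.

    Nodes are integer ids in preorder; node 0 is the root.  ``lengths[v]``
    is the length of the branch above ``v`` (NaN for the root).  Unnamed
    internal nodes receive deterministic preorder labels ``nd<k>`` so that
    branch partitions and reconciliations are serializable.
    """

    def __init__(
        self,
        parent: Sequence[int],
        names: Sequence[str],
        lengths: Sequence[float],
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.names = list(names)
        self.lengths = np.asarray(lengths, dtype=float)
        n = len(self.parent)
        if not (len(self.names) == len(self.lengths) == n):
            raise ValueError("parent/names/lengths must have equal length")
        if n == 0 or self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise ValueError("node 0 must be the unique root (preorder ids)")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(1, n):
            self.children[self.parent[v]].append(v)
        self.is_leaf = np.array([not self.children[v] for v in range(n)])
        self._validate()

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        if np.any(self.lengths[1:] < 0) or np.any(np.isnan(self.lengths[1:])):
            raise ValueError("branch lengths must be present and >= 0")
        leaf_names = self.leaf_names
        if any(not nm for nm in leaf_names):
            raise ValueError("leaf names must be non-empty")
        if len(set(leaf_names)) != len(leaf_names):
            raise ValueError("leaf names must be unique")
        if len(set(self.names)) != len(self.names):
            raise ValueError("node labels must be unique")

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return 0

    @property
    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.is_leaf)

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[v] for v in np.flatnonzero(self.is_leaf)]

    @property
    def name_to_id(self) -> dict[str, int]:
        return {nm: v for v, nm in enumerate(self.names)}

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def subtree(self, v: int) -> list[int]:
        """Preorder list of nodes in the clade rooted at ``v`` (inclusive)."""
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self.children[u])
        return out

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    def mrca(self, leaf_names: Sequence[str]) -> int:
        ids = [self.name_to_id[nm] for nm in leaf_names]
        anc = self._ancestor_sets()
        common = set.intersection(*(anc[v] for v in ids))
        # deepest common ancestor = the one with the most ancestors itself
        return max(common, key=lambda u: len(anc[u]))

    def _ancestor_sets(self) -> list[set[int]]:
        anc: list[set[int]] = [set() for _ in range(self.n_nodes)]
        anc[0] = {0}
        for v in range(1, self.n_nodes):
            anc[v] = anc[self.parent[v]] | {v}
        return anc

    def copy(self) -> "PhyloTree":
        return type(self)(self.parent.copy(), list(self.names), self.lengths.copy())

    def prune(self, keep: Sequence[str]):
        """Restrict the tree to a subset of leaves.

        Unary internal nodes created by the removal are suppressed (their
        branch lengths are summed), so path lengths between the kept leaves
        are preserved.  Returns the same tree type.
        """
        keep_set = set(keep)
        missing = keep_set - set(self.leaf_names)
        if missing:
            raise ValueError(f"cannot keep unknown leaves: {sorted(missing)}")
        if not keep_set:
            raise ValueError("at least one leaf must be kept")

        def rec(v: int):
            if self.is_leaf[v]:
                if self.names[v] not in keep_set:
                    return None
                return [self.names[v], float(self.lengths[v]), []]
            kids = [k for k in (rec(c) for c in self.children[v]) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:  # suppress unary node
                kids[0][1] += float(self.lengths[v])
                return kids[0]
            return [self.names[v], float(self.lengths[v]), kids]

        root_node = rec(self.root)
        parent, names, lengths = [], [], []

        def emit(node, parent_id):
            my_id = len(names)
            parent.append(parent_id)
            names.append(node[0])
            lengths.append(np.nan if parent_id == -1 else node[1])
            for child in node[2]:
                emit(child, my_id)

        emit(root_node, -1)
        if isinstance(self, DatedTree):
            calib = {
                nm: age for nm, age in getattr(self, "calibrations", {}).items() if nm in names
            }
            return DatedTree(parent, names, lengths, calib)
        return PhyloTree(parent, names, lengths)

    # -- serialization -----------------------------------------------------

    def write(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__} {len(self.leaf_names)} leaves>"


class DatedTree(PhyloTree):
    """Ultrametric species tree; branch lengths in millions of years."""

    #: relative tolerance on root-to-tip path equality
    ULTRAMETRIC_RTOL = 1e-6

    def __init__(self, parent, names, lengths, calibrations: Mapping[str, float] | None = None):
        super().__init__(parent, names, lengths)
        self.calibrations = dict(calibrations or {})
        d = self.depths()
        tip_d = d[self.is_leaf]
        self.root_age = float(tip_d.max())
        if self.root_age > 0 and (tip_d.max() - tip_d.min()) > self.ULTRAMETRIC_RTOL * self.root_age:
            raise ValueError(
                "tree is not ultrametric: root-to-tip depths range "
                f"[{tip_d.min():.6g}, {tip_d.max():.6g}]"
            )

    def node_ages(self) -> np.ndarray:
        """Age of each node in My before present (tips at ~0)."""
        return self.root_age - self.depths()

    def copy(self) -> "DatedTree":
        return DatedTree(self.parent.copy(), list(self.names), self.lengths.copy(), self.calibrations)


def _fmt(x: float) -> str:
    return np.format_float_positional(float(x), unique=True, trim="-")


def write_newick(tree: PhyloTree) -> str:
    def rec(v: int) -> str:
        if tree.is_leaf[v]:
            s = tree.names[v]
        else:
            s = "(" + ",".join(rec(c) for c in tree.children[v]) + ")" + tree.names[v]
        if v != tree.root:
            s += ":" + _fmt(tree.lengths[v])
        return s

    return rec(tree.root) + ";"


def parse_newick(
    text: str,
    dated: bool = False,
    calibrations: Mapping[str, float] | None = None,
) -> PhyloTree | DatedTree:
    """Parse a rooted Newick string.

    Branch lengths are required on every non-root branch; square-bracket
    comments are ignored.  Unnamed internal nodes are labelled ``nd<k>``
    by preorder index.  With ``dated=True`` the tree must be ultrametric
    (relative tolerance 1e-6) and a :class:`DatedTree` is returned.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick: {exc}") from exc

    root = dtree.seed_node
    # preorder ids
    nodes = list(dtree.preorder_node_iter())
    idx = {id(nd): k for k, nd in enumerate(nodes)}
    parent, names, lengths = [], [], []
    for k, nd in enumerate(nodes):
        parent.append(-1 if nd is root else idx[id(nd.parent_node)])
        if nd.is_leaf():
            nm = nd.taxon.label if nd.taxon is not None else (nd.label or "")
        else:
            nm = nd.label or f"nd{k}"
        names.append(nm)
        if nd is root:
            lengths.append(np.nan)
        else:
            if nd.edge.length is None:
                raise ValueError(f"missing branch length above node {nm!r}")
            lengths.append(float(nd.edge.length))
    if dated:
        return DatedTree(parent, names, lengths, calibrations)
    return PhyloTree(parent, names, lengths)
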