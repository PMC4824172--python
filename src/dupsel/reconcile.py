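"""Gene-tree / species-tree reconciliation and branch partitions.

Duplication nodes are found by the parsimony (Zmasek-Eddy) LCA mapping: a
gene-tree internal node is a duplication iff its species mapping equals the
mapping of at least one of its children.  Branch partitions assign every
branch of the gene tree to an omega class for the branch codon models:

* ``immediate``       - only the two branches directly produced by each
                        duplication get the focal class;
* ``all_descendants`` - every branch descending from a duplication node
                        (the event's child branches and everything below)
                        gets the focal class.

Event-focused partitions additionally distinguish the two lineages produced
by a single duplication (asymmetric, K=3) or pool them (symmetric, K=2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .trees import PhyloTree

__all__ = [
    "ReconciliationResult",
    "BranchPartition",
    "reconcile_lca",
    "partition_branches",
    "partition_event",
]


@dataclass
class ReconciliationResult:
    """LCA species mapping of each gene-tree node plus the duplication set."""

    gene_tree: PhyloTree
    species_tree: PhyloTree
    mapping: np.ndarray  # gene node id -> species node id
    duplications: set[int] = field(default_factory=set)

    @property
    def duplication_names(self) -> list[str]:
        return sorted(self.gene_tree.names[v] for v in self.duplications)

    def to_frame(self) -> pd.DataFrame:
        g, s = self.gene_tree, self.species_tree
        return pd.DataFrame(
            {
                "gene_node": [g.names[v] for v in range(g.n_nodes)],
                "species_node": [s.names[self.mapping[v]] for v in range(g.n_nodes)],
                "duplication": [v in self.duplications for v in range(g.n_nodes)],
            }
        )


class BranchPartition:
    """Assignment of every branch (identified by its child node) to a class.

    Class 0 is the background; classes 1..K-1 are the focal classes.  The
    root carries no branch and is kept at class 0.  ``labels`` optionally
    names each class for reporting (e.g. by the leaf set it spans), so
    asymmetric results do not depend on Newick child order.
    """

    def __init__(self, tree: PhyloTree, classes: np.ndarray, labels: list[str] | None = None):
        self.tree = tree
        self.classes = np.asarray(classes, dtype=int)
        if self.classes.shape != (tree.n_nodes,):
            raise ValueError("classes must assign every node")
        if self.classes[tree.root] != 0:
            raise ValueError("the root carries no branch; its class must be 0")
        k = int(self.classes.max()) + 1
        present = set(np.unique(self.classes[1:])) | {0}
        if present != set(range(k)):
            raise ValueError("class indices must be contiguous from 0")
        self.n_classes = k
        self.labels = labels or [f"class{i}" for i in range(k)]

    @classmethod
    def background(cls, tree: PhyloTree) -> "BranchPartition":
        return cls(tree, np.zeros(tree.n_nodes, dtype=int), ["background"])

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.classes[1:], minlength=self.n_classes)

    def merge_classes(self, mapping: Mapping[int, int]) -> "BranchPartition":
        """Relabel classes (e.g. ``{2: 1}`` pools class 2 into class 1)."""
        new = self.classes.copy()
        for old, tgt in mapping.items():
            new[new == old] = tgt
        # compact to contiguous indices preserving order
        uniq = sorted(set(new[1:]) | {0})
        remap = {c: i for i, c in enumerate(uniq)}
        new = np.array([remap[c] for c in new])
        return BranchPartition(self.tree, new)

    def to_frame(self) -> pd.DataFrame:
        t = self.tree
        rows = [(t.names[v], int(self.classes[v])) for v in range(t.n_nodes) if v != t.root]
        return pd.DataFrame(rows, columns=["branch", "class"])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BranchPartition)
            and self.tree is other.tree
            and np.array_equal(self.classes, other.classes)
        )


def _check_binary(tree: PhyloTree, what: str) -> None:
    if not tree.is_binary():
        raise ValueError(f"{what} contains polytomies; only binary trees are supported")


def reconcile_lca(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    leaf_map: Mapping[str, str],
) -> ReconciliationResult:
    """Map gene-tree nodes to species-tree nodes by LCA reconciliation."""
    _check_binary(gene_tree, "gene tree")
    sp_ids = species_tree.name_to_id
    sp_anc = species_tree._ancestor_sets()

    def lca(a: int, b: int) -> int:
        common = sp_anc[a] & sp_anc[b]
        return max(common, key=lambda u: len(sp_anc[u]))

    mapping = np.full(gene_tree.n_nodes, -1, dtype=int)
    for v in gene_tree.postorder():
        if gene_tree.is_leaf[v]:
            name = gene_tree.names[v]
            if name not in leaf_map:
                raise ValueError(f"gene-tree leaf {name!r} has no species mapping")
            sp = leaf_map[name]
            if sp not in sp_ids or not species_tree.is_leaf[sp_ids[sp]]:
                raise ValueError(f"{sp!r} is not a species-tree leaf")
            mapping[v] = sp_ids[sp]
        else:
            kids = gene_tree.children[v]
            m = mapping[kids[0]]
            for c in kids[1:]:
                m = lca(m, mapping[c])
            mapping[v] = m
    dups = {
        int(v)
        for v in range(gene_tree.n_nodes)
        if not gene_tree.is_leaf[v]
        and any(mapping[c] == mapping[v] for c in gene_tree.children[v])
    }
    return ReconciliationResult(gene_tree, species_tree, mapping, dups)


def _resolve_nodes(tree: PhyloTree, nodes: Iterable[int | str]) -> list[int]:
    ids = []
    name_map = tree.name_to_id
    for n in nodes:
        v = name_map[n] if isinstance(n, str) else int(n)
        if not 0 <= v < tree.n_nodes:
            raise ValueError(f"node {n!r} not in tree")
        ids.append(v)
    return ids


def partition_branches(
    gene_tree: PhyloTree,
    dup_nodes: Iterable[int | str],
    mode: str = "immediate",
) -> BranchPartition:
    """Two-class partition from a set of duplication nodes.

    ``immediate``: exactly the child branches of each duplication node are
    class 1.  ``all_descendants``: a branch is class 1 iff any duplication
    node lies on its path to the root (equivalently, the branch descends
    from a duplication event).  Class membership is binary: overlapping
    events are not double-counted.
    """
    _check_binary(gene_tree, "gene tree")
    if mode not in ("immediate", "all_descendants"):
        raise ValueError("mode must be 'immediate' or 'all_descendants'")
    dups = set(_resolve_nodes(gene_tree, dup_nodes))
    for v in dups:
        if gene_tree.is_leaf[v]:
            raise ValueError(f"duplication node {gene_tree.names[v]!r} is a leaf")
    classes = np.zeros(gene_tree.n_nodes, dtype=int)
    if mode == "immediate":
        for d in dups:
            for c in gene_tree.children[d]:
                classes[c] = 1
    else:
        for v in range(1, gene_tree.n_nodes):
            u = gene_tree.parent[v]
            while u != -1:
                if u in dups:
                    classes[v] = 1
                    break
                u = gene_tree.parent[u]
    labels = ["background", "post-duplication"] if classes.max() else ["background"]
    return BranchPartition(gene_tree, classes, labels)


def partition_event(
    gene_tree: PhyloTree,
    focal_dup: int | str,
    mode: str = "all_descendants",
    symmetric: bool = False,
) -> BranchPartition:
    """Partition for a single focal duplication event.

    Asymmetric (default): lineage 1 -> class 1, lineage 2 -> class 2, rest
    of the tree -> class 0.  Symmetric: the two lineages pooled as class 1.
    ``immediate`` lineages are the event's child branches only;
    ``all_descendants`` lineages are the whole child subtrees including
    their stem branches.
    """
    _check_binary(gene_tree, "gene tree")
    (v,) = _resolve_nodes(gene_tree, [focal_dup])
    if gene_tree.is_leaf[v]:
        raise ValueError("focal duplication must be an internal node")
    kids = gene_tree.children[v]
    classes = np.zeros(gene_tree.n_nodes, dtype=int)
    lineages = []
    for c in kids:
        lineages.append([c] if mode == "immediate" else gene_tree.subtree(c))
    if mode not in ("immediate", "all_descendants"):
        raise ValueError("mode must be 'immediate' or 'all_descendants'")
    labels = ["background"]
    for i, lin in enumerate(lineages):
        cls = 1 if symmetric else i + 1
        for u in lin:
            classes[u] = cls
    if symmetric:
        labels.append("post-duplication")
    else:
        for c in kids:
            tips = sorted(gene_tree.names[u] for u in gene_tree.subtree(c) if gene_tree.is_leaf[u])
            labels.append("lineage[" + ",".join(tips) + "]")
    return BranchPartition(gene_tree, classes, labels)
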