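"""Felsenstein pruning over codon alignments with per-node scaling.

Site patterns are compressed once per (alignment, tree) pair; all model
families then evaluate pattern log-likelihoods through the same engine.
Missing codons contribute a partial likelihood of one over all states.
"""

from __future__ import annotations

import numpy as np

from ..alignments import CodonAlignment
from ..trees import PhyloTree

__all__ = ["PruningEngine"]

_TINY = 1e-300


class PruningEngine:
    """Pruning likelihood evaluator bound to one alignment and tree."""

    def __init__(self, alignment: CodonAlignment, tree: PhyloTree):
        if alignment.n_sites == 0:
            raise ValueError("alignment has zero codon columns")
        name_to_row = {nm: i for i, nm in enumerate(alignment.names)}
        missing = [nm for nm in tree.leaf_names if nm not in name_to_row]
        if missing:
            raise ValueError(f"alignment lacks sequences for tree leaves: {missing}")
        self.tree = tree
        self.alignment = alignment
        rows = np.array([name_to_row[tree.names[v]] for v in tree.leaves])
        data = alignment.codes[rows]  # (n_leaves, n_sites) in tree-leaf order
        patterns, self.pattern_index, counts = np.unique(
            data.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (n_leaves, n_patterns)
        self.counts = counts.astype(float)
        self.leaf_row = {int(v): k for k, v in enumerate(tree.leaves)}
        self.n_patterns = self.patterns.shape[1]
        self.n_sites = alignment.n_sites
        self._post = tree.postorder()

    def pattern_logliks(self, pmats: dict[int, np.ndarray], pi: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihoods given per-branch transition matrices."""
        tree = self.tree
        npat = self.n_patterns
        if tree.n_nodes == 1:  # degenerate single-leaf tree: lnL = sum log pi
            codes = self.patterns[0]
            root_l = np.where(codes >= 0, pi[np.clip(codes, 0, None)], 1.0)
            return np.log(np.clip(root_l, _TINY, None))
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(npat)
        for v in self._post:
            if tree.is_leaf[v]:
                continue
            acc = np.ones((npat, 61))
            for c in tree.children[v]:
                p = pmats[c]
                if tree.is_leaf[c]:
                    codes = self.patterns[self.leaf_row[c]]
                    contrib = np.ones((npat, 61))
                    obs = codes >= 0
                    contrib[obs] = p[:, codes[obs]].T
                else:
                    contrib = partial.pop(c) @ p.T
                acc *= contrib
            scale = acc.max(axis=1)
            np.clip(scale, _TINY, None, out=scale)
            acc /= scale[:, None]
            logscale += np.log(scale)
            partial[v] = acc
        root_l = partial[tree.root] @ pi
        return np.log(np.clip(root_l, _TINY, None)) + logscale

    def loglik(self, pmats: dict[int, np.ndarray], pi: np.ndarray) -> float:
        return float(self.pattern_logliks(pmats, pi) @ self.counts)

    def site_values(self, pattern_values: np.ndarray) -> np.ndarray:
        """Expand per-pattern values back to per-site order."""
        return np.asarray(pattern_values)[..., self.pattern_index]
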