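"""Synthetic data generation: codon alignments, gene-count tables, fixtures.

Codon alignments are evolved site-by-site with exact per-branch transition
matrices (no Gillespie stepping), under any model family the engine fits:
a single omega, branch-class omegas on a partition, or the M8/M8a site
mixture (true site-class labels are returned for site models).  The fixture
factory builds the study trees used throughout the tests: a 16-taxon dated
species tree of depth 245 My with named calibration nodes (Brachycera 200,
Cyclorrhapha 150, Schizophora 70) and an 8-leaf gene tree carrying a single
duplication whose two child clades span four species each, with branch
lengths of 0.3 substitutions per codon site (informative but unsaturated).
"""

from __future__ import annotations

import numpy as np

from .alignments import CodonAlignment
from .codon.model import CodonModelSpec, branch_class_eigs, site_class_eigs
from .codon.rates import prob_matrix
from .reconcile import BranchPartition
from .trees import DatedTree, PhyloTree, parse_newick
from .turnover import TurnoverModel, simulate_family_counts

__all__ = ["simulate_codon_alignment", "simulate_family_counts", "make_fixtures"]


def _evolve(states: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(states)
    for s in np.unique(states):
        idx = states == s
        out[idx] = rng.choice(61, size=int(idx.sum()), p=P[s])
    return out


def simulate_codon_alignment(
    tree: PhyloTree,
    partition: BranchPartition | None,
    spec: CodonModelSpec,
    nsites: int,
    seed: int | np.random.Generator,
) -> tuple[CodonAlignment, np.ndarray | None]:
    """Simulate a codon alignment on ``tree`` under ``spec``.

    Returns the alignment and, for M8/M8A specs, the true per-site class
    labels (0..ncat-1 = beta classes, ncat = selected class); None for
    single-class and branch models.  Identical seeds give byte-identical
    output.  Branch lengths are interpreted exactly as in fitting: expected
    substitutions per codon site under the supplied model's normalization.
    """
    if nsites < 1:
        raise ValueError("nsites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.pi is not None:
        pi = np.asarray(spec.pi, dtype=float)
        pi = pi / pi.sum()
    elif spec.freq_model.upper() == "UNIFORM":
        pi = np.full(61, 1.0 / 61)
    else:
        raise ValueError(
            "simulation needs explicit pi or freq_model='UNIFORM' "
            "(empirical frequency models are estimated from data, not simulated from)"
        )

    site_labels = None
    if spec.family in ("M8", "M8A"):
        eigs, rho, _, weights = site_class_eigs(
            spec.kappa, spec.p0, spec.p, spec.q, spec.omega_s, pi, spec.ncat
        )
        site_labels = rng.choice(len(weights), size=nsites, p=weights)
        scales = np.full(len(eigs), rho)
        branch_class = None
    else:
        omegas = spec.omegas()
        if partition is None:
            partition = BranchPartition.background(tree)
        if len(omegas) != partition.n_classes:
            raise ValueError("spec omega vector must match partition class count")
        eigs, scales = branch_class_eigs(spec.kappa, omegas, pi)
        branch_class = partition.classes

    states = {tree.root: rng.choice(61, size=nsites, p=pi)}
    for v in range(1, tree.n_nodes):
        parent = states[tree.parent[v]]
        child = np.empty(nsites, dtype=parent.dtype)
        if branch_class is not None:
            k = int(branch_class[v])
            P = prob_matrix(eigs[k], float(tree.lengths[v]) / scales[k])
            child = _evolve(parent, P, rng)
        else:
            for k, eig in enumerate(eigs):
                idx = site_labels == k
                if not idx.any():
                    continue
                P = prob_matrix(eig, float(tree.lengths[v]) / scales[k])
                child[idx] = _evolve(parent[idx], P, rng)
        states[v] = child

    codes = np.stack([states[v] for v in tree.leaves]).astype(np.int16)
    aln = CodonAlignment([tree.names[v] for v in tree.leaves], codes)
    return aln, site_labels


# ---------------------------------------------------------------------------
# fixtures

# (name, age, children); leaves are plain names (age 0)
_SPECIES_TOPOLOGY = (
    "root",
    245.0,
    [
        (
            "nematocera",
            210.0,
            [
                (
                    "culicoidea",
                    120.0,
                    [
                        ("culicidae", 60.0, ["Anopheles", ("aedini", 40.0, ["Aedes", "Culex"])]),
                        "Corethrella",
                    ],
                ),
                (
                    "midges",
                    150.0,
                    [
                        ("chironomoidea", 100.0, ["Chironomus", "Belgica"]),
                        ("psychodidae", 70.0, ["Lutzomyia", "Phlebotomus"]),
                    ],
                ),
            ],
        ),
        (
            "Brachycera",
            200.0,
            [
                ("tabanomorpha", 130.0, ["Hermetia", "Tabanus"]),
                (
                    "Cyclorrhapha",
                    150.0,
                    [
                        ("aschiza", 110.0, ["Megaselia", "Episyrphus"]),
                        (
                            "Schizophora",
                            70.0,
                            [
                                ("hippoboscoidea", 40.0, ["Glossina", "Stomoxys"]),
                                ("muscoidea", 50.0, ["Musca", "Lucilia"]),
                            ],
                        ),
                    ],
                ),
            ],
        ),
    ],
)

CALIBRATIONS = {"root": 245.0, "Brachycera": 200.0, "Cyclorrhapha": 150.0, "Schizophora": 70.0}


def _to_newick(node, parent_age: float | None) -> str:
    if isinstance(node, str):
        name, age, children = node, 0.0, None
    else:
        name, age, children = node
    body = name
    if children is not None:
        body = "(" + ",".join(_to_newick(c, age) for c in children) + ")" + name
    if parent_age is None:
        return body
    return f"{body}:{parent_age - age:g}"


GENE_TREE_NEWICK = (
    "((SpA_1:0.3,(SpB_1:0.3,(SpC_1:0.3,SpD_1:0.3):0.3):0.3):0.3,"
    "(SpA_2:0.3,(SpB_2:0.3,(SpC_2:0.3,SpD_2:0.3):0.3):0.3):0.3);"
)
GENE_SPECIES_NEWICK = "(SpA:4,(SpB:3,(SpC:2,SpD:2):1):1);"


def make_fixtures() -> dict:
    """Deterministic study fixtures.

    Returns a dict with:

    * ``species_tree``      - 16-taxon :class:`DatedTree`, root age 245 My,
      internal calibrations Brachycera=200, Cyclorrhapha=150, Schizophora=70;
    * ``gene_tree``         - 8-leaf gene tree, all branch lengths 0.3,
      with one duplication at its root (two 4-leaf child clades);
    * ``gene_species_tree`` - the 4-species tree those genes map onto;
    * ``leaf_map``          - gene leaf -> species leaf;
    * ``duplication_node``  - label of the duplication node (the gene root);
    * ``focal_clade``       - label of the first post-duplication clade's MRCA.
    """
    species_newick = _to_newick(_SPECIES_TOPOLOGY, None) + ";"
    species_tree = parse_newick(species_newick, dated=True, calibrations=CALIBRATIONS)
    gene_tree = parse_newick(GENE_TREE_NEWICK)
    gene_species_tree = parse_newick(GENE_SPECIES_NEWICK)
    leaf_map = {nm: nm.split("_")[0] for nm in gene_tree.leaf_names}
    return {
        "species_tree": species_tree,
        "gene_tree": gene_tree,
        "gene_species_tree": gene_species_tree,
        "leaf_map": leaf_map,
        "duplication_node": gene_tree.names[gene_tree.root],
        "focal_clade": gene_tree.names[gene_tree.children[gene_tree.root][0]],
    }
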