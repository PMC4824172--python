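"""LCA reconciliation and duplication-aware branch partitions."""

import numpy as np
import pytest

from dupsel import parse_newick, partition_branches, partition_event, reconcile_lca


@pytest.fixture(scope="module")
def simple_species():
    return parse_newick("((a:1,b:1):1,c:2);")


def test_congruent_trees_have_no_duplications(simple_species):
    gene = parse_newick("((a1:1,b1:1):1,c1:2);")
    rec = reconcile_lca(gene, simple_species, {"a1": "a", "b1": "b", "c1": "c"})
    assert rec.duplications == set()


def test_single_duplication_at_root():
    species = parse_newick("(a:1,b:1);")
    gene = parse_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
    rec = reconcile_lca(gene, species, {n: n[0] for n in gene.leaf_names})
    assert rec.duplications == {gene.root}
    # brute-force check of the mapping: every internal node spans both species
    assert all(rec.mapping[v] == species.root for v in range(gene.n_nodes) if not gene.is_leaf[v])


def test_fixture_duplication_separates_the_two_subclades(fixtures):
    """The marked duplication sits on the branch ancestral to both clades."""
    rec = reconcile_lca(fixtures["gene_tree"], fixtures["gene_species_tree"], fixtures["leaf_map"])
    assert rec.duplication_names == [fixtures["duplication_node"]]


def test_species_identical_gene_tree_yields_zero_duplications(species_tree):
    relabeled = species_tree.write()
    gene = parse_newick(relabeled.replace("Brachycera", "").replace("Cyclorrhapha", "").replace("Schizophora", ""))
    rec = reconcile_lca(gene, species_tree, {nm: nm for nm in gene.leaf_names})
    assert rec.duplications == set()


def test_unmapped_leaf_rejected(simple_species):
    gene = parse_newick("(a1:1,b1:1);")
    with pytest.raises(ValueError, match="no species mapping"):
        reconcile_lca(gene, simple_species, {"a1": "a"})


def test_polytomies_rejected(simple_species):
    gene = parse_newick("(a1:1,b1:1,c1:1);")
    with pytest.raises(ValueError, match="polytom"):
        reconcile_lca(gene, simple_species, {"a1": "a", "b1": "b", "c1": "c"})


# -- partitions -------------------------------------------------------------


def test_immediate_marks_exactly_the_event_child_branches(gene_tree):
    part = partition_branches(gene_tree, [gene_tree.names[0]], mode="immediate")
    assert part.n_classes == 2
    assert part.class_sizes()[1] == 2
    fg = np.flatnonzero(part.classes == 1)
    assert set(fg) == set(gene_tree.children[gene_tree.root])


def test_all_descendants_closed_under_descent(gene_tree):
    focal = gene_tree.children[gene_tree.root][0]
    part = partition_branches(gene_tree, [focal], mode="all_descendants")
    fg = set(np.flatnonzero(part.classes == 1))
    # every branch strictly below the duplication node, and nothing else
    expected = set(gene_tree.subtree(focal)) - {focal}
    assert fg == expected
    for v in fg:
        assert all(u in fg for u in gene_tree.subtree(v) if u != v)


def test_all_descendants_branch_count_by_enumeration():
    # duplication with 4-leaf and 3-leaf child subtrees:
    # (2*4-2) + (2*3-2) internal-clade branches plus the two child branches = 12
    gene = parse_newick(
        "(out:1,(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,g:1):1)D:1);"
    )
    part = partition_branches(gene, ["D"], mode="all_descendants")
    assert part.class_sizes()[1] == 12


def test_empty_duplication_set_gives_all_background(gene_tree):
    part = partition_branches(gene_tree, [], mode="immediate")
    assert part.n_classes == 1
    assert (part.classes == 0).all()


def test_nested_duplications_not_double_counted():
    gene = parse_newick("(((a:1,b:1)D2:1,c:1)D1:1,d:1);")
    part = partition_branches(gene, ["D1", "D2"], mode="immediate")
    # D2's stem is both a child-of-D1 branch and a duplication node itself
    assert part.n_classes == 2
    assert part.class_sizes()[1] == 4  # {D2, c, a, b} branches, each once


def test_event_partition_asymmetric_and_merge_identity(gene_tree):
    root = gene_tree.names[gene_tree.root]
    asym = partition_event(gene_tree, root, "all_descendants", symmetric=False)
    sym = partition_event(gene_tree, root, "all_descendants", symmetric=True)
    assert asym.n_classes == 3 and sym.n_classes == 2
    merged = asym.merge_classes({2: 1})
    np.testing.assert_array_equal(merged.classes, sym.classes)
    # symmetric event partition == partition_branches restricted to the event
    both = partition_branches(gene_tree, [root], mode="all_descendants")
    np.testing.assert_array_equal(sym.classes, both.classes)
    # lineage labels name the leaf sets, independent of child order
    assert any("SpA_1" in lbl for lbl in asym.labels)


def test_event_partition_immediate_asymmetric_single_branches(gene_tree):
    part = partition_event(gene_tree, gene_tree.names[0], "immediate", symmetric=False)
    assert list(part.class_sizes()) == [12, 1, 1]


def test_event_partition_rejects_leaf(gene_tree):
    with pytest.raises(ValueError, match="internal"):
        partition_event(gene_tree, "SpA_1", "immediate")


def test_partition_serialization(gene_tree):
    part = partition_branches(gene_tree, [gene_tree.names[0]], mode="immediate")
    df = part.to_frame()
    assert len(df) == gene_tree.n_nodes - 1
    assert set(df["class"]) == {0, 1}
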