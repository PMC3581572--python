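import io
import itertools

import numpy as np
import pytest

from orthosim.evolver import GeneTree, GeneTreeNode
from orthosim.truth import (
    OrthologPairSet,
    PairClass,
    classify_pair,
    groups_to_pairs,
    labelled_tree_to_pairs,
    parse_nhx_gene_tree,
    read_groups,
    read_pairs_tsv,
    true_ortholog_pairs,
    write_nhx_gene_tree,
    write_pairs_tsv,
)


def leaf(species, gene):
    return GeneTreeNode(event="leaf", species=species, gene_id=gene, length=1.0)


def node(event, *children):
    n = GeneTreeNode(event=event, length=1.0)
    for c in children:
        n.add_child(c)
    return n


def random_labelled_tree(rng, n_species=4, max_leaves=10) -> GeneTree:
    """Random binary gene tree with random event labels and species."""
    counter = itertools.count(1)
    leaves = [
        leaf(f"S{rng.integers(1, n_species + 1)}", f"g{next(counter)}")
        for _ in range(int(rng.integers(2, max_leaves + 1)))
    ]
    while len(leaves) > 1:
        i, j = sorted(rng.choice(len(leaves), size=2, replace=False))
        b = leaves.pop(j)
        a = leaves.pop(i)
        ev = ["speciation", "duplication", "transfer"][int(rng.integers(0, 3))]
        leaves.append(node(ev, a, b))
    return GeneTree(leaves[0], "F0")


class TestPairSet:
    def test_unordered_semantics(self):
        s = OrthologPairSet([("A|1", "B|1")])
        assert ("B|1", "A|1") in s
        s.add("B|1", "A|1")
        assert len(s) == 1

    def test_same_species_pair_rejected(self):
        with pytest.raises(ValueError, match="one species"):
            OrthologPairSet([("A|1", "A|2")])

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            OrthologPairSet([("A|1", "A|1")])


class TestClassifyPair:
    @pytest.mark.parametrize(
        "event,expected",
        [
            ("speciation", PairClass.ORTHOLOG),
            ("duplication", PairClass.PARALOG),
            ("transfer", PairClass.XENOLOG),
        ],
    )
    def test_two_leaf_trees(self, event, expected):
        a, b = leaf("A", "1"), leaf("B", "1")
        tree = GeneTree(node(event, a, b), "F0")
        assert classify_pair(tree, a, b) is expected

    def test_separate_trees_error(self):
        a, b = leaf("A", "1"), leaf("B", "1")
        t1 = GeneTree(node("speciation", a, leaf("C", "1")), "F0")
        with pytest.raises(ValueError, match="share a tree"):
            classify_pair(t1, a, b)

    def test_partition_property(self):
        """Every cross-species leaf pair falls in exactly one class."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            tree = random_labelled_tree(rng)
            leaves = tree.leaves()
            for x, y in itertools.combinations(leaves, 2):
                if x.species == y.species:
                    continue
                assert classify_pair(tree, x, y) in (
                    PairClass.ORTHOLOG, PairClass.PARALOG, PairClass.XENOLOG
                )


class TestTruthExtraction:
    def test_duplication_root_splits_pairs(self):
        t = node(
            "duplication",
            node("speciation", leaf("A", "1"), leaf("B", "1")),
            node("speciation", leaf("A", "2"), leaf("B", "2")),
        )
        pairs = true_ortholog_pairs([GeneTree(t, "F0")])
        assert pairs == OrthologPairSet([("A|1", "B|1"), ("A|2", "B|2")])

    @pytest.mark.parametrize("seed", range(4))
    def test_cartesian_extraction_equals_lca_classification(self, seed):
        """Speciation-node Cartesian products and pairwise LCA labels are
        two routes to the same ortholog set."""
        rng = np.random.default_rng(seed)
        for _ in range(50):
            tree = random_labelled_tree(rng)
            by_extraction = true_ortholog_pairs([tree])
            by_lca = OrthologPairSet()
            for x, y in itertools.combinations(tree.leaves(), 2):
                if x.species == y.species:
                    continue
                if classify_pair(tree, x, y) is PairClass.ORTHOLOG:
                    by_lca.add(f"{x.species}|{x.gene_id}", f"{y.species}|{y.gene_id}")
            assert by_extraction == by_lca

    def test_invariant_under_leaf_order(self):
        a1, b1, c1 = leaf("A", "1"), leaf("B", "1"), leaf("C", "1")
        t1 = node("speciation", node("speciation", a1, b1), c1)
        a2, b2, c2 = leaf("A", "1"), leaf("B", "1"), leaf("C", "1")
        t2 = node("speciation", c2, node("speciation", b2, a2))
        assert true_ortholog_pairs([GeneTree(t1, "F0")]) == true_ortholog_pairs(
            [GeneTree(t2, "F0")]
        )

    def test_unlabelled_node_is_error(self):
        t = node("unknown", leaf("A", "1"), leaf("B", "1"))
        with pytest.raises(ValueError, match="unlabelled"):
            true_ortholog_pairs([GeneTree(t, "F0")])

    def test_xenolog_pairs_cross_a_transfer_node(self):
        """With transfers present, every non-ortholog, non-paralog pair has
        its two genes on opposite sides of some transfer node."""
        t = node(
            "speciation",
            node("transfer", leaf("A", "1"), leaf("B", "1")),
            leaf("C", "1"),
        )
        tree = GeneTree(t, "F0")
        leaves = {l.gene_id + l.species: l for l in tree.leaves()}
        a, b = leaves["1A"], leaves["1B"]
        assert classify_pair(tree, a, b) is PairClass.XENOLOG
        truth = true_ortholog_pairs([tree])
        assert ("A|1", "B|1") not in truth
        assert ("A|1", "C|1") in truth and ("B|1", "C|1") in truth


class TestGroupsToPairs:
    def test_documented_example(self):
        pairs = groups_to_pairs([["A|1", "B|1", "B|2"]])
        assert pairs == OrthologPairSet([("A|1", "B|1"), ("A|1", "B|2")])

    def test_singleton_and_single_species_groups_empty(self):
        assert len(groups_to_pairs([["A|1"]])) == 0
        assert len(groups_to_pairs([["A|1", "A|2", "A|3"]])) == 0

    def test_malformed_id_rejected(self):
        with pytest.raises(ValueError, match="species tag"):
            groups_to_pairs([["A|1", "gene2"]])

    def test_agreement_with_labelled_tree_for_clean_orthogroup(self):
        t = node(
            "speciation",
            node("speciation", leaf("A", "1"), leaf("B", "1")),
            leaf("C", "1"),
        )
        from_tree = labelled_tree_to_pairs(GeneTree(t, "F0"))
        from_group = groups_to_pairs([["A|1", "B|1", "C|1"]])
        assert from_tree == from_group


class TestReadersWriters:
    def test_pairs_tsv_round_trip(self):
        pairs = OrthologPairSet([("A|x", "B|y"), ("A|x", "C|z")])
        buf = io.StringIO()
        write_pairs_tsv(pairs, buf)
        buf.seek(0)
        assert read_pairs_tsv(buf) == pairs

    def test_read_groups_orthomcl_layout(self):
        text = "OG1: A|1 B|1 B|2\nOG2: C|5\n"
        groups = read_groups(io.StringIO(text))
        assert groups == [["A|1", "B|1", "B|2"], ["C|5"]]

    def test_read_groups_plain_layout(self):
        groups = read_groups(io.StringIO("A|1 B|1\nA|2 C|2\n"))
        assert groups == [["A|1", "B|1"], ["A|2", "C|2"]]

    def test_nhx_round_trip(self):
        t = node(
            "speciation",
            node("duplication", leaf("A", "g1"), leaf("A", "g2")),
            node("transfer", leaf("B", "g1"), leaf("C", "g1")),
        )
        tree = GeneTree(t, "F0")
        text = write_nhx_gene_tree(tree)
        again = parse_nhx_gene_tree(text, "F0")
        assert labelled_tree_to_pairs(again) == labelled_tree_to_pairs(tree)
        events = sorted(n.event for n in again.internal_nodes())
        assert events == ["duplication", "speciation", "transfer"]

    def test_nhx_missing_annotation_rejected(self):
        with pytest.raises(ValueError, match="annotation"):
            parse_nhx_gene_tree("((A|1:1,B|1:1):1,C|1:2):0;")

    def test_nhx_d_dialect(self):
        text = "((A|1:1,B|1:1):1[&&NHX:D=N],(A|2:1,B|2:1):1[&&NHX:D=Y]):0[&&NHX:D=N];"
        tree = parse_nhx_gene_tree(text)
        pairs = labelled_tree_to_pairs(tree)
        assert ("A|1", "B|1") in pairs
        assert ("A|2", "B|2") not in pairs  # duplication node
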