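"""p-distances, neighbor joining, majority-rule consensus, supertrees."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.calculate import treecompare

from pangtm.phylogeny import (
    build_supertree,
    majority_consensus,
    neighbor_joining,
    p_distance_matrix,
    root_with_outgroup,
)


def rf_distance(newick_a: str, newick_b: str) -> int:
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True)


class TestPDistance:
    def test_identical_sequences(self):
        d = p_distance_matrix({"a": "MKVL", "b": "MKVL", "c": "MKVL"})
        assert (d.to_numpy() == 0).all()

    def test_half_different(self):
        d = p_distance_matrix({"a": "AAAA", "b": "AATT", "c": "AAAA"})
        assert d.at["a", "b"] == pytest.approx(0.5)

    def test_fully_different(self):
        d = p_distance_matrix({"a": "AAAA", "b": "TTTT", "c": "CCCC"})
        assert d.at["a", "b"] == pytest.approx(1.0)

    def test_ambiguity_sites_ignored(self):
        d = p_distance_matrix({"a": "AXAA", "b": "ATTA", "c": "AAAA"})
        # site 2 is masked for the (a, b) pair: 1 diff over 3 compared sites
        assert d.at["a", "b"] == pytest.approx(1 / 3)

    def test_unequal_lengths_name_taxa(self):
        with pytest.raises(ValueError, match="length"):
            p_distance_matrix({"a": "AAA", "b": "AAAA", "c": "AAA"})

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        seqs = {
            f"t{i}": "".join(rng.choice(list("ACDEFGHIKL"), size=30))
            for i in range(5)
        }
        d = p_distance_matrix(seqs)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]],
            index=list("abc"), columns=list("abc"),
        )
        tree = neighbor_joining(d)
        dm = {}
        pdm = tree.phylogenetic_distance_matrix()
        for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
            dm[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
        assert dm[frozenset(("a", "b"))] == pytest.approx(0.3)
        assert dm[frozenset(("a", "c"))] == pytest.approx(0.5)
        assert dm[frozenset(("b", "c"))] == pytest.approx(0.6)

    def test_additive_distances_recover_tree(self):
        # distances generated from ((a:1,b:2):1,(c:3,d:1):1) are additive
        d = pd.DataFrame(
            [
                [0, 3, 6, 4],
                [3, 0, 7, 5],
                [6, 7, 0, 4],
                [4, 5, 4, 0],
            ],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        tree = neighbor_joining(d)
        # four-point condition check: NJ path metric reproduces the input
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for x, y in itertools.combinations("abcd", 2):
            assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(d.at[x, y])
        assert rf_distance(to_newick(tree), "((a,b),(c,d));") == 0

    def test_closest_pair_joined_first(self):
        d = pd.DataFrame(
            [
                [0.0, 0.2, 0.9, 0.9],
                [0.2, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.4],
                [0.9, 0.9, 0.4, 0.0],
            ],
            index=list("abcd"), columns=list("abcd"),
        )
        tree = neighbor_joining(d)
        assert rf_distance(to_newick(tree), "((a,b),(c,d));") == 0

    def test_matches_scikit_bio_on_random_matrices(self):
        """Topology agrees with an independent NJ implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj

        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            # additive-ish random distances: random positive branch tree metric
            base = rng.uniform(0.1, 1.0, size=(n, n))
            d = (base + base.T) / 2
            np.fill_diagonal(d, 0.0)
            ours = neighbor_joining(pd.DataFrame(d, index=labels, columns=labels))
            theirs = nj(DistanceMatrix(d, ids=labels))
            assert rf_distance(to_newick(ours), str(theirs)) == 0

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(3)
        n = 7
        labels = [f"t{i}" for i in range(n)]
        base = rng.uniform(0.05, 1.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(pd.DataFrame(d, index=labels, columns=labels))
        assert all(
            (e.length or 0.0) >= 0.0 for e in tree.preorder_edge_iter()
        )


def _trees(newicks):
    return [
        dendropy.Tree.get(data=nwk, schema="newick") for nwk in newicks
    ]


class TestMajorityConsensus:
    def test_identical_trees_full_support(self):
        trees = _trees(["((a,b),(c,d),e);"] * 3)
        cons = majority_consensus(trees)
        assert rf_distance(to_newick(cons), "((a,b),(c,d),e);") == 0
        supports = [
            float(n.label) for n in cons.preorder_node_iter()
            if n.label and not n.is_leaf()
        ]
        assert supports and all(s == pytest.approx(100.0) for s in supports)

    def test_two_of_three_retained_with_support(self):
        trees = _trees(["((a,b),c,d);", "((a,b),c,d);", "(a,(b,c),d);"])
        cons = majority_consensus(trees)
        assert rf_distance(to_newick(cons), "((a,b),c,d);") == 0
        supports = [
            float(n.label) for n in cons.preorder_node_iter()
            if n.label and not n.is_leaf()
        ]
        assert supports == [pytest.approx(200 / 3)]

    def test_conflicting_clade_at_half_dropped(self):
        trees = _trees(["((a,b),(c,d),e);", "((a,c),(b,d),e);"])
        cons = majority_consensus(trees)  # every non-trivial split at 50%
        internal = [
            n for n in cons.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert internal == []  # star tree: strict > 0.5 rule

    def test_differing_leaf_sets_rejected(self):
        trees = _trees(["((a,b),c,d);", "((a,b),c,e);"])
        with pytest.raises(ValueError, match="symmetric difference"):
            majority_consensus(trees)

    def test_supports_are_multiples_of_tree_fraction(self):
        rng = np.random.default_rng(11)
        taxa = [f"t{i}" for i in range(6)]
        newicks = []
        for _ in range(10):
            order = list(rng.permutation(taxa))
            newicks.append(
                f"(({order[0]},{order[1]}),(({order[2]},{order[3]}),"
                f"{order[4]}),{order[5]});"
            )
        cons = majority_consensus(_trees(newicks))
        for node in cons.preorder_node_iter():
            if node.label and not node.is_leaf():
                assert float(node.label) % 10.0 == pytest.approx(0.0)

    def test_matches_dendropy_consensus(self):
        """Consensus topology equals dendropy's majority-rule consensus."""
        rng = np.random.default_rng(23)
        taxa = [f"t{i}" for i in range(6)]
        newicks = []
        for _ in range(10):
            order = list(rng.permutation(taxa))
            newicks.append(
                f"((({order[0]},{order[1]}),{order[2]}),"
                f"(({order[3]},{order[4]}),{order[5]}));"
            )
        cons = majority_consensus(_trees(newicks))
        tns = dendropy.TaxonNamespace()
        tree_list = dendropy.TreeList.get(
            data="\n".join(newicks), schema="newick", taxon_namespace=tns
        )
        ref = tree_list.consensus(min_freq=0.5)
        assert rf_distance(to_newick(cons), ref.as_string(schema="newick")) == 0


class TestRooting:
    def test_leafset_unchanged(self):
        tree = _trees(["((a,b),(c,o),d);"])[0]
        rooted = root_with_outgroup(tree, "o")
        leaves = {lf.taxon.label for lf in rooted.leaf_node_iter()}
        assert leaves == {"a", "b", "c", "d", "o"}

    def test_outgroup_is_child_of_root(self):
        tree = _trees(["((a,b),c,o);"])[0]
        rooted = root_with_outgroup(tree, "o")
        root_children = rooted.seed_node.child_nodes()
        labels = {c.taxon.label for c in root_children if c.is_leaf()}
        assert "o" in labels

    def test_ingroup_forms_clade(self):
        tree = _trees(["((a,b),c,o);"])[0]
        rooted = root_with_outgroup(tree, "o")
        for child in rooted.seed_node.child_nodes():
            if child.is_leaf():
                continue
            ingroup = {lf.taxon.label for lf in child.leaf_iter()}
            assert ingroup == {"a", "b", "c"}

    def test_idempotent_topology(self):
        tree = _trees(["((a,b),(c,d),o);"])[0]
        once = root_with_outgroup(tree, "o")
        twice = root_with_outgroup(once, "o")
        assert rf_distance(to_newick(once), to_newick(twice)) == 0

    def test_missing_outgroup_rejected(self):
        tree = _trees(["((a,b),c,d);"])[0]
        with pytest.raises(ValueError, match="outgroup"):
            root_with_outgroup(tree, "zz")


class TestSupertree:
    def test_single_family_consensus_is_that_tree(self):
        aln = {
            "fam1": {
                "a": "AAAAAAAAAA",
                "b": "AAAAAAAAAT",
                "c": "TTTTTAAAAA",
                "o": "TTTTTTTTTA",
            }
        }
        tree, fam_trees, _ = build_supertree(aln, outgroup="o")
        assert len(fam_trees) == 1
        supports = [
            float(n.label) for n in tree.preorder_node_iter()
            if n.label and not n.is_leaf()
        ]
        assert all(s == pytest.approx(100.0) for s in supports)

    def test_family_missing_outgroup_skipped(self):
        aln = {
            "fam1": {"a": "AAAA", "b": "AAAT", "c": "TTTT", "o": "TTTA"},
            "fam2": {"a": "AAAA", "b": "AAAT", "c": "TTTT"},
        }
        with pytest.warns(UserWarning, match="fam2"):
            _, fam_trees, _ = build_supertree(aln, outgroup="o")
        assert len(fam_trees) == 1

    def test_all_families_missing_outgroup_is_error(self):
        aln = {"fam1": {"a": "AAAA", "b": "AAAT", "c": "TTTT"}}
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no usable families"):
                build_supertree(aln, outgroup="o")

    def test_species_tree_recovery(self, small_sim):
        """Consensus over simulated core families equals the true tree."""
        cfg, genomes, _, truth = small_sim
        taxa = list(cfg.taxa)
        core = sorted(
            f for f in truth.family_membership if f.startswith("C")
        )[:25]
        alignments = {
            f: {t: genomes[t][f"{t}|{f}|0"] for t in taxa} for f in core
        }
        tree, _, _ = build_supertree(alignments, outgroup=cfg.outgroup)
        assert rf_distance(to_newick(tree), truth.species_tree) == 0
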