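"""Admission rules, tree pruning, foreground marking, gene trees."""

import itertools

import numpy as np
import pytest

from conftest import random_tree
from omegascan.filtering import (
    FilterPolicy,
    admit,
    build_gene_tree,
    check_monophyly,
    mark_foreground,
    prune_to_alignment,
    select_complete_orthologs,
)
from omegascan.io import BranchLabelMap, CodonAlignment
from omegascan.trees import Phylogeny, TreeError


def aln_with_taxa(taxa, gene_id="g"):
    return CodonAlignment(gene_id, tuple(taxa), [["ATG"] for _ in taxa])


LABELS = BranchLabelMap({"A": 1, "B": 1, "C": 1, "D": 1, "E": 0, "F": 0, "G": 0})


class TestAdmit:
    def test_thresholds_met(self):
        aln = aln_with_taxa("ABCDEFG")
        assert admit(aln, LABELS, 1, FilterPolicy(4, 3)) is None

    def test_default_policy_admits_everything(self):
        aln = aln_with_taxa("AE")
        assert admit(aln, LABELS, 1, FilterPolicy()) is None

    def test_below_background(self):
        aln = aln_with_taxa("ABCDEF")
        flag = admit(aln, LABELS, 1, FilterPolicy(4, 3))
        assert flag is not None and flag.reason == "below_min_background"

    def test_below_foreground(self):
        aln = aln_with_taxa("ABEFG")
        flag = admit(aln, LABELS, 1, FilterPolicy(4, 3))
        assert flag is not None and flag.reason == "below_min_foreground"


class TestPruning:
    def test_drop_one_leaf(self):
        tree = Phylogeny.from_newick("((A,B),(C,D));")
        pruned = prune_to_alignment(tree, {"A", "B", "C"})
        assert pruned.taxa == {"A", "B", "C"}
        assert pruned.bipartitions() == set()  # ((A,B),C): no nontrivial split
        assert pruned.is_monophyletic({"A", "B"})

    def test_identity_restriction(self):
        tree = Phylogeny.from_newick("((A,B),((C,D),E));")
        pruned = prune_to_alignment(tree, tree.taxa)
        assert pruned.bipartitions() == tree.bipartitions()

    def test_lengths_summed_through_suppressed_node(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        pruned = prune_to_alignment(tree, {"A", "C"})
        assert pruned.path_length("A", "C") == pytest.approx(4.0, abs=1e-12)
        a = [lf for lf in pruned.leaves() if lf.label == "A"][0]
        assert a.length == pytest.approx(2.0, abs=1e-12)

    def test_errors(self):
        tree = Phylogeny.from_newick("((A,B),(C,D));")
        with pytest.raises(TreeError):
            prune_to_alignment(tree, {"A", "X"})
        with pytest.raises(TreeError):
            prune_to_alignment(tree, {"A"})

    def test_random_restriction_matches_brute_force(self):
        """Pruned bipartitions equal brute-force restrictions; paths kept."""
        rng = np.random.default_rng(42)
        labels = list("ABCDEFGH")
        for _ in range(10):
            tree = random_tree(rng, labels)
            full_bips = tree.bipartitions()
            for size in (2, 4, 6):
                subset = set(rng.choice(labels, size=size, replace=False))
                pruned = tree.pruned_to(subset)
                # oracle: restrict every original bipartition to the subset
                anchor = min(subset)
                expected = set()
                for side in full_bips:
                    s = frozenset(side & subset)
                    if 1 < len(s) < len(subset) - 1:
                        expected.add(s if anchor in s else frozenset(subset - s))
                assert pruned.bipartitions() == expected
                for a, b in itertools.combinations(sorted(subset), 2):
                    assert pruned.path_length(a, b) == pytest.approx(
                        tree.path_length(a, b), abs=1e-9
                    )
                # idempotence
                again = pruned.pruned_to(subset)
                assert again.bipartitions() == pruned.bipartitions()


class TestMarkForeground:
    def test_clade_scope_marks_stem_and_members(self):
        tree = Phylogeny.from_newick("((A,B),(C,D));")
        labels = BranchLabelMap({"A": 1, "B": 1})
        marked, mono = mark_foreground(tree, labels, 1)
        assert mono
        mrca = marked.mrca({"A", "B"})
        assert mrca.mark == 1
        assert all(c.mark == 1 for c in mrca.children)
        others = [lf for lf in marked.leaves() if lf.label in ("C", "D")]
        assert all(lf.mark == 0 for lf in others)

    def test_stem_scope_marks_only_stem(self):
        tree = Phylogeny.from_newick("((A,B),(C,D));")
        labels = BranchLabelMap({"A": 1, "B": 1})
        marked, _ = mark_foreground(tree, labels, 1, scope="stem")
        mrca = marked.mrca({"A", "B"})
        assert mrca.mark == 1
        assert all(c.mark == 0 for c in mrca.children)

    def test_non_monophyletic_foreground(self):
        tree = Phylogeny.from_newick("((A,C),(B,D));")
        labels = BranchLabelMap({"A": 1, "B": 1})
        marked, mono = mark_foreground(tree, labels, 1)
        assert not mono and marked is None

    def test_single_leaf_foreground(self):
        tree = Phylogeny.from_newick("((A,B),(C,D));")
        labels = BranchLabelMap({"A": 1})
        marked, mono = mark_foreground(tree, labels, 1)
        assert mono
        leaf = [lf for lf in marked.leaves() if lf.label == "A"][0]
        assert leaf.mark == 1

    def test_missing_foreground_raises(self):
        tree = Phylogeny.from_newick("((A,B),(C,D));")
        labels = BranchLabelMap({"X": 1})
        with pytest.raises(TreeError):
            mark_foreground(tree, labels, 1)

    def test_verdict_matches_unrooted_monophyly(self):
        rng = np.random.default_rng(7)
        labels_all = list("ABCDEFGH")
        for _ in range(20):
            tree = random_tree(rng, labels_all)
            fg = set(rng.choice(labels_all, size=3, replace=False))
            lmap = BranchLabelMap({t: (1 if t in fg else 0) for t in labels_all})
            _, mono = mark_foreground(tree, lmap, 1)
            assert mono == check_monophyly(tree, fg)


class TestCompleteOrthologs:
    def test_exact_equality(self):
        alns = [
            aln_with_taxa("ABC", "g1"),
            aln_with_taxa("AB", "g2"),
            aln_with_taxa("ABC", "g3"),
            aln_with_taxa("ABCD", "g4"),
        ]
        assert select_complete_orthologs(alns, {"A", "B", "C"}) == ["g1", "g3"]

    def test_empty_collection(self):
        assert select_complete_orthologs([], {"A"}) == []


class TestGeneTree:
    def test_shared_substitutions_pair_ab_cd(self):
        # A,B share 10 private substitutions vs C,D and vice versa
        base = ["ATG"] * 30
        ab = list(base)
        cd = list(base)
        for i in range(10):
            ab[i] = "GTA"
            cd[i + 10] = "CTC"
        aln = CodonAlignment("g", ("A", "B", "C", "D"), [ab, list(ab), cd, list(cd)])
        tree = build_gene_tree(aln)
        assert tree.is_monophyletic({"A", "B"})
        assert tree.is_monophyletic({"C", "D"})
        assert not tree.is_monophyletic({"A", "C"})

    def test_identical_sequences_zero_lengths(self):
        aln = aln_with_taxa("ABCD")
        tree = build_gene_tree(aln)
        assert tree.taxa == {"A", "B", "C", "D"}
        assert all((n.length or 0.0) == 0.0 for n in tree.postorder())

    def test_three_taxa(self):
        aln = CodonAlignment(
            "g", ("A", "B", "C"), [["ATG", "AAA"], ["ATG", "AAG"], ["ATG", "CCC"]]
        )
        tree = build_gene_tree(aln)
        assert tree.taxa == {"A", "B", "C"}

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            build_gene_tree(aln_with_taxa("AB"))


class TestCheckMonophyly:
    def test_clade_side_of_split(self):
        tree = Phylogeny.from_newick("((A,B),(C,D));")
        assert check_monophyly(tree, {"A", "B"})
        assert not check_monophyly(tree, {"A", "C"})

    def test_entire_leaf_set(self):
        tree = Phylogeny.from_newick("((A,B),(C,D));")
        assert check_monophyly(tree, {"A", "B", "C", "D"})
        assert check_monophyly(tree, {"A"})
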