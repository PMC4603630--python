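"""Species-tree and reconciled gene-tree I/O, validation, reconciliation."""

import numpy as np
import pytest

from adjevo import trees as T


class TestSpeciesTree:
    def test_minimal_tree(self):
        sp = T.parse_species_tree("(A:1.0,B:1.0)R;")
        assert len(list(sp.postorder())) == 3
        assert sp.root.name == "R"
        assert {n.name for n in sp.leaves} == {"A", "B"}

    def test_twelve_leaves_give_eleven_ancestors(self, rng):
        # random rooted binary tree with 12 leaves
        from adjevo.simulate import random_species_tree
        sp = random_species_tree(12, rng)
        assert len(sp.leaves) == 12
        assert len(sp.internal_nodes) == 11

    def test_non_binary_rejected(self):
        with pytest.raises(T.TreeStructureError):
            T.parse_species_tree("(A,B,C)R;")

    def test_duplicate_names_rejected(self):
        with pytest.raises(T.TreeStructureError):
            T.parse_species_tree("(A:1,A:1)R;")

    def test_negative_length_rejected(self):
        with pytest.raises(T.TreeStructureError):
            T.parse_species_tree("(A:-1,B:1)R;")

    def test_auto_naming_postorder(self):
        sp = T.parse_species_tree("((A:1,B:1):1,(C:1,D:1):1)R;")
        assert [n.name for n in sp.internal_nodes] == ["ANC1", "ANC2", "R"]

    def test_roundtrip_exact(self, rng):
        from adjevo.simulate import random_species_tree
        for _ in range(5):
            sp = random_species_tree(int(rng.integers(3, 15)), rng)
            text = sp.to_newick()
            again = T.parse_species_tree(text)
            assert again.to_newick() == text
            for a, b in zip(sp.postorder(), again.postorder()):
                assert a.name == b.name
                if a.length is not None:
                    assert abs(a.length - b.length) < 1e-12


class TestReconciledGeneTree:
    def test_parse_speciation_cherry(self, species4):
        nhx = ("(gA__A[&&NHX:S=A:D=N],gB__B[&&NHX:S=B:D=N])"
               "[&&NHX:S=X:D=N];")
        gt = T.parse_reconciled_gene_tree(nhx, species4)
        assert gt.root.event == T.SPECIATION
        assert gt.root.species.name == "X"

    def test_parse_duplication_same_species_children(self, species4):
        nhx = ("(gA__A[&&NHX:S=A:D=N],hA__A[&&NHX:S=A:D=N])"
               "[&&NHX:S=A:D=Y];")
        gt = T.parse_reconciled_gene_tree(nhx, species4)
        assert gt.root.event == T.DUPLICATION

    def test_event_inferred_without_d_tag(self, species4):
        nhx = "(gA__A[&&NHX:S=A],hA__A[&&NHX:S=A])[&&NHX:S=A];"
        gt = T.parse_reconciled_gene_tree(nhx, species4)
        assert gt.root.event == T.DUPLICATION

    def test_unknown_species_rejected(self, species4):
        nhx = "(gA__A[&&NHX:S=A:D=N],gZ[&&NHX:S=Z:D=N])[&&NHX:S=X:D=N];"
        with pytest.raises(T.ReconciliationError):
            T.parse_reconciled_gene_tree(nhx, species4)

    def test_child_species_outside_parent_rejected(self, species4):
        # parent in X=(A,B) but child in D
        nhx = "(gA__A[&&NHX:S=A:D=N],gD__D[&&NHX:S=D:D=N])[&&NHX:S=X:D=N];"
        with pytest.raises(T.ReconciliationError):
            T.parse_reconciled_gene_tree(nhx, species4)

    def test_nhx_roundtrip(self, species4, rng):
        from adjevo.simulate import simulate_reconciled_family
        for _ in range(5):
            gt, _ = simulate_reconciled_family(species4, 0.3, 0.3, rng)
            text = gt.to_nhx()
            again = T.parse_reconciled_gene_tree(text, species4)
            assert again.to_nhx() == text
            for a, b in zip(gt.postorder(), again.postorder()):
                assert (a.event, a.species.name) == (b.event, b.species.name)


class TestLcaReconcile:
    def test_root_duplication(self, species4):
        gt = T.lca_reconcile("((gA__A,gB__B),(hA__A,hB__B));", species4)
        assert gt.root.event == T.DUPLICATION
        assert gt.root.species.name == "X"

    def test_cherry_speciation(self, species4):
        gt = T.lca_reconcile("(gA__A,gB__B);", species4)
        assert gt.root.event == T.SPECIATION

    def test_congruent_tree_no_events(self, species4):
        gt = T.lca_reconcile("(((a__A,b__B),c__C),d__D);", species4)
        events = [n.event for n in gt.postorder()]
        assert T.DUPLICATION not in events
        assert T.LOSS_LEAF not in events

    def test_leaf_species_mapping(self, species4):
        gt = T.lca_reconcile("(x,y);", species4,
                             leaf_species={"x": "A", "y": "B"})
        assert gt.root.species.name == "X"
        with pytest.raises(T.ReconciliationError):
            T.lca_reconcile("(x,y);", species4)


class TestInsertLossLeaves:
    def test_path_completion(self, species4):
        # edge from the root straight to a leaf in A traverses Y and X:
        # speciations must appear at Y (loss in C) and X (loss in B)
        nhx = "(a__A[&&NHX:S=A:D=N],d__D[&&NHX:S=D:D=N])[&&NHX:S=R:D=N];"
        gt = T.parse_reconciled_gene_tree(nhx, species4)
        full = T.insert_loss_leaves(gt)
        losses = [n.species.name for n in full.postorder()
                  if n.event == T.LOSS_LEAF]
        assert sorted(losses) == ["B", "C"]
        full.validate(strict=True)

    def test_idempotent(self, species4, rng):
        from adjevo.simulate import simulate_reconciled_family
        for _ in range(5):
            gt, _ = simulate_reconciled_family(species4, 0.2, 0.4, rng)
            once = T.insert_loss_leaves(gt)
            twice = T.insert_loss_leaves(once)
            assert twice.to_nhx() == once.to_nhx()

    def test_whole_clade_loss_single_leaf(self, species4):
        # gene present in C and D only: one loss leaf at the X stem, not
        # one per species below X
        gt = T.lca_reconcile("(c__C,d__D);", species4)
        losses = [n for n in gt.postorder() if n.event == T.LOSS_LEAF]
        assert len(losses) == 1
        assert losses[0].species.name == "X"


class TestSingleDupConstraint:
    def test_duplication_free_ok(self, species4):
        gt = T.lca_reconcile("(((a__A,b__B),c__C),d__D);", species4)
        ok, off = T.check_single_dup_constraint(gt)
        assert ok and not off

    def test_two_dups_same_branch_flagged(self, species4):
        nhx = ("((a__A[&&NHX:S=A:D=N],b__A[&&NHX:S=A:D=N])[&&NHX:S=A:D=Y],"
               "c__A[&&NHX:S=A:D=N])[&&NHX:S=A:D=Y];")
        gt = T.parse_reconciled_gene_tree(nhx, species4)
        ok, off = T.check_single_dup_constraint(gt)
        assert not ok and len(off) == 1

    def test_dups_separated_by_speciation_ok(self, species4):
        gt = T.lca_reconcile(
            "(((a__A,b__A),(c__B,d__B)),((e__A,f__A),(g__B,h__B)));",
            species4)
        # root duplication at X, two speciations, then duplications at A/B
        assert sum(n.event == T.DUPLICATION
                   for n in gt.postorder()) >= 2
        ok, off = T.check_single_dup_constraint(gt)
        assert ok, [o.name for o in off]
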