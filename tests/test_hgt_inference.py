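import pytest

from xenoscan.grouping import CandidateGroup
from xenoscan.hgt_inference import (UnresolvablePlacement, classify_origin,
                                    combine_cross_species_groups, count_events,
                                    shared_event_assessment, sister_branches)
from xenoscan.taxonomy import RECIPIENT, SELF
from xenoscan.trees import read_newick

B = "DONOR:bacteria"
F = "DONOR:fungi"


def cats(**kw):
    out = {}
    for label, names in kw.items():
        cat = {"bact": B, "fung": F, "animal": RECIPIENT, "self": SELF}[label]
        for n in names:
            out[n] = cat
    return out


class TestSisterBranches:
    TREE = read_newick("(((Q1:1,Q2:1):1,(B1:1,B2:1):1):1,(F1:1,F2:1):1);")

    def test_direct_read_off(self):
        a = sister_branches(self.TREE, {"Q1", "Q2"})
        assert a.sister_leaves == {"B1", "B2"}
        assert a.ancestral_sister_leaves == {"F1", "F2"}

    def test_parent_at_root_no_ancestral_sister(self):
        t = read_newick("((Q1:1,Q2:1):1,(B1:1,B2:1):1);")
        a = sister_branches(t, {"Q1", "Q2"})
        assert a.ancestral_sister_leaves is None

    def test_query_spanning_root_unresolvable(self):
        with pytest.raises(UnresolvablePlacement):
            sister_branches(self.TREE, {"Q1", "F1"})

    def test_cryptic_homolog_absorbed_into_query_clade(self):
        t = read_newick("(((Q1:1,CRY:1):1,(B1:1,B2:1):1):1,(F1:1,F2:1):1);")
        a = sister_branches(t, {"Q1"},
                            cats(self=["CRY"], bact=["B1", "B2"], fung=["F1", "F2"]))
        assert "CRY" in a.clade_leaves
        assert a.sister_leaves == {"B1", "B2"}


class TestClassifyOrigin:
    def analysis(self, tree, queries):
        return sister_branches(tree, queries)

    def test_uniform_kingdom(self):
        a = self.analysis(TestSisterBranches.TREE, {"Q1", "Q2"})
        call = classify_origin(a, cats(bact=["B1", "B2", "F1", "F2"]))
        assert call.origin == "bacteria" and call.donor_count == 4

    def test_complex_two_kingdoms(self):
        a = self.analysis(TestSisterBranches.TREE, {"Q1", "Q2"})
        call = classify_origin(a, cats(bact=["B1", "B2"], fung=["F1", "F2"]))
        assert call.origin == "complex:bacteria|fungi"

    def test_animals_in_both_branches_rejects(self):
        a = self.analysis(TestSisterBranches.TREE, {"Q1", "Q2"})
        call = classify_origin(a, cats(animal=["B1", "F1"], bact=["B2"], fung=["F2"]))
        assert call.origin == "none"

    def test_animal_in_one_branch_tolerated(self):
        a = self.analysis(TestSisterBranches.TREE, {"Q1", "Q2"})
        call = classify_origin(a, cats(bact=["B1", "B2", "F2"], animal=["F1"]))
        assert call.origin == "bacteria"

    def test_mixed_sister_is_other(self):
        a = self.analysis(TestSisterBranches.TREE, {"Q1", "Q2"})
        call = classify_origin(a, cats(bact=["B1"], fung=["B2", "F1", "F2"]))
        assert call.origin == "other"

    def test_empty_sister_no_donor_evidence(self):
        t = read_newick("(((Q1:1,A1:1):1,(B1:1,B2:1):1):1,C:1);")
        a = sister_branches(t, {"Q1"})
        call = classify_origin(a, cats(animal=["A1"], bact=["B1", "B2", "C"]))
        assert call.origin == "none" and "no donor" in call.reason

    def test_invariant_to_pruning_outside_leaves(self):
        big = read_newick(
            "((((Q1:1,Q2:1):1,(B1:1,B2:1):1):1,(F1:1,F2:1):1):1,(X1:1,X2:1):1);")
        small = TestSisterBranches.TREE
        c = cats(bact=["B1", "B2"], fung=["F1", "F2", "X1", "X2"])
        call_big = classify_origin(sister_branches(big, {"Q1", "Q2"}), c)
        call_small = classify_origin(sister_branches(small, {"Q1", "Q2"}), c)
        assert call_big.origin == call_small.origin == "complex:bacteria|fungi"


class TestCountEvents:
    def test_tandem_duplicates_are_one_event(self):
        t = read_newick("(((Q1:1,Q2:1):1,(B1:1,B2:1):1):1,F1:1);")
        n, assign = count_events(t, {"Q1", "Q2"})
        assert n == 1 and assign["Q1"] == assign["Q2"]

    def test_donor_separated_queries_two_events(self):
        t = read_newick("(((Q1:1,B1:1):1,(Q2:1,B2:1):1):1,F1:1);")
        n, assign = count_events(t, {"Q1", "Q2"})
        assert n == 2 and assign["Q1"] != assign["Q2"]

    def test_single_query_single_event(self):
        t = read_newick("((Q1:1,B1:1):1,B2:1);")
        n, _ = count_events(t, {"Q1"})
        assert n == 1

    def test_never_exceeds_query_count(self):
        t = read_newick("((((Q1:1,B1:1):1,Q2:1):1,(Q3:1,B2:1):1):1,F1:1);")
        n, _ = count_events(t, {"Q1", "Q2", "Q3"})
        assert n <= 3


class TestCombineGroups:
    def g(self, gid, members, method="shared_hits"):
        return CandidateGroup(gid, frozenset(members), method)

    def test_merge_via_orthogroup(self):
        a = [self.g("a0", {"A_g1"})]
        b = [self.g("b0", {"B_g1"})]
        out = combine_cross_species_groups(a, b, {"A_g1": "OG1", "B_g1": "OG1"})
        assert len(out) == 1 and out[0].query_ids == {"A_g1", "B_g1"}

    def test_no_links_lists_unchanged(self):
        a = [self.g("a0", {"A_g1"})]
        b = [self.g("b0", {"B_g1"})]
        out = combine_cross_species_groups(a, b, {})
        assert {g.query_ids for g in out} == {frozenset({"A_g1"}), frozenset({"B_g1"})}

    def test_transitive_merge_via_single_og(self):
        a = [self.g("a0", {"A_g1"}), self.g("a1", {"A_g2"})]
        b = [self.g("b0", {"B_g1"})]
        og = {"A_g1": "OG1", "A_g2": "OG1", "B_g1": "OG1"}
        out = combine_cross_species_groups(a, b, og)
        assert len(out) == 1 and out[0].query_ids == {"A_g1", "A_g2", "B_g1"}


class TestSharedEventAssessment:
    def tree_mono(self, support):
        t = read_newick("(((QA:1,QB:1):1,(B1:1,B2:1):1):1,F1:1);")
        node = t.mrca({"QA", "QB"})
        node.support = support
        return t

    def test_supported_monophyly_single_ancestral(self):
        v = shared_event_assessment(self.tree_mono((85.0, 96.0)), {"QA"}, {"QB"})
        assert v == "single_ancestral"

    def test_weak_monophyly_reported_distinctly(self):
        v = shared_event_assessment(self.tree_mono((70.0, 96.0)), {"QA"}, {"QB"})
        assert v == "single_ancestral_weak"

    def test_non_monophyletic_with_small_p_independent(self):
        t = read_newick("(((QA:1,B1:1):1,(QB:1,B2:1):1):1,F1:1);")
        assert shared_event_assessment(t, {"QA"}, {"QB"}, au_p=0.01) == "independent"

    def test_non_monophyletic_with_large_p_inconclusive(self):
        t = read_newick("(((QA:1,B1:1):1,(QB:1,B2:1):1):1,F1:1);")
        assert shared_event_assessment(t, {"QA"}, {"QB"}, au_p=0.30) == "inconclusive"

    def test_one_species_absent(self):
        t = self.tree_mono((90.0, 99.0))
        assert shared_event_assessment(t, {"QA"}, set()) == "single_species"
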