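"""Monophyly, sister groups, origin classification and split chronology."""

import dendropy
import numpy as np
import pytest

from apoptrace.clades import (
    bipartition_present,
    chronology,
    classify_family_origin,
    predates_eukaryogenesis,
    sister_leaves,
)
from apoptrace.phylo import patristic_distances
from apoptrace.simulate import random_tree


def _tree(newick, rooted=True):
    t = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
    t.is_rooted = rooted
    return t


class TestBipartition:
    def test_present_split(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert bipartition_present(t, {"A", "B"})

    def test_absent_split(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert not bipartition_present(t, {"A", "C"})

    def test_improper_subset_rejected(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            bipartition_present(t, {"A", "B", "C", "D"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_edge_enumeration(self, seed):
        t = random_tree([f"T{i}" for i in range(8)], seed=seed)
        all_leaves = frozenset(f"T{i}" for i in range(8))
        # brute-force oracle: enumerate leafsets below every edge
        edge_sets = set()
        for nd in t.preorder_node_iter():
            if nd.parent_node is None:
                continue
            below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            edge_sets.add(below)
            edge_sets.add(all_leaves - below)
        rng = np.random.default_rng(seed)
        for _ in range(20):
            k = int(rng.integers(1, 7))
            subset = frozenset(rng.choice(sorted(all_leaves), size=k, replace=False))
            assert bipartition_present(t, subset) == (subset in edge_sets)


class TestSisterLeaves:
    def test_cherry_sister_is_third_leaf(self):
        t = _tree("((A:1,B:1):1,C:1);")
        assert sister_leaves(t, {"A", "B"}) == {"C"}

    def test_nested_cherry(self):
        t = _tree("(((A:1,B:1):1,C:1):1,D:1);")
        assert sister_leaves(t, {"A", "B"}) == {"C"}

    def test_nonmonophyletic_clade_rejected(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError, match="monophyletic"):
            sister_leaves(t, {"A", "C"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_mrca_walk(self, seed):
        t = random_tree([f"T{i}" for i in range(9)], seed=seed)
        # oracle: pick an internal node, its leafset's sister is its sibling's
        internal = [
            nd for nd in t.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        for nd in internal:
            clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            sibs = set()
            for ch in nd.parent_node.child_nodes():
                if ch is not nd:
                    sibs.update(lf.taxon.label for lf in ch.leaf_iter())
            assert sister_leaves(t, clade) == frozenset(sibs)


class TestOriginClassification:
    def test_eubacterial_without_archaeal_neighbors(self, taxonomy):
        t = _tree("(((Yeast:1,Human:1):1,Ecoli1:1):1,ArchA:1);")
        call = classify_family_origin(t, ["Yeast", "Human", "Ecoli1", "ArchA"], taxonomy)
        assert call.call == "eubacterial"
        assert "Ecoli1" in call.noneuk_neighbors

    def test_pure_eukaryotic_family(self, taxonomy):
        t = _tree("((Yeast:1,Human:1):1,(PlantA:1,AmoebaA:1):1);")
        call = classify_family_origin(t, ["Yeast", "Human", "PlantA", "AmoebaA"], taxonomy)
        assert call.call == "eukaryote_only"

    def test_mixed_neighborhood_is_ambiguous(self, taxonomy):
        # rooted at ArchA, the minimal clade around {Yeast, Human} contains
        # Ecoli1 and its sister is the archaeal outgroup itself
        t = _tree("((Yeast:1,Ecoli1:1):1,(Human:1,ArchA:1):1);")
        call = classify_family_origin(t, ["Yeast", "Human"], taxonomy)
        assert call.call == "ambiguous"

    def test_missing_taxonomy_entry_named(self, taxonomy):
        t = _tree("((Yeast:1,Mystery:1):1,Ecoli1:1);")
        with pytest.raises(KeyError, match="Mystery"):
            classify_family_origin(t, ["Yeast", "Mystery"], taxonomy)

    def test_leaf_order_invariance(self, taxonomy):
        t = _tree("(((Yeast:1,Human:1):1,Ecoli1:1):1,ArchA:1);")
        a = classify_family_origin(t, ["Yeast", "Human", "Ecoli1", "ArchA"], taxonomy)
        b = classify_family_origin(t, ["ArchA", "Ecoli1", "Human", "Yeast"], taxonomy)
        assert a.call == b.call and a.clade_leaves == b.clade_leaves


class TestPredatesEukaryogenesis:
    def test_paralogs_nested_among_bacteria(self, taxonomy):
        t = _tree("(((Human:1,Ecoli1:1):1,Ecoli2:1):1,((Yeast:1,Ecoli1b:1):1,Ecoli2b:1):1);")
        # second bacterial pair needs taxonomy entries
        taxonomy.seq_to_species.update({"Ecoli1b": "E_coli", "Ecoli2b": "B_subtilis"})
        assert predates_eukaryogenesis(t, {"Human"}, {"Yeast"}, taxonomy)

    def test_sister_paralogs_do_not_predate(self, taxonomy):
        t = _tree("(((Human:1,Yeast:1):1,Ecoli1:1):1,Ecoli2:1);")
        assert not predates_eukaryogenesis(t, {"Human"}, {"Yeast"}, taxonomy)

    def test_symmetric_in_clades(self, taxonomy):
        taxonomy.seq_to_species.update({"Ecoli1b": "E_coli", "Ecoli2b": "B_subtilis"})
        t = _tree("(((Human:1,Ecoli1:1):1,Ecoli2:1):1,((Yeast:1,Ecoli1b:1):1,Ecoli2b:1):1);")
        assert predates_eukaryogenesis(t, {"Human"}, {"Yeast"}, taxonomy) == \
            predates_eukaryogenesis(t, {"Yeast"}, {"Human"}, taxonomy)

    def test_no_bacteria_is_error(self, taxonomy):
        t = _tree("((Human:1,Yeast:1):1,PlantA:1);")
        with pytest.raises(ValueError, match="eubacterial"):
            predates_eukaryogenesis(t, {"Human"}, {"Yeast"}, taxonomy)

    def test_decision_matches_patristic_oracle(self, taxonomy):
        taxonomy.seq_to_species.update({"Ecoli1b": "E_coli", "Ecoli2b": "B_subtilis"})
        for seed in range(6):
            labels = ["Human", "Yeast", "Ecoli1", "Ecoli2", "Ecoli1b", "Ecoli2b"]
            t = random_tree(labels, seed=seed)
            got = predates_eukaryogenesis(t, {"Human"}, {"Yeast"}, taxonomy)
            # oracle: direct all-pairs path computation
            labs, d = patristic_distances(t)
            pos = {l: i for i, l in enumerate(labs)}
            d_ab = d[pos["Human"], pos["Yeast"]]
            bact = ["Ecoli1", "Ecoli2", "Ecoli1b", "Ecoli2b"]
            d_a = min(d[pos["Human"], pos[e]] for e in bact)
            d_b = min(d[pos["Yeast"], pos[e]] for e in bact)
            forms = bipartition_present(t, {"Human", "Yeast"})
            assert got == (d_a < d_ab and d_b < d_ab and not forms)


class TestChronology:
    def test_root_tie_broken_by_preorder(self):
        t = _tree("((A:1,B:1):1,(C:2,D:2):0);")
        rep = chronology(t)
        heights = [e.height for e in rep.events]
        assert heights == [2.0, 2.0, 1.0]
        assert rep.first().preorder_index == 0  # root wins the tie

    def test_two_leaf_tree_single_event(self):
        t = _tree("(A:1,B:1);")
        rep = chronology(t)
        assert len(rep.events) == 1
        assert rep.events[0].height == 1.0

    def test_scale_invariant_ordering(self):
        t1 = _tree("((A:1,B:1):1,(C:2,D:2):0.5);")
        t2 = _tree("((A:3,B:3):3,(C:6,D:6):1.5);")
        order1 = [e.child_leafsets for e in chronology(t1).events]
        order2 = [e.child_leafsets for e in chronology(t2).events]
        assert order1 == order2

    def test_missing_branch_length_is_error(self):
        t = _tree("((A:1,B:1),(C:2,D:2):1);")
        with pytest.raises(ValueError, match="branch length"):
            chronology(t)

    def test_first_event_is_root_on_clocklike_trees(self):
        from apoptrace.simulate import EndosymbiosisScenario, simulate_endosymbiosis
        t = _tree("((A:2,(B:1,C:1):1):1,(D:2,E:2):1);")
        rep = chronology(t)
        root_children = {frozenset({"A", "B", "C"}), frozenset({"D", "E"})}
        assert set(rep.first().child_leafsets) == root_children
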