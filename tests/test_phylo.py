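"""Distances, neighbor joining, bootstrap and rooting."""

import io
import math

import dendropy
import numpy as np
import pytest

from apoptrace.phylo import (
    BootstrapSpec,
    DistanceMatrix,
    bootstrap_support,
    edge_bipartitions,
    neighbor_joining,
    nontrivial_bipartitions,
    p_distance_matrix,
    patristic_distances,
    poisson_correct,
    poisson_distance,
    root_tree,
)
from apoptrace.seqio import MultipleAlignment
from apoptrace.simulate import random_tree


def _additive(tree):
    labels, d = patristic_distances(tree)
    return DistanceMatrix(labels=labels, values=d)


class TestPDistance:
    def test_one_of_four(self):
        aln = MultipleAlignment(rows=[("a", "AAAA"), ("b", "AAAT")])
        D = p_distance_matrix(aln)
        assert D.values[0, 1] == pytest.approx(0.25)

    def test_identical_rows(self):
        aln = MultipleAlignment(rows=[("a", "WYWY"), ("b", "WYWY")])
        assert p_distance_matrix(aln).values[0, 1] == 0.0

    def test_pairwise_deletion_matches_column_scan(self):
        rng = np.random.default_rng(0)
        alphabet = np.array(list("ACDE-"))
        rows = [("r%d" % i, "".join(rng.choice(alphabet, size=60))) for i in range(4)]
        aln = MultipleAlignment(rows=rows)
        D = p_distance_matrix(aln)
        for i in range(4):
            for j in range(i + 1, 4):
                num = den = 0
                for x, y in zip(rows[i][1], rows[j][1]):
                    if x != "-" and y != "-":
                        den += 1
                        num += x != y
                assert D.values[i, j] == pytest.approx(num / den)

    def test_no_comparable_columns_is_error(self):
        aln = MultipleAlignment(rows=[("a", "A-"), ("b", "-A")])
        with pytest.raises(ValueError, match="comparable"):
            p_distance_matrix(aln)


class TestPoisson:
    def test_closed_form_values(self):
        assert poisson_distance(0.0) == 0.0
        assert poisson_distance(0.5) == pytest.approx(0.693147, abs=1e-6)

    def test_saturation_clamped(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert poisson_distance(1.0) == 10.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
        )
        t = neighbor_joining(D)
        lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0), "C": pytest.approx(3.0)}

    def test_four_taxon_additive_recovery(self):
        gen = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        t = neighbor_joining(_additive(gen))
        got = edge_bipartitions(t)
        # internal AB|CD edge (canonical side excludes leaf A) has length 2
        assert got[frozenset({"C", "D"})] == pytest.approx(2.0, abs=1e-9)
        for key in (frozenset({"B"}), frozenset({"C"}), frozenset({"D"}),
                    frozenset({"B", "C", "D"})):
            assert got[key] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrices_recover_tree_exactly(self, seed):
        gen = random_tree([f"T{i}" for i in range(12)], seed=seed)
        t = neighbor_joining(_additive(gen))
        want = edge_bipartitions(gen)
        got = edge_bipartitions(t)
        assert set(want) == set(got)
        for key, ln in want.items():
            assert got[key] == pytest.approx(ln, abs=1e-9)

    def test_agrees_with_dendropy_nj_on_noisy_matrix(self):
        # independent implementation check on a non-additive matrix
        rng = np.random.default_rng(7)
        gen = random_tree([f"T{i}" for i in range(8)], seed=3)
        labels, d = patristic_distances(gen)
        noise = rng.uniform(0.98, 1.02, size=d.shape)
        d = d * (noise + noise.T) / 2
        np.fill_diagonal(d, 0.0)
        ours = neighbor_joining(DistanceMatrix(labels=labels, values=d))

        csv = "," + ",".join(labels) + "\n"
        for i, lab in enumerate(labels):
            csv += lab + "," + ",".join(f"{x:.10f}" for x in d[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=","
        )
        theirs = pdm.nj_tree()
        t2 = dendropy.Tree.get(
            data=theirs.as_string(schema="newick"), schema="newick",
            suppress_internal_node_taxa=True,
        )
        assert nontrivial_bipartitions(ours) == nontrivial_bipartitions(t2)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["a", "b"], values=np.array([[0, 1], [2, 0]], float))

    def test_row_order_invariance_up_to_relabeling(self):
        gen = random_tree([f"T{i}" for i in range(7)], seed=5)
        D = _additive(gen)
        perm = [3, 1, 0, 6, 4, 5, 2]
        D2 = DistanceMatrix(
            labels=[D.labels[k] for k in perm], values=D.values[np.ix_(perm, perm)]
        )
        assert edge_bipartitions(neighbor_joining(D)) == pytest.approx(
            edge_bipartitions(neighbor_joining(D2))
        )


def _clean_split_alignment():
    """A and B near-identical, C and D near-identical, the pairs maximally
    separated: every column supports AB|CD."""
    return MultipleAlignment(
        rows=[
            ("A", "AAAAAAAAAAAAAAAAAAAA"),
            ("B", "AAAAAAAAAAAAAAAAAAAC"),
            ("C", "WWWWWWWWWWWWWWWWWWWW"),
            ("D", "WWWWWWWWWWWWWWWWWWWY"),
        ]
    )


class TestBootstrap:
    def test_clean_split_has_full_support(self):
        t = bootstrap_support(_clean_split_alignment(), BootstrapSpec(replicates=100, seed=0))
        sups = [nd.support for nd in t.preorder_node_iter() if nd.support is not None]
        assert sups == [100.0]

    def test_single_replicate_quantization(self):
        t = bootstrap_support(_clean_split_alignment(), BootstrapSpec(replicates=1, seed=0))
        sups = [nd.support for nd in t.preorder_node_iter() if nd.support is not None]
        assert all(s in (0.0, 100.0) for s in sups)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(4)
        rows = [("r%d" % i, "".join(rng.choice(list("ACDEFG"), size=40))) for i in range(6)]
        aln = MultipleAlignment(rows=rows)
        def supports(seed):
            t = bootstrap_support(aln, BootstrapSpec(replicates=30, seed=seed))
            return sorted(
                nd.support for nd in t.preorder_node_iter() if nd.support is not None
            )
        assert supports(9) == supports(9)

    def test_supports_in_range(self):
        rng = np.random.default_rng(11)
        rows = [("r%d" % i, "".join(rng.choice(list("ACDE"), size=30))) for i in range(6)]
        t = bootstrap_support(MultipleAlignment(rows=rows), BootstrapSpec(replicates=25, seed=1))
        for nd in t.preorder_node_iter():
            if nd.support is not None:
                assert 0.0 <= nd.support <= 100.0


class TestRooting:
    def test_symmetric_two_branch_midpoint(self):
        t = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        r = root_tree(t, mode="midpoint")
        kids = r.seed_node.child_nodes()
        assert sorted(k.edge.length for k in kids) == [pytest.approx(1.0)] * 2 or sorted(
            k.edge.length for k in kids
        ) == [pytest.approx(0.0), pytest.approx(2.0)]

    def test_chain_midpoint_halfway(self):
        t = dendropy.Tree.get(data="(A:1,B:2);", schema="newick")
        r = root_tree(t, mode="midpoint")
        lengths = sorted(lf.edge.length for lf in r.leaf_node_iter())
        assert lengths == [pytest.approx(1.5), pytest.approx(1.5)]

    @pytest.mark.parametrize("mode,outgroup", [("midpoint", None), ("outgroup", {"T0", "T1"})])
    def test_patristic_distances_preserved(self, mode, outgroup):
        gen = dendropy.Tree.get(
            data="((T0:0.3,T1:0.4):0.8,((T2:0.2,T3:0.9):0.1,T4:0.5):0.3);",
            schema="newick",
        )
        l0, d0 = patristic_distances(gen)
        r = root_tree(gen, mode=mode, outgroup=outgroup)
        l1, d1 = patristic_distances(r)
        assert l0 == l1
        assert np.allclose(d0, d1)

    def test_outgroup_must_be_bipartition(self):
        t = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        with pytest.raises(ValueError, match="bipartition"):
            root_tree(t, mode="outgroup", outgroup={"A", "C"})
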