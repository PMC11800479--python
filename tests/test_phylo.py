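import math

import numpy as np
import pytest

from xenoscan.phylo import (Alignment, DistanceMatrix, bootstrap_support,
                            constrain_monophyly, dedupe_identical,
                            neighbor_joining, poisson_distance, trim_columns)
from xenoscan.trees import Node, Tree


def random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree with branch lengths in [0.1, 1.0]."""
    names = [f"L{i}" for i in range(n_leaves)]
    bl = lambda: float(rng.uniform(0.1, 1.0))  # noqa: E731
    root = Node(None)
    for name in names[:3]:
        root.add(Node(name, bl()))
    edges = list(root.children)
    for name in names[3:]:
        edge = edges[int(rng.integers(len(edges)))]
        parent = edge.parent
        mid = Node(None, edge.length * float(rng.uniform(0.2, 0.8)))
        edge.length = edge.length - mid.length
        parent.children[parent.children.index(edge)] = mid
        mid.parent = parent
        mid.add(edge)
        leaf = Node(name, bl())
        mid.add(leaf)
        edges.extend([leaf, mid, edge])
        edges = [e for e in {id(x): x for x in edges}.values()]
    return Tree(root, rooted=False)


def dm_from_tree(tree):
    names, dist = tree.leaf_distances()
    names = sorted(names)
    n = len(names)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dist[(min(names[i], names[j]), max(names[i], names[j]))]
    return DistanceMatrix(names, m)


def branch_length_map(tree):
    """Canonical bipartition -> branch length (terminal branches keyed by leaf)."""
    names = set(tree.leaf_names())
    anchor = min(names)
    below = tree.clade_leaf_sets()
    out = {}
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = below[id(node)]
        canon = frozenset(side if anchor not in side else names - side)
        out[canon] = out.get(canon, 0.0) + node.length
    return out


class TestAlignmentOps:
    def test_dedupe_keeps_first(self):
        aln = Alignment(["a", "b", "c", "d"], ["AAA", "AAA", "AAA", "CCC"])
        out, removed = dedupe_identical(aln)
        assert out.ids == ["a", "d"]
        assert removed == {"b": "a", "c": "a"}

    def test_dedupe_all_distinct_unchanged(self):
        aln = Alignment(["a", "b"], ["AAA", "CCC"])
        out, removed = dedupe_identical(aln)
        assert out.ids == ["a", "b"] and not removed

    def test_trim_boundary_kept_at_equality(self):
        # gap fractions 0, 0.25, 0.5, 0.75 at threshold 0.5 -> 3 columns kept
        aln = Alignment(
            ["a", "b", "c", "d"],
            ["ACDE", "ACD-", "AC--", "A---"],
        )
        out, kept = trim_columns(aln, 0.5)
        assert kept == [0, 1, 2]
        assert out.n_sites == 3

    def test_trim_gap_free_identity(self):
        aln = Alignment(["a", "b"], ["ACD", "ACD"])
        out, kept = trim_columns(aln, 0.5)
        assert out.rows == aln.rows and kept == [0, 1, 2]

    def test_trim_all_removed_raises(self):
        aln = Alignment(["a", "b"], ["--", "--"])
        with pytest.raises(ValueError):
            trim_columns(aln, 0.4)


class TestPoissonDistance:
    def test_identical_rows_zero(self):
        d = poisson_distance(Alignment(["a", "b"], ["ACDEF", "ACDEF"]))
        assert d.matrix[0, 1] == 0.0

    def test_half_mismatch_closed_form(self):
        d = poisson_distance(Alignment(["a", "b"], ["ACDE", "ACWY"]))
        assert d.matrix[0, 1] == pytest.approx(math.log(2), abs=1e-12)

    def test_saturation_capped(self):
        d = poisson_distance(Alignment(["a", "b"], ["ACDE", "WYHK"]))
        assert d.matrix[0, 1] == 10.0

    def test_gaps_excluded_from_comparison(self):
        d = poisson_distance(Alignment(["a", "b"], ["AC-E", "ACW-"]))
        assert d.matrix[0, 1] == 0.0  # only the two shared columns match


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        ids = ["A", "B", "C", "D"]
        la, lb, lc, ld, mid = 0.2, 0.3, 0.4, 0.5, 1.0
        d = {("A", "B"): la + lb, ("A", "C"): la + mid + lc,
             ("A", "D"): la + mid + ld, ("B", "C"): lb + mid + lc,
             ("B", "D"): lb + mid + ld, ("C", "D"): lc + ld}
        m = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            m[i, j] = m[j, i] = v
        tree = neighbor_joining(DistanceMatrix(ids, m))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        bl = branch_length_map(tree)
        assert bl[frozenset({"C", "D"})] == pytest.approx(mid, abs=1e-12)

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], m))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_all_zero_distances_star(self):
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), np.zeros((4, 4))))
        assert all(n.length == 0.0 for n in tree.postorder() if n is not tree.root)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_random_additive_recovery(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            gen = random_additive_tree(rng, n)
            rec = neighbor_joining(dm_from_tree(gen))
            assert rec.bipartitions() == gen.bipartitions()
            gl, rl = branch_length_map(gen), branch_length_map(rec)
            for split, length in gl.items():
                assert rl[split] == pytest.approx(length, abs=1e-9)

    def test_matches_dendropy_on_additive_matrix(self, rng):
        # independent oracle: dendropy's NJ on the same matrix
        import dendropy

        gen = random_additive_tree(rng, 8)
        dm = dm_from_tree(gen)
        csv = "," + ",".join(dm.ids) + "\n"
        for i, name in enumerate(dm.ids):
            csv += name + "," + ",".join(f"{x:.10f}" for x in dm.matrix[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv))
        dtree = pdm.nj_tree()
        ours = neighbor_joining(dm)
        # compare unrooted bipartitions
        theirs = set()
        names = set(dm.ids)
        anchor = min(names)
        for edge in dtree.preorder_edge_iter():
            head = edge.head_node
            leaves = {l.taxon.label for l in head.leaf_iter()}
            if 1 < len(leaves) < len(names) - 1:
                theirs.add(frozenset(leaves if anchor not in leaves
                                     else names - leaves))
        assert ours.bipartitions() == theirs


class TestConstrainedNJ:
    def test_constraint_already_monophyletic(self):
        gen_ids = ["A", "B", "C", "D"]
        m = np.array([[0, 0.5, 3, 3], [0.5, 0, 3, 3], [3, 3, 0, 0.5], [3, 3, 0.5, 0]],
                     dtype=float)
        dm = DistanceMatrix(gen_ids, m)
        un = neighbor_joining(dm)
        con = constrain_monophyly(dm, {"A", "B"})
        assert con.bipartitions() == un.bipartitions()

    def test_forced_split_against_signal(self):
        ids = ["A", "B", "C", "D"]
        m = np.array([[0, 0.5, 3, 3], [0.5, 0, 3, 3], [3, 3, 0, 0.5], [3, 3, 0.5, 0]],
                     dtype=float)
        con = constrain_monophyly(DistanceMatrix(ids, m), {"A", "C"})
        assert con.is_monophyletic({"A", "C"})

    def test_n_minus_one_constraint(self):
        ids = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(5)
        m = rng.uniform(1, 2, size=(5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        con = constrain_monophyly(DistanceMatrix(ids, m), {"A", "B", "C", "D"})
        assert con.is_monophyletic({"A", "B", "C", "D"})

    def test_full_set_constraint_rejected(self):
        with pytest.raises(ValueError):
            constrain_monophyly(DistanceMatrix(["A", "B", "C"], np.zeros((3, 3))),
                                {"A", "B", "C"})

    def test_random_constraints_always_satisfied(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 10))
            gen = random_additive_tree(rng, n)
            dm = dm_from_tree(gen)
            k = int(rng.integers(2, n - 1))
            subset = set(rng.choice(dm.ids, size=k, replace=False).tolist())
            con = constrain_monophyly(dm, subset)
            assert con.is_monophyletic(subset)


class TestBootstrap:
    @pytest.fixture
    def two_clade_alignment(self, rng):
        # two well-separated pairs: (A,B) vs (C,D)
        n = 200
        base = rng.integers(0, 20, size=n)
        other = (base + rng.integers(1, 20, size=n)) % 20
        from xenoscan.phylo import AA
        mk = lambda arr: "".join(AA[i] for i in arr)  # noqa: E731
        flip = rng.random(n) < 0.05
        return Alignment(
            ["A", "B", "C", "D"],
            [mk(base), mk(np.where(flip, other, base)),
             mk(other), mk(np.where(flip, base, other))],
        )

    def test_unambiguous_split_gets_full_support(self, two_clade_alignment):
        t = bootstrap_support(two_clade_alignment, B=100, seed=3)
        sup = [n.support for n in t.postorder()
               if not n.is_leaf and n is not t.root and n.support]
        assert sup and all(s[1] == 100.0 for s in sup)

    def test_single_replicate_support_binary(self, two_clade_alignment):
        t = bootstrap_support(two_clade_alignment, B=1, seed=3)
        for n in t.postorder():
            if n.support is not None:
                assert n.support[1] in (0.0, 100.0)

    def test_same_seed_identical(self, two_clade_alignment):
        t1 = bootstrap_support(two_clade_alignment, B=50, seed=9)
        t2 = bootstrap_support(two_clade_alignment, B=50, seed=9)
        s1 = sorted(n.support for n in t1.postorder() if n.support)
        s2 = sorted(n.support for n in t2.postorder() if n.support)
        assert s1 == s2

    def test_custom_builder_path_matches_contract(self, two_clade_alignment):
        from xenoscan.phylo import neighbor_joining as nj, poisson_distance as pd_

        t = bootstrap_support(two_clade_alignment, B=20, seed=3,
                              tree_builder=lambda a: nj(pd_(a)))
        assert set(t.leaf_names()) == {"A", "B", "C", "D"}
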