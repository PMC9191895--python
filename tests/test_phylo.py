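"""NJ exactness, rooting, age-cutoff clades, bootstrap, logo matrices."""

import itertools
import math
import random

import numpy as np
import pytest
from skbio import TreeNode

from pepfam.phylo import (DistanceMatrix, bootstrap_support, clades_by_age,
                          msa_distance, nj_tree, node_ages, root_tree,
                          sequence_logo)
from pepfam.seqio import Msa, read_newick

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_additive_tree(n, rng):
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        a.length = rng.uniform(0.1, 2.0)
        b.length = rng.uniform(0.1, 2.0)
        nodes.append(TreeNode(children=[a, b]))
    nodes[0].length = 0.0
    return nodes[0]


def _dm_from_tree(tree):
    names = sorted(t.name for t in tree.tips())
    tt = tree.tip_tip_distances()
    M = np.array([[0.0 if a == b else tt[a, b] for b in names] for a in names])
    return DistanceMatrix(ids=names, matrix=M)


class TestDistances:
    def test_identical_rows_zero(self):
        dm = msa_distance(Msa([("a", "MKV"), ("b", "MKV")]))
        assert dm.get("a", "b") == 0.0

    def test_poisson_closed_form(self):
        dm = msa_distance(Msa([("a", "MKVA"), ("b", "MKWW")]), model="poisson")
        assert dm.get("a", "b") == pytest.approx(math.log(2))

    def test_pairwise_deletion(self):
        dm = msa_distance(Msa([("a", "MK-V"), ("b", "MKW-")]))
        assert dm.get("a", "b") == 0.0  # only 2 shared ungapped, both match

    def test_zero_shared_columns_error_names_pair(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            msa_distance(Msa([("a", "M-"), ("b", "-M")]))


class TestNeighborJoining:
    def test_four_taxon_exact_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive matrix by hand
        ids = list("abcd")
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                     dtype=float)
        tree = nj_tree(DistanceMatrix(ids=ids, matrix=D))
        tt = tree.tip_tip_distances()
        for a, b in itertools.combinations(ids, 2):
            assert tt[a, b] == pytest.approx(D[ids.index(a), ids.index(b)])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)

    def test_random_additive_trees_recovered(self):
        """RF distance 0 and path metric reproduced within 1e-9."""
        rng = random.Random(5)
        for trial in range(50):
            n = rng.randint(4, 16)
            src = _random_additive_tree(n, rng)
            dm = _dm_from_tree(src)
            rec = nj_tree(dm)
            assert src.compare_rfd(rec, rooted=False) == 0
            tt = rec.tip_tip_distances()
            for i, a in enumerate(dm.ids):
                for b in dm.ids[i + 1:]:
                    assert abs(tt[a, b] - dm.get(a, b)) < 1e-9

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids=list("abc"), matrix=D))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((2 + 3 - 5) / 2)
        assert lengths["b"] == pytest.approx((2 + 5 - 3) / 2)
        assert lengths["c"] == pytest.approx((3 + 5 - 2) / 2)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(ids=["a", "b"],
                                   matrix=np.array([[0., 1.], [1., 0.]])))


class TestRooting:
    def test_outgroup_pendant_edge_midpoint(self):
        tree = read_newick("((a:1,b:1):0.5,(c:3,d:4):0.5);")
        rooted = root_tree(tree, outgroup="c")
        assert len(rooted.children) == 2
        og_side = next(c for c in rooted.children
                       if {t.name for t in c.tips()} == {"c"} or c.name == "c")
        assert og_side.length == pytest.approx(1.5)

    def test_path_lengths_preserved(self):
        tree = read_newick("((a:1,b:2):1,(c:3,d:4):0.5);")
        before = tree.tip_tip_distances()
        rooted = root_tree(tree.copy(), outgroup="d")
        after = rooted.tip_tip_distances()
        for a, b in itertools.combinations("abcd", 2):
            assert after[a, b] == pytest.approx(before[a, b])

    def test_midpoint_on_longest_path(self):
        tree = read_newick("((a:1,b:1):0.0,c:4);")
        rooted = root_tree(tree, midpoint=True)
        depths = {t.name: rooted.distance(t) for t in rooted.tips()}
        assert depths["c"] == pytest.approx(2.5)

    def test_absent_outgroup_raises(self):
        with pytest.raises(ValueError):
            root_tree(read_newick("((a:1,b:1):1,c:1);"), outgroup="zz")


class TestClades:
    def test_cutoff_zero_all_singletons(self):
        tree = read_newick("(((a:1,b:1):1,c:2):1,d:9);")
        cs = clades_by_age(tree, 0.0)
        assert sorted(leaves for _, leaves, _ in cs.clades) == \
            [["a"], ["b"], ["c"], ["d"]]

    def test_cutoff_above_root_single_clade(self):
        tree = read_newick("(((a:1,b:1):1,c:2):1,d:9);")
        cs = clades_by_age(tree, 100.0)
        assert len(cs) == 1 and cs.clades[0][1] == ["a", "b", "c", "d"]

    def test_caterpillar_cherries_and_singletons(self):
        """Unit-branch caterpillar at cutoff 1.5, vs hand enumeration."""
        tree = read_newick("((((a:1,b:1):1,c:1):1,d:1):1,e:1);")
        cs = clades_by_age(tree, 1.5)
        got = sorted(tuple(leaves) for _, leaves, _ in cs.clades)
        assert got == [("a", "b"), ("c",), ("d",), ("e",)]

    def test_partition_of_leaves_and_monotone_coarsening(self):
        rng = random.Random(2)
        tree = root_tree(_dm_and_tree(rng), midpoint=True)
        leaves = {t.name for t in tree.tips()}
        prev = None
        for cutoff in (0.0, 0.5, 1.0, 2.0, 5.0, 100.0):
            cs = clades_by_age(tree, cutoff)
            mapping = cs.leaf_to_clade()
            assert set(mapping) == leaves  # exact partition
            if prev is not None:
                # coarsening: any two leaves together before stay together
                for x, y in itertools.combinations(sorted(leaves), 2):
                    if prev[x] == prev[y]:
                        assert mapping[x] == mapping[y]
            prev = mapping

    def test_unrooted_rejected(self):
        tree = read_newick("(a:1,b:1,c:1);")
        with pytest.raises(ValueError):
            clades_by_age(tree, 1.0)


def _dm_and_tree(rng):
    return nj_tree(_dm_from_tree(_random_additive_tree(10, rng)))


class TestBootstrap:
    def _block_msa(self, seed=0, n_cols=60, p=0.05):
        g = np.random.default_rng(seed)
        rows = []
        for base_name, base in (("x", None), ("y", None)):
            base = "".join(g.choice(list(AA)) for _ in range(n_cols))
            for i in range(3):
                mut = "".join(
                    str(g.choice(list(AA))) if g.random() < p else c
                    for c in base)
                rows.append((f"{base_name}{i}", mut))
        return Msa(rows)

    def test_clean_split_full_support(self):
        msa = self._block_msa()
        ref, support = bootstrap_support(msa, n_replicates=100, rng_seed=2)
        block = frozenset({frozenset({"x0", "x1", "x2"}),
                           frozenset({"y0", "y1", "y2"})})
        assert support[block] == 1.0

    def test_supports_bounded_and_deterministic(self):
        msa = self._block_msa(seed=3, p=0.25)
        _, s1 = bootstrap_support(msa, n_replicates=20, rng_seed=9)
        _, s2 = bootstrap_support(msa, n_replicates=20, rng_seed=9)
        assert s1 == s2
        assert all(0.0 <= v <= 1.0 for v in s1.values())

    def test_single_replicate_binary(self):
        msa = self._block_msa(seed=4)
        _, s = bootstrap_support(msa, n_replicates=1, rng_seed=0)
        assert set(s.values()) <= {0.0, 1.0}

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            bootstrap_support(Msa([("a", "MK"), ("b", "MK"), ("c", "MK")]), 10, 0)


class TestLogo:
    def test_conserved_column_max_ic(self):
        msa = Msa([(f"s{i}", "W") for i in range(10)])
        logo = sequence_logo(msa)
        assert logo.information[0] == pytest.approx(math.log2(20))

    def test_uniform_column_zero_ic(self):
        msa = Msa([(f"s{i}", c) for i, c in enumerate(AA)])
        logo = sequence_logo(msa)
        assert logo.information[0] == pytest.approx(0.0)

    def test_occupancy_boundary_strictly_less(self):
        # 20 rows; column 1 has exactly 5% occupancy (1 residue): retained
        rows = [(f"s{i}", "M" + ("K" if i == 0 else "-")) for i in range(20)]
        logo = sequence_logo(Msa(rows), occupancy_min=0.05)
        assert logo.columns == [0, 1]
        # below the boundary (1/21 < 5%) the column is trimmed
        rows.append(("s20", "M-"))
        logo = sequence_logo(Msa(rows), occupancy_min=0.05)
        assert logo.columns == [0]

    def test_trimming_idempotent(self):
        rows = [(f"s{i}", "MA--K") for i in range(10)] + [("t", "MAW-K")]
        logo1 = sequence_logo(Msa(rows))
        kept = ["".join(row[c] for c in logo1.columns) for _, row in Msa(rows).records]
        logo2 = sequence_logo(Msa(list(zip([r for r, _ in rows] + [], kept))))
        assert logo2.columns == list(range(len(logo1.columns)))
        assert np.allclose(logo1.frequencies, logo2.frequencies)

    def test_all_trimmed_raises(self):
        rows = [(f"s{i}", "--") for i in range(5)]
        with pytest.raises(ValueError):
            sequence_logo(Msa(rows))
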