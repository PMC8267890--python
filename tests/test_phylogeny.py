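import itertools

import numpy as np
import pandas as pd
import pytest

from pangevo import phylogeny as phy
from pangevo.trees import Tree, all_unrooted_topologies, random_tree

from .helpers import brute_force_fitch, grid_k_score


class TestBinaryEncode:
    def test_abundance_thresholding_and_at_export(self):
        pm = pd.DataFrame({"C1": [3, 0], "C2": [1, 2]}, index=["g1", "g2"])
        binary = phy.binary_encode(pm)
        assert binary.loc["g1", "C1"] == 1
        assert binary.loc["g2", "C1"] == 0
        rows = phy.to_at_rows(binary)
        assert rows["g1"] == "TT"
        assert rows["g2"] == "AT"

    def test_all_present_all_t(self):
        pm = pd.DataFrame({"C1": [1, 2], "C2": [5, 1]}, index=["g1", "g2"])
        assert set("".join(phy.to_at_rows(phy.binary_encode(pm)).values())) == {"T"}


def _perfect_matrix():
    # characters compatible with ((A,B),(C,D),E); all non-constant
    chars = {"A": [1, 1, 0, 0, 1, 0], "B": [1, 1, 0, 0, 0, 1],
             "C": [0, 0, 1, 1, 0, 0], "D": [0, 0, 1, 0, 0, 0],
             "E": [0, 0, 0, 0, 0, 0]}
    return pd.DataFrame(chars).T


class TestParsimonyTree:
    def test_perfect_phylogeny_recovered_with_minimal_length(self):
        m = _perfect_matrix()
        tree = phy.parsimony_tree(m, n_bootstrap=0)
        assert frozenset({"A", "B"}) in set(tree.bipartitions()) or \
            frozenset({"C", "D"}) in set(tree.bipartitions())
        best = min(phy.fitch_length(t, m)
                   for t in all_unrooted_topologies(list("ABCDE")))
        assert phy.fitch_length(tree, m) == best == 6

    def test_identical_rows_become_siblings(self):
        m = pd.DataFrame({"A": [1, 1, 0, 0], "B": [1, 1, 0, 0],
                          "C": [0, 0, 1, 1], "D": [0, 1, 1, 1]}).T
        tree = phy.parsimony_tree(m, n_bootstrap=0)
        # the A|B split is canonically recorded as its complement {C, D}
        assert frozenset({"C", "D"}) in set(tree.bipartitions())

    def test_homogeneous_characters_give_full_support(self):
        m = pd.DataFrame({"A": [1] * 100, "B": [1] * 100, "C": [0] * 100,
                          "D": [0] * 100, "E": [0] * 100}).T
        tree = phy.parsimony_tree(m, n_bootstrap=200, seed=3)
        supports = [n.support for n in tree.internal_nodes()
                    if n.support is not None]
        assert supports and all(s == 100 for s in supports)

    def test_hill_climbing_never_worse_than_nj_start(self, rng):
        for _ in range(5):
            m = pd.DataFrame(rng.integers(0, 2, size=(6, 30)),
                             index=list("ABCDEF"))
            start = phy.neighbor_joining(phy._hamming(m.set_axis(m.index.map(str))))
            final = phy.parsimony_tree(m, n_bootstrap=0)
            assert phy.fitch_length(final, m) <= phy.fitch_length(start, m)

    def test_fitch_matches_enumeration_on_small_trees(self, rng):
        for _ in range(20):
            labels = [f"T{i}" for i in range(rng.integers(4, 7))]
            tree = random_tree(labels, rng, 0.1)
            states = {lab: int(rng.integers(0, 2)) for lab in labels}
            m = pd.DataFrame({"c": [states[lab] for lab in labels]},
                             index=labels)
            assert phy.fitch_length(tree, m) == brute_force_fitch(tree, states)

    def test_too_few_taxa_rejected(self):
        m = pd.DataFrame({"A": [1], "B": [0]}).T
        with pytest.raises(ValueError, match="3 taxa"):
            phy.parsimony_tree(m)


class TestConcatAndMask:
    def test_gap_column_dropped_then_constants(self):
        alns = {"c1": {"g1": "AAC-T", "g2": "AACAT", "g3": "AGCAT"}}
        sm = phy.concat_and_mask(alns)
        # column 4 has a gap; columns 1,3,5 constant after masking
        assert sm.n_after_gap_mask == 4
        assert sm.n_variable == 1
        assert sm.rows["g1"] == "A"
        assert sm.rows["g3"] == "G"

    def test_all_constant_gives_empty_supermatrix(self):
        alns = {"c1": {"g1": "AAA", "g2": "AAA", "g3": "AAA"}}
        sm = phy.concat_and_mask(alns)
        assert sm.n_variable == 0
        with pytest.raises(ValueError, match="empty supermatrix"):
            phy.distance_tree(sm)

    def test_survivor_count_matches_column_scan(self, rng):
        genomes = ["g1", "g2", "g3", "g4"]
        alns = {}
        for c in range(3):
            width = int(rng.integers(10, 20))
            rows = {}
            for g in genomes:
                chars = rng.choice(list("ACGT-"), size=width,
                                   p=[0.3, 0.3, 0.2, 0.15, 0.05])
                rows[g] = "".join(chars)
            alns[f"c{c}"] = rows
        sm = phy.concat_and_mask(alns)
        mat = np.array([list("".join(alns[f"c{c}"][g] for c in range(3)))
                        for g in genomes])
        survivors = 0
        for j in range(mat.shape[1]):                # independent column scan
            col = mat[:, j]
            if "-" not in col and len(set(col)) > 1:
                survivors += 1
        assert sm.n_variable == survivors
        assert [p[0] for p in sm.partitions] == ["c0", "c1", "c2"]
        assert sm.partitions[-1][2] == sm.n_concatenated

    def test_missing_genome_row_names_cluster(self):
        alns = {"bad": {"g1": "AA"}, "good": {"g1": "AA", "g2": "AA"}}
        with pytest.raises(ValueError, match="bad|good"):
            phy.concat_and_mask(alns)


class TestDistanceTree:
    def test_three_taxa_additive(self):
        sm = phy.SuperMatrix(taxa=["a", "b", "c"],
                             rows={"a": "AAAA", "b": "AATT", "c": "TTTT"},
                             partitions=[("c1", 0, 4)], n_concatenated=4,
                             n_after_gap_mask=4, n_variable=4)
        tree = phy.distance_tree(sm)
        # three-point condition: path lengths equal pairwise p-distances
        dist = {}
        for x, y in itertools.combinations("abc", 2):
            dist[(x, y)] = _path_length(tree, x, y)
        assert dist[("a", "b")] == pytest.approx(0.5)
        assert dist[("a", "c")] == pytest.approx(1.0)
        assert dist[("b", "c")] == pytest.approx(0.5)

    def test_additive_quartet_recovers_true_split(self):
        rows = {"a": "AAAAAAAAAA", "b": "AAAAAAAATT", "c": "TTTTTTTTAA",
                "d": "TTTTTTTTTT"}
        sm = phy.SuperMatrix(taxa=list("abcd"), rows=rows,
                             partitions=[("c1", 0, 10)], n_concatenated=10,
                             n_after_gap_mask=10, n_variable=10)
        tree = phy.distance_tree(sm)
        assert set(tree.bipartitions()) == {frozenset({"c", "d"})}

    def test_zero_distances_give_zero_branch_lengths(self):
        dm = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        tree = phy.neighbor_joining(dm)
        for node in tree.postorder():
            if node is not tree.root and node.length is not None:
                assert node.length == pytest.approx(0.0)


class TestCompareTrees:
    def test_identical_trees(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert phy.compare_trees(t, t) == (0, 0.0)

    def test_uniform_rescaling_scores_zero(self):
        t1 = Tree.from_newick("((A:1,B:2):0.5,(C:1,D:3):0.5);")
        t2 = Tree.from_newick("((A:2,B:4):1,(C:2,D:6):1);")
        rf, k = phy.compare_trees(t1, t2)
        assert rf == 0
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_nni_neighbours_rf_two_and_grid_oracle_k(self):
        t1 = Tree.from_newick("(((A:1,B:1):1,C:2):1,(D:1,E:1):1);")
        t2 = Tree.from_newick("(((A:1,C:1):1,B:2):1,(D:1,E:1):1);")
        rf, k = phy.compare_trees(t1, t2)
        assert rf == 2
        assert k == pytest.approx(grid_k_score(t1, t2), abs=1e-4)

    def test_rf_is_a_metric_on_fixtures(self):
        trees = [phy.compare_trees] and [
            Tree.from_newick("(((A,B),C),(D,E));"),
            Tree.from_newick("(((A,C),B),(D,E));"),
            Tree.from_newick("(((A,D),C),(B,E));"),
        ]
        for t in trees:
            assert phy.compare_trees(t, t)[0] == 0
        for t1, t2 in itertools.permutations(trees, 2):
            assert phy.compare_trees(t1, t2)[0] == phy.compare_trees(t2, t1)[0]
        for t1, t2, t3 in itertools.permutations(trees, 3):
            assert phy.compare_trees(t1, t3)[0] <= \
                phy.compare_trees(t1, t2)[0] + phy.compare_trees(t2, t3)[0]

    def test_leaf_set_mismatch_rejected(self):
        t1 = Tree.from_newick("((A,B),C);")
        t2 = Tree.from_newick("((A,B),D);")
        with pytest.raises(ValueError, match="leaf sets"):
            phy.compare_trees(t1, t2)


def _path_length(tree, a, b):
    def ancestors(label):
        node = tree.find(label)
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    pa, pb = ancestors(a), ancestors(b)
    ids_b = {id(n): i for i, n in enumerate(pb)}
    for i, n in enumerate(pa):
        if id(n) in ids_b:
            up = sum(x.length or 0 for x in pa[:i])
            down = sum(x.length or 0 for x in pb[:ids_b[id(n)]])
            return up + down
    raise AssertionError("no common ancestor")
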