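import numpy as np
import pytest

from auxfam import phylogeny as ph
from auxfam import synthetic_data as sd
from auxfam.io_core import IoError, SequenceSet


def _aln(*pairs):
    return SequenceSet(list(pairs), alphabet="aligned-protein")


class TestPDistance:
    def test_identical_sequences(self):
        dm = ph.p_distance(_aln(("a", "MKVL"), ("b", "MKVL")))
        assert dm.matrix[0, 1] == 0

    def test_one_mismatch_in_four(self):
        dm = ph.p_distance(_aln(("a", "MKVL"), ("b", "MKVA")))
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_of_gaps(self):
        dm = ph.p_distance(_aln(("a", "MK-L"), ("b", "MAVL")))
        # column 3 skipped: 1 mismatch over 3 comparable columns
        assert dm.matrix[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns_names_pair(self):
        with pytest.raises(IoError, match=r"\(a, b\)"):
            ph.p_distance(_aln(("a", "MK--"), ("b", "--VL")))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(IoError, match="equal length"):
            ph.p_distance(_aln(("a", "MKV"), ("b", "MKVL")))

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(41)
        aas = np.array(list("ACDEF-"))
        seqs = ["".join(aas[rng.integers(0, 6, 40)]) for _ in range(4)]
        dm = ph.p_distance(_aln(*[(f"s{i}", s) for i, s in enumerate(seqs)]))
        for i in range(4):
            for j in range(i + 1, 4):
                comp = mism = 0
                for x, y in zip(seqs[i], seqs[j]):
                    if x != "-" and y != "-":
                        comp += 1
                        mism += x != y
                assert dm.matrix[i, j] == pytest.approx(mism / comp)


class TestNjTree:
    def test_three_taxon_closed_form(self):
        dm = ph.DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        tree = ph.nj_tree(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        dm = ph.DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(IoError):
            ph.nj_tree(dm)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_recovers_planted_additive_trees(self, n):
        for seed in range(5):
            dm, planted = sd.random_additive_matrix(n, seed=seed + 10 * n)
            tree = ph.nj_tree(dm)
            assert ph.bipartitions(tree) == planted
            assert np.allclose(
                ph.patristic_matrix(tree, dm.ids), dm.matrix, atol=1e-9
            )

    def test_four_taxon_least_squares_oracle(self):
        # NJ's choice beats every alternative unrooted quartet topology
        # under least squares against the input distances
        rng = np.random.default_rng(5)
        dm, _ = sd.random_additive_matrix(4, seed=77)
        noisy = dm.matrix + rng.uniform(0, 0.01, size=(4, 4))
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        dmn = ph.DistanceMatrix(dm.ids, noisy)
        tree = ph.nj_tree(dmn)
        got = ph.bipartitions(tree)

        def quartet_rss(split):
            # fit all 5 branch lengths by least squares for topology
            # AB|CD parameterised by the split
            (a, b), (c, d) = split
            idx = {t: i for i, t in enumerate(dm.ids)}
            rows, y = [], []
            # path indicator matrix: columns ea, eb, ec, ed, em
            paths = {
                (a, b): [1, 1, 0, 0, 0],
                (a, c): [1, 0, 1, 0, 1],
                (a, d): [1, 0, 0, 1, 1],
                (b, c): [0, 1, 1, 0, 1],
                (b, d): [0, 1, 0, 1, 1],
                (c, d): [0, 0, 1, 1, 0],
            }
            for (x, z), row in paths.items():
                rows.append(row)
                y.append(noisy[idx[x], idx[z]])
            coef, rss, *_ = np.linalg.lstsq(
                np.array(rows, float), np.array(y), rcond=None
            )
            fit = np.array(rows) @ coef
            return float(((fit - np.array(y)) ** 2).sum())

        a, b, c, d = dm.ids
        splits = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
        best = min(splits, key=quartet_rss)
        want = frozenset(
            {frozenset(best[0]), frozenset(best[1])}
        )
        assert want in got

    def test_agrees_with_scikit_bio(self):
        # independent NJ implementation as a cross-check
        import io

        import dendropy
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        dm, _ = sd.random_additive_matrix(7, seed=99)
        noise = np.random.default_rng(1).uniform(0, 0.05, size=dm.matrix.shape)
        noisy = dm.matrix + (noise + noise.T) / 2
        np.fill_diagonal(noisy, 0)
        ours = ph.nj_tree(ph.DistanceMatrix(dm.ids, noisy))
        theirs_nwk = skbio_nj(SkbioDM(noisy, ids=dm.ids)).write(io.StringIO())
        theirs = dendropy.Tree.get(
            data=theirs_nwk.getvalue(), schema="newick",
            taxon_namespace=ours.taxon_namespace,
        )
        assert ph.bipartitions(ours) == ph.bipartitions(theirs)


class TestBootstrap:
    def test_identical_pair_gets_full_support(self):
        aln, truth = sd.generate_alignment(
            n_taxa=8, n_pairs=1, seed=3, pair_mutations=0
        )
        tree = ph.bootstrap_supports(aln, n_reps=30, seed=4)
        pairs = {p.taxa for p in ph.sister_pairs(tree, threshold=99)}
        assert tuple(truth.planted_pairs[0]) in pairs
        support = [
            p.support for p in ph.sister_pairs(tree, threshold=0)
            if p.taxa == tuple(truth.planted_pairs[0])
        ]
        assert support[0] == 100.0

    def test_single_replicate_supports_are_binary(self):
        aln, _ = sd.generate_alignment(n_taxa=6, n_pairs=1, seed=5)
        tree = ph.bootstrap_supports(aln, n_reps=1, seed=6)
        sups = {
            node.support
            for node in tree.preorder_node_iter()
            if hasattr(node, "support")
        }
        assert sups <= {0.0, 100.0}

    def test_same_seed_same_supports(self):
        aln, _ = sd.generate_alignment(n_taxa=7, n_pairs=2, seed=7)
        t1 = ph.bootstrap_supports(aln, n_reps=20, seed=8)
        t2 = ph.bootstrap_supports(aln, n_reps=20, seed=8)

        def sups(t):
            return sorted(
                n.support for n in t.preorder_node_iter()
                if hasattr(n, "support")
            )

        assert sups(t1) == sups(t2)

    def test_supports_invariant_to_leaf_order(self):
        aln, _ = sd.generate_alignment(n_taxa=7, n_pairs=2, seed=9)
        shuffled = SequenceSet(
            list(reversed(aln.records)), alphabet=aln.alphabet
        )
        t1 = ph.bootstrap_supports(aln, n_reps=25, seed=10)
        t2 = ph.bootstrap_supports(shuffled, n_reps=25, seed=10)

        def by_bip(t):
            all_leaves = frozenset(x.taxon.label for x in t.leaf_node_iter())
            out = {}
            for n in t.preorder_node_iter():
                if hasattr(n, "support"):
                    clade = frozenset(
                        x.taxon.label for x in n.leaf_iter()
                    )
                    out[frozenset({clade, all_leaves - clade})] = n.support
            return out

        b1, b2 = by_bip(t1), by_bip(t2)
        for bip in set(b1) & set(b2):
            assert b1[bip] == pytest.approx(b2[bip])


class TestSisterPairs:
    def test_planted_pairs_recovered(self):
        aln, truth = sd.generate_alignment(seed=11)
        tree = ph.bootstrap_supports(aln, n_reps=100, seed=12)
        got = {p.taxa for p in ph.sister_pairs(tree, threshold=99)}
        assert got == {tuple(p) for p in truth.planted_pairs}

    def test_threshold_100_always_empty(self):
        aln, _ = sd.generate_alignment(n_taxa=8, n_pairs=2, seed=13,
                                       pair_mutations=0)
        tree = ph.bootstrap_supports(aln, n_reps=20, seed=14)
        assert ph.sister_pairs(tree, threshold=100) == []

    def test_star_like_data_yields_nothing(self):
        # all-random taxa: no cherry should clear the 99% bar
        aln, _ = sd.generate_alignment(n_taxa=10, n_pairs=0, seed=15)
        tree = ph.bootstrap_supports(aln, n_reps=50, seed=16)
        assert ph.sister_pairs(tree, threshold=99) == []

    def test_pairs_are_subset_of_cherries(self):
        aln, _ = sd.generate_alignment(seed=17)
        tree = ph.bootstrap_supports(aln, n_reps=30, seed=18)
        cherry_pairs = {pair for pair, _ in ph.cherries(tree)}
        for p in ph.sister_pairs(tree, threshold=0):
            assert p.taxa in cherry_pairs
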