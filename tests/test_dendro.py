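import numpy as np
import pytest

from virsig.dendro import (
    NewickError,
    Node,
    bootstrap_trees,
    clade_support,
    cophenetic_correlation,
    cophenetic_matrix,
    pruned_rebootstrap,
    prune_table,
    read_newick,
    resample_table,
    upgma,
    write_newick,
)
from virsig.similarity import DistanceMatrix, pairwise_distance_matrix
from virsig.simulate import TableConfig, simulate_signature_table


def dm(labels, values):
    return DistanceMatrix(list(labels), np.asarray(values, dtype=float))


class TestUPGMA:
    def test_two_taxa(self):
        tree = upgma(dm("AB", [[0, 0.6], [0.6, 0]]))
        assert tree.height == pytest.approx(0.3)
        assert sorted(tree.leaves()) == ["A", "B"]

    def test_hand_computed_three_taxa(self):
        tree = upgma(dm("ABC", [[0, 2, 8], [2, 0, 8], [8, 8, 0]]))
        clades = tree.clades()
        assert frozenset({"A", "B"}) in clades
        assert clades[frozenset({"A", "B"})].height == pytest.approx(1.0)
        assert tree.height == pytest.approx(4.0)

    def test_size_weighted_linkage(self):
        # after merging (A,B), d((AB),C) = (d(A,C)+d(B,C))/2 = 5; then
        # d((ABC),D) = (2*... size-weighted) -> hand value 8.667/2
        values = [
            [0, 2, 4, 10],
            [2, 0, 6, 8],
            [4, 6, 0, 8],
            [10, 8, 8, 0],
        ]
        tree = upgma(dm("ABCD", values))
        clades = tree.clades()
        ab = clades[frozenset({"A", "B"})]
        assert ab.height == pytest.approx(1.0)
        abc = clades[frozenset({"A", "B", "C"})]
        assert abc.height == pytest.approx(0.5 * (4 + 6) / 2)
        assert tree.height == pytest.approx(0.5 * (10 + 8 + 8) / 3)

    def test_ultrametric_input_reproduced_exactly(self):
        # build a random tree, take its cophenetic matrix, re-cluster
        rng = np.random.default_rng(5)
        base = simulate_signature_table(TableConfig(n_families=3, genomes_per_family=3,
                                                    score_noise_sd=5.0, seed=8))[0]
        original = upgma(pairwise_distance_matrix(base))
        coph = cophenetic_matrix(original, sorted(original.leaves()))
        rebuilt = upgma(coph)
        coph2 = cophenetic_matrix(rebuilt, coph.labels)
        np.testing.assert_allclose(coph2.values, coph.values, atol=1e-12)

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(9)
        for _ in range(5):
            n = 8
            M = rng.uniform(0.1, 1.0, size=(n, n))
            M = 0.5 * (M + M.T)
            np.fill_diagonal(M, 0)
            labels = [f"t{i}" for i in range(n)]
            tree = upgma(dm(labels, M))
            ours = cophenetic_matrix(tree, labels).values
            Z = linkage(squareform(M), method="average")
            theirs = squareform(cophenet(Z))
            np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_heights_monotone_rootward(self, small_annotation):
        table, _ = small_annotation
        tree = upgma(pairwise_distance_matrix(table))

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(tree)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["A", "B"], np.array([[0.0, 0.2], [0.3, 0.0]])))


class TestCopheneticCorrelation:
    def test_ultrametric_gives_one(self):
        tree = upgma(dm("ABC", [[0, 2, 8], [2, 0, 8], [8, 8, 0]]))
        assert cophenetic_correlation(tree, dm("ABC", [[0, 2, 8], [2, 0, 8], [8, 8, 0]])) \
            == pytest.approx(1.0)

    def test_noise_ladder_decreases(self):
        rng = np.random.default_rng(11)
        n = 10
        base = np.zeros((n, n))
        # two tight blocks far apart: strongly ultrametric-ish
        for i in range(n):
            for j in range(n):
                if i != j:
                    base[i, j] = 0.1 if (i < 5) == (j < 5) else 0.9
        labels = [f"t{i}" for i in range(n)]
        rhos = []
        for noise in (0.0, 0.1, 0.3):
            delta = rng.uniform(-noise, noise, size=(n, n))
            delta = 0.5 * (delta + delta.T)
            M = np.clip(base + delta, 0.01, 1.0)
            np.fill_diagonal(M, 0)
            tree = upgma(dm(labels, M))
            rhos.append(cophenetic_correlation(tree, dm(labels, M)))
        assert rhos[0] == pytest.approx(1.0, abs=1e-9)
        assert rhos[0] > rhos[1] > rhos[2]

    def test_against_direct_pearson_oracle(self, small_annotation):
        from scipy.stats import pearsonr

        table, _ = small_annotation
        matrix = pairwise_distance_matrix(table)
        tree = upgma(matrix)
        C = cophenetic_matrix(tree, matrix.labels)
        iu = np.triu_indices(len(matrix), k=1)
        expected = pearsonr(C.values[iu], matrix.values[iu]).statistic
        assert cophenetic_correlation(tree, matrix) == pytest.approx(expected, abs=1e-12)

    def test_too_few_taxa(self):
        tree = upgma(dm("AB", [[0, 1], [1, 0]]))
        with pytest.raises(ValueError):
            cophenetic_correlation(tree, dm("AB", [[0, 1], [1, 0]]))


@pytest.fixture(scope="module")
def block_table():
    return simulate_signature_table(
        TableConfig(n_families=4, genomes_per_family=4, profiles_per_family=5,
                    score_noise_sd=8.0, location_jitter_sd=30.0, seed=21)
    )[0]


def single_profile_table():
    """Two families scored against a database holding a single profile."""
    from virsig.annotation import SignatureTable
    from virsig.genome_io import Taxonomy

    accs = [f"{f}_v{i}" for f in ("FamA", "FamB") for i in range(3)]
    fams = ["FamA"] * 3 + ["FamB"] * 3
    pphmm = np.array([[50.0], [52.0], [51.0], [20.0], [21.0], [22.0]])
    locations = np.array([[500.0]] * 3 + [[900.0]] * 3)
    return SignatureTable(
        accs, [Taxonomy(family=f) for f in fams], pphmm, locations,
        np.zeros((6, 2)), ["P0"], ["FamA", "FamB"],
    )


class TestBootstrap:
    def test_single_profile_database_identity(self):
        table = single_profile_table()
        best = upgma(pairwise_distance_matrix(table))
        reps = bootstrap_trees(table, n_reps=10, seed=0)
        assert [write_newick(t) for t in reps] == [write_newick(best)] * 10
        support = clade_support(best, reps)
        assert support and all(v == 100.0 for v in support.values())

    def test_seed_reproducibility(self, block_table):
        t1 = bootstrap_trees(block_table, n_reps=5, seed=4)
        t2 = bootstrap_trees(block_table, n_reps=5, seed=4)
        assert [write_newick(t) for t in t1] == [write_newick(t) for t in t2]

    def test_planted_families_supported(self, block_table):
        best = upgma(pairwise_distance_matrix(block_table))
        reps = bootstrap_trees(block_table, n_reps=100, seed=1)
        support = clade_support(best, reps)
        fams = {}
        for acc in block_table.accessions:
            fams.setdefault(acc.rsplit("_", 1)[0], set()).add(acc)
        for fam, members in fams.items():
            clade = frozenset(members)
            assert clade in support, fam
            assert support[clade] >= 70.0

    def test_support_counting(self):
        best = upgma(dm("ABCD", [[0, .1, .8, .9], [.1, 0, .8, .9],
                                 [.8, .8, 0, .5], [.9, .9, .5, 0]]))
        other = upgma(dm("ABCD", [[0, .9, .8, .1], [.9, 0, .5, .9],
                                  [.8, .5, 0, .8], [.1, .9, .8, 0]]))
        reps = [best, best, other, other]
        support = clade_support(best, reps)
        assert support[frozenset({"A", "B"})] == 50.0
        # invariant to replicate order
        assert clade_support(best, list(reversed(reps))) == support

    def test_leafset_mismatch_rejected(self):
        a = upgma(dm("AB", [[0, 1], [1, 0]]))
        b = upgma(dm("AC", [[0, 1], [1, 0]]))
        with pytest.raises(ValueError):
            clade_support(a, [b])


class TestPrunedRebootstrap:
    def test_dropped_columns_equal_all_zero_columns(self, block_table):
        clade = [a for a in block_table.accessions if a.startswith("Fam00")]
        pruned = prune_table(block_table, clade)
        sub = block_table.subset([block_table.index_of(a) for a in clade])
        expected_dropped = int((sub.pphmm == 0).all(axis=0).sum())
        assert len(block_table.profile_ids) - len(pruned.profile_ids) == expected_dropped
        assert pruned.gom_labels == ["Fam00"]

    def test_noop_pruning_matches_plain_bootstrap_of_subtable(self):
        table = simulate_signature_table(
            TableConfig(n_families=1, genomes_per_family=5, profiles_per_family=4,
                        score_noise_sd=10.0, location_jitter_sd=40.0, seed=6)
        )[0]
        clade = list(table.accessions)
        _, support_pruned = pruned_rebootstrap(table, clade, n_reps=20, seed=9)
        best = upgma(pairwise_distance_matrix(table))
        support_plain = clade_support(best, bootstrap_trees(table, n_reps=20, seed=9))
        assert support_pruned == support_plain

    def test_irrelevant_profiles_do_not_depress_support(self):
        # a family whose profiles are 10% of the columns: plain bootstrap can
        # draw mostly irrelevant columns; pruning removes them
        table = simulate_signature_table(
            TableConfig(n_families=10, genomes_per_family=3, profiles_per_family=2,
                        score_noise_sd=12.0, location_jitter_sd=50.0, seed=13)
        )[0]
        clade = [a for a in table.accessions if a.startswith("Fam00")]
        _, sup_pruned = pruned_rebootstrap(table, clade, n_reps=50, seed=2)
        sub = table.subset([table.index_of(a) for a in clade])
        best = upgma(pairwise_distance_matrix(sub))
        sup_plain = clade_support(best, bootstrap_trees(sub, n_reps=50, seed=2))
        mean_pruned = np.mean(list(sup_pruned.values()))
        mean_plain = np.mean(list(sup_plain.values()))
        assert mean_pruned >= mean_plain


class TestNewick:
    def test_write_read_write_byte_identical(self, block_table):
        tree = upgma(pairwise_distance_matrix(block_table))
        text = write_newick(tree)
        again = write_newick(read_newick(text))
        assert again == text

    def test_two_leaf_serialisation(self):
        tree = upgma(dm("AB", [[0, 0.6], [0.6, 0]]))
        assert write_newick(tree) == "(A:0.3,B:0.3);"

    def test_supports_survive_roundtrip(self):
        tree = upgma(dm("ABC", [[0, .2, .8], [.2, 0, .8], [.8, .8, 0]]))
        tree.clades()[frozenset({"A", "B"})].support = 87.5
        back = read_newick(write_newick(tree))
        assert back.clades()[frozenset({"A", "B"})].support == 87.5

    def test_heights_recovered(self):
        tree = upgma(dm("ABC", [[0, 2, 8], [2, 0, 8], [8, 8, 0]]))
        back = read_newick(write_newick(tree))
        assert back.height == pytest.approx(4.0)
        assert back.clades()[frozenset({"A", "B"})].height == pytest.approx(1.0)

    def test_malformed_input_reports_position(self):
        with pytest.raises(NewickError, match="position"):
            read_newick("(A:0.1,B:0.2")
        with pytest.raises(NewickError):
            read_newick("(A:xx,B:0.2);")


class TestResampleTable:
    def test_duplicate_columns_appear_multiply(self, block_table):
        idx = np.zeros(len(block_table.profile_ids), dtype=int)
        rep = resample_table(block_table, idx)
        assert (rep.pphmm == block_table.pphmm[:, [0]]).all()
        assert rep.profile_ids == [block_table.profile_ids[0]] * len(idx)
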