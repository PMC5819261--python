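import numpy as np
import pytest

from virsig.classify import (
    CandidateAssignment,
    ThresholdModel,
    UNCLASSIFIED,
    build_sub_pipeline,
    classify,
    cross_validate,
    fit_group_threshold,
    fit_thresholds,
    metagenomic_length_filter,
    nearest_neighbour,
    split_reference_test,
    threshold_check,
    topological_evaluate,
    update_database,
)
from virsig.dendro import Node
from virsig.genome_io import GenomeRecord, Taxonomy
from virsig.simulate import SimulationConfig, simulate_queries, simulate_reference_set


def leaf(name):
    return Node(name=name)


def join(*children, height=1.0):
    return Node(children=list(children), height=height)


class TestNearestNeighbour:
    def test_identical_query(self, small_annotation):
        from virsig.similarity import cgj_matrix

        table, _ = small_annotation
        S = cgj_matrix(table)
        cand = nearest_neighbour(table.accessions[0], S[0], table)
        assert cand.group == table.label(0)
        assert cand.cgj == pytest.approx(1.0)

    def test_tie_broken_by_smallest_accession(self, small_annotation):
        table, _ = small_annotation
        sims = np.zeros(len(table))  # everything ties at zero
        cand = nearest_neighbour("q", sims, table)
        assert cand.neighbour_id == min(table.accessions)
        assert cand.cgj == 0.0


class TestGroupThreshold:
    def test_separable_midpoint(self):
        model = fit_group_threshold([0.8, 0.9], [0.1, 0.2], group="F")
        assert model.threshold == pytest.approx(0.5, abs=1e-6)

    def test_overlapping_matches_weighted_error_of_exhaustive_scan(self, rng):
        intra = rng.normal(0.7, 0.08, size=60).clip(0, 1)
        inter = rng.normal(0.3, 0.08, size=200).clip(0, 1)
        model = fit_group_threshold(intra, inter, group="F")

        def weighted_error(cut):
            # balanced class weights: each class contributes its error rate
            return (intra < cut).mean() + (inter >= cut).mean()

        cuts = np.unique(np.concatenate([intra, inter]))
        best = min(weighted_error(c) for c in cuts)
        assert weighted_error(model.threshold) <= best + 0.02

    def test_sample_cap_applies(self, rng):
        intra = rng.uniform(0.6, 1.0, size=500)
        inter = rng.uniform(0.0, 0.4, size=500)
        model = fit_group_threshold(intra, inter, cap=100, seed=1, group="F")
        assert model.n_intra == 100 and model.n_inter == 100
        assert 0.4 <= model.threshold <= 0.6

    def test_degenerate_cases(self):
        with pytest.warns(RuntimeWarning):
            assert fit_group_threshold([0.5], [], group="F").threshold == 0.0
        # single-member group: most similar outsider sets the bar
        model = fit_group_threshold([], [0.2, 0.35], group="F")
        assert model.threshold == pytest.approx(0.35)
        with pytest.raises(ValueError):
            fit_group_threshold([], [], group="F")

    def test_threshold_check_boundary(self):
        model = ThresholdModel("F", 0.5, 10, 10)
        assert threshold_check(CandidateAssignment("q", "F", "r", 0.5), model)
        assert threshold_check(CandidateAssignment("q", "F", "r", 0.9), model)
        assert not threshold_check(CandidateAssignment("q", "F", "r", 0.3), model)

    def test_monotonicity(self):
        cand = CandidateAssignment("q", "F", "r", 0.6)
        passed = [threshold_check(cand, ThresholdModel("F", t, 1, 1))
                  for t in np.linspace(0, 1, 21)]
        # once rejected at some threshold, rejected for all higher ones
        assert passed == sorted(passed, reverse=True)


class TestTopologicalEvaluate:
    refs = {"R1": "f", "R2": "f", "R3": "h", "R1g": "g", "R2g": "g"}

    def test_sister_condition(self):
        tree = join(join(leaf("Q"), leaf("R1"), height=0.2), leaf("R2"), height=0.6)
        ok, cond = topological_evaluate(tree, "Q", "f", {"R1": "f", "R2": "f"})
        assert ok and cond == "sister"

    def test_outgroup_condition(self):
        tree = join(join(leaf("Q"), leaf("R1g"), height=0.2), leaf("R2"), height=0.6)
        ok, cond = topological_evaluate(tree, "Q", "f", {"R1g": "g", "R2": "f"})
        assert ok and cond == "outgroup"

    def test_sister_basal_condition(self):
        sister = join(join(leaf("R1"), leaf("R2"), height=0.1), leaf("R3"), height=0.3)
        tree = join(join(leaf("Q"), sister, height=0.5), leaf("R1g"), height=0.8)
        ok, cond = topological_evaluate(
            tree, "Q", "f", {"R1": "f", "R2": "f", "R3": "h", "R1g": "g"}
        )
        assert ok and cond == "sister-basal"

    def test_reject_when_no_condition_holds(self):
        tree = join(
            join(leaf("Q"), leaf("R1g"), height=0.2),
            join(leaf("R2g"), leaf("R3"), height=0.2),
            height=0.6,
        )
        ok, cond = topological_evaluate(
            tree, "Q", "f", {"R1g": "g", "R2g": "g", "R3": "h"}
        )
        assert not ok and cond == ""

    def test_other_queries_are_transparent(self):
        # Q's sister is another query; the family refs sit one level up
        tree = join(
            join(join(leaf("Q"), leaf("Q2"), height=0.1), leaf("R1"), height=0.3),
            leaf("R2"),
            height=0.6,
        )
        ok, cond = topological_evaluate(tree, "Q", "f", {"R1": "f", "R2": "f"})
        assert ok and cond == "sister"

    def test_missing_query_errors(self):
        tree = join(leaf("A"), leaf("B"))
        with pytest.raises(ValueError):
            topological_evaluate(tree, "Q", "f", {"A": "f", "B": "f"})


@pytest.fixture(scope="module")
def small_pipeline(small_ref):
    return build_sub_pipeline(small_ref.genomes, seed=0)


class TestClassify:
    def test_self_classification(self, small_ref, small_pipeline):
        results = classify(small_ref.genomes, [small_pipeline])
        for g, r in zip(small_ref.genomes, results):
            assert r.label == g.taxonomy.family
            assert r.cgj == pytest.approx(1.0)

    def test_known_queries_assigned(self, small_ref, small_pipeline):
        queries, truth = simulate_queries(small_ref, mode="known", n_queries=4, seed=5)
        results = classify(queries, [small_pipeline])
        expected = dict(zip(truth.accession, truth.family))
        for r in results:
            assert r.label == expected[r.query_id]

    def test_unknown_family_unclassified(self, small_ref, small_pipeline):
        queries, _ = simulate_queries(small_ref, mode="unknown", n_queries=3, seed=6)
        results = classify(queries, [small_pipeline])
        assert all(r.label == UNCLASSIFIED for r in results)
        assert all(r.cgj == 0.0 for r in results)

    def test_arbitration_prefers_higher_cgj(self, small_ref, small_pipeline):
        # a second, weaker pipeline built from a subset of the references
        weak = build_sub_pipeline(small_ref.genomes[:6], seed=0)
        weak.name = "II"
        queries, truth = simulate_queries(small_ref, mode="known", n_queries=3, seed=8)
        results = classify(queries, [weak, small_pipeline])
        expected = dict(zip(truth.accession, truth.family))
        for r in results:
            assert r.label == expected[r.query_id]
            assert "I" in r.trace

    def test_empty_queries(self, small_pipeline):
        assert classify([], [small_pipeline]) == []


class TestCrossValidation:
    def test_small_groups_all_in_test(self, rng):
        genomes = [
            GenomeRecord(f"a{i}", ["ACGT" * 30], taxonomy=Taxonomy(family="Big"))
            for i in range(6)
        ] + [
            GenomeRecord(f"b{i}", ["ACGT" * 30], taxonomy=Taxonomy(family="Tiny"))
            for i in range(2)
        ]
        refs, tests = split_reference_test(genomes, rng)
        assert all(g.taxonomy.family == "Big" for g in refs)
        assert sum(g.taxonomy.family == "Tiny" for g in tests) == 2
        assert len(refs) == round(0.67 * 6)

    def test_always_test_families_never_referenced(self, rng):
        genomes = [
            GenomeRecord(f"{f}{i}", ["ACGT" * 30], taxonomy=Taxonomy(family=f))
            for f in ("X", "Y") for i in range(5)
        ]
        refs, tests = split_reference_test(genomes, rng, always_test=["Y"])
        assert all(g.taxonomy.family != "Y" for g in refs)
        assert sum(g.taxonomy.family == "Y" for g in tests) == 5

    def test_metric_definitions(self):
        from virsig.classify import FoldMetrics

        m = FoldMetrics(0, n_known=10, n_known_correct=9,
                        n_unknown=5, n_unknown_unclassified=5)
        assert m.sensitivity == pytest.approx(90.0)
        assert m.specificity == pytest.approx(100.0)

    def test_end_to_end_on_tiny_set(self, small_ref):
        metrics = cross_validate(small_ref.genomes, seed=3, n_folds=1)
        (m,) = metrics
        assert m.n_known + m.n_unknown == 3  # one test genome per family
        assert m.sensitivity == pytest.approx(100.0)


class TestMetagenomicLengthFilter:
    def _refs(self):
        return [
            GenomeRecord("r1", ["A" * 1000], taxonomy=Taxonomy(family="F")),
            GenomeRecord("r2", ["A" * 1500], taxonomy=Taxonomy(family="F")),
        ]

    def test_shorter_than_group_minimum_excluded(self):
        q = GenomeRecord("q1", ["A" * 900])
        assert metagenomic_length_filter([q], {"q1": "F"}, self._refs()) == []

    def test_exact_minimum_retained(self):
        q = GenomeRecord("q1", ["A" * 1000])
        assert metagenomic_length_filter([q], {"q1": "F"}, self._refs()) == [q]

    def test_unknown_group_retained_with_warning(self):
        q = GenomeRecord("q1", ["A" * 10])
        with pytest.warns(RuntimeWarning):
            kept = metagenomic_length_filter([q], {"q1": "Ghost"}, self._refs())
        assert kept == [q]


class TestUpdateDatabase:
    def test_zero_new_genomes_identical(self, small_ref, small_db):
        updated = update_database(small_ref.genomes, [])
        assert updated.profile_ids == small_db.profile_ids
        assert [p.member_ids for p in updated.profiles] == \
               [p.member_ids for p in small_db.profiles]

    def test_novel_family_adds_profiles(self, small_ref, small_db):
        novel_cfg = SimulationConfig(n_families=1, genomes_per_family=2,
                                     genes_per_genome=3, seed=321)
        novel = simulate_reference_set(novel_cfg)
        for g in novel.genomes:
            g.accession = "NOV_" + g.accession
            g.taxonomy = Taxonomy(baltimore_group="I", family="Novel00")
        updated = update_database(small_ref.genomes, novel.genomes)
        assert len(updated) >= len(small_db) + novel_cfg.genes_per_genome

    def test_original_signatures_survive_update(self, small_ref, small_db):
        from virsig.annotation import annotate_references

        novel_cfg = SimulationConfig(n_families=1, genomes_per_family=2,
                                     genes_per_genome=3, seed=321)
        novel = simulate_reference_set(novel_cfg)
        for g in novel.genomes:
            g.accession = "NOV_" + g.accession
            g.taxonomy = Taxonomy(baltimore_group="I", family="Novel00")
        updated = update_database(small_ref.genomes, novel.genomes)
        table, _ = annotate_references(small_ref.genomes, updated)
        genes = small_ref.config.genes_per_genome
        assert ((table.pphmm > 0).sum(axis=1) >= genes).all()
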