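"""Information content, MICA similarity, set scores, permutation test."""

import itertools
import math

import numpy as np
import pytest

from denovotest.phenosim import (
    ICTable,
    Ontology,
    OntologyError,
    PhenotypeSimilarityModel,
    ProbandAnnotations,
    ic,
    pair_similarity,
    permutation_p,
    propagate_usage,
    set_score,
)
from denovotest.simulate import OntologySimConfig, gen_ontology_and_annotations


class TestOntology:
    def test_cycle_rejected(self):
        with pytest.raises(OntologyError, match="cycle"):
            Ontology.from_edges([("A", "B"), ("B", "A")])

    def test_multiple_roots_rejected(self):
        with pytest.raises(OntologyError, match="root"):
            Ontology.from_edges([("A", "R1"), ("B", "R2")])

    def test_ancestors_include_self_and_both_diamond_paths(self, diamond_ontology):
        anc = diamond_ontology.ancestors("L")
        assert anc == {"L", "C", "E", "A", "B", "root"}


class TestPropagateUsage:
    def test_parent_count_dominates_child(self, diamond_ontology, small_cohort):
        counts = propagate_usage(diamond_ontology, small_cohort)
        for child, parent in diamond_ontology.edges():
            assert counts[parent] >= counts[child]

    def test_siblings_count_parent_once(self, diamond_ontology):
        ann = ProbandAnnotations(
            annotations={"x": {"C", "D"}, "y": {"B"}}, ontology=diamond_ontology
        )
        counts = propagate_usage(diamond_ontology, ann)
        assert counts["A"] == 1  # proband x counted once despite two children

    def test_diamond_counts_match_bruteforce_closure(self, diamond_ontology,
                                                     small_cohort):
        counts = propagate_usage(diamond_ontology, small_cohort)
        for term in diamond_ontology.terms:
            brute = sum(
                any(term in diamond_ontology.ancestors(t)
                    for t in small_cohort.terms_of(pid))
                for pid in small_cohort.proband_ids
            )
            assert counts[term] == brute

    def test_root_counts_every_annotated_proband(self, diamond_ontology,
                                                 small_cohort):
        counts = propagate_usage(diamond_ontology, small_cohort)
        assert counts["root"] == small_cohort.n_probands


class TestIC:
    def test_full_usage_gives_zero(self):
        assert ic("t", {"t": 100}, 100) == pytest.approx(0.0)

    def test_examples(self):
        assert ic("t", {"t": 5}, 100) == pytest.approx(math.log(20), abs=1e-12)
        assert ic("t", {"t": 1}, 100) == pytest.approx(math.log(100), abs=1e-12)

    def test_zero_usage_is_an_error(self):
        with pytest.raises(ValueError, match="zero usage"):
            ic("t", {"t": 0}, 100)

    def test_count_above_cohort_rejected(self):
        with pytest.raises(ValueError):
            ic("t", {"t": 101}, 100)

    def test_anti_monotonicity_on_random_ontologies(self):
        for seed in range(10):
            onto, ann, _ = gen_ontology_and_annotations(
                OntologySimConfig(depth=3, branching=2, n_probands=30,
                                  terms_per_proband=2, seed=seed)
            )
            counts = propagate_usage(onto, ann)
            for child, parent in onto.edges():
                if counts[child] > 0:
                    assert ic(parent, counts, 30) <= ic(child, counts, 30) + 1e-12


class TestPairSimilarity:
    def test_identical_single_term_scores_own_ic(self, diamond_ontology,
                                                 small_cohort):
        table = ICTable.from_annotations(diamond_ontology, small_cohort)
        assert pair_similarity({"L"}, {"L"}, table) == pytest.approx(
            table.ic("L")
        )

    def test_disjoint_branches_meet_at_root_for_zero(self, diamond_ontology,
                                                     small_cohort):
        table = ICTable.from_annotations(diamond_ontology, small_cohort)
        # D (under A) and E (under B) share only the root, used by everyone
        assert pair_similarity({"D"}, {"E"}, table) == pytest.approx(0.0)

    def test_matches_bruteforce_over_triples(self, diamond_ontology, small_cohort):
        table = ICTable.from_annotations(diamond_ontology, small_cohort)
        counts = propagate_usage(diamond_ontology, small_cohort)
        N = small_cohort.n_probands
        for pa, pb in itertools.combinations(small_cohort.proband_ids, 2):
            ta, tb = small_cohort.terms_of(pa), small_cohort.terms_of(pb)
            brute = max(
                max(
                    (ic(c, counts, N)
                     for c in diamond_ontology.ancestors(a)
                     & diamond_ontology.ancestors(b)
                     if counts[c] > 0),
                    default=0.0,
                )
                for a in ta
                for b in tb
            )
            assert pair_similarity(ta, tb, table) == pytest.approx(brute, abs=1e-12)

    def test_symmetry(self, diamond_ontology, small_cohort):
        table = ICTable.from_annotations(diamond_ontology, small_cohort)
        for pa, pb in itertools.combinations(small_cohort.proband_ids, 2):
            ta, tb = small_cohort.terms_of(pa), small_cohort.terms_of(pb)
            assert pair_similarity(ta, tb, table) == pair_similarity(tb, ta, table)


class TestSetScore:
    def test_two_probands_equals_pair_similarity(self, diamond_ontology,
                                                 small_cohort):
        table = ICTable.from_annotations(diamond_ontology, small_cohort)
        assert set_score(["p1", "p2"], small_cohort, table) == pytest.approx(
            pair_similarity(small_cohort.terms_of("p1"),
                            small_cohort.terms_of("p2"), table)
        )

    def test_identical_trio_scores_three_times_ic(self, diamond_ontology):
        ann = ProbandAnnotations(
            annotations={"a": {"L"}, "b": {"L"}, "c": {"L"}, "d": {"B"}},
            ontology=diamond_ontology,
        )
        table = ICTable.from_annotations(diamond_ontology, ann)
        assert set_score(["a", "b", "c"], ann, table) == pytest.approx(
            3 * table.ic("L")
        )

    def test_matches_bruteforce_double_loop(self, diamond_ontology, small_cohort):
        table = ICTable.from_annotations(diamond_ontology, small_cohort)
        ids = list(small_cohort.proband_ids)[:5]
        brute = sum(
            pair_similarity(small_cohort.terms_of(a), small_cohort.terms_of(b), table)
            for a, b in itertools.combinations(ids, 2)
        )
        assert set_score(ids, small_cohort, table) == pytest.approx(brute)

    def test_order_invariance_and_incremental_growth(self, diamond_ontology,
                                                     small_cohort):
        table = ICTable.from_annotations(diamond_ontology, small_cohort)
        ids = ["p1", "p3", "p5"]
        assert set_score(ids, small_cohort, table) == pytest.approx(
            set_score(list(reversed(ids)), small_cohort, table)
        )
        grown = set_score(ids + ["p6"], small_cohort, table)
        added = sum(
            pair_similarity(small_cohort.terms_of(i), small_cohort.terms_of("p6"),
                            table)
            for i in ids
        )
        assert grown == pytest.approx(set_score(ids, small_cohort, table) + added)

    def test_fewer_than_two_rejected(self, diamond_ontology, small_cohort):
        table = ICTable.from_annotations(diamond_ontology, small_cohort)
        with pytest.raises(ValueError):
            set_score(["p1"], small_cohort, table)


class TestModelFastPath:
    """The vectorised model must agree exactly with the scalar functions."""

    def test_pair_and_set_scores_agree(self, diamond_ontology, small_cohort):
        model = PhenotypeSimilarityModel(diamond_ontology, small_cohort)
        for pa, pb in itertools.combinations(small_cohort.proband_ids, 2):
            assert model.pair_similarity(pa, pb) == pytest.approx(
                pair_similarity(small_cohort.terms_of(pa),
                                small_cohort.terms_of(pb), model.ic_table)
            )
        ids = list(small_cohort.proband_ids)[:4]
        res = model.fit(ids, n_samples=10, seed=0)
        assert res.observed_score == pytest.approx(model.set_score(ids))

    def test_vectorised_agreement_on_random_ontology(self):
        onto, ann, _ = gen_ontology_and_annotations(
            OntologySimConfig(depth=3, branching=2, n_probands=25,
                              terms_per_proband=3, extra_diamond_edges=4, seed=5)
        )
        model = PhenotypeSimilarityModel(onto, ann)
        ids = list(ann.proband_ids)
        for pa, pb in itertools.combinations(ids[:8], 2):
            assert model.pair_similarity(pa, pb) == pytest.approx(
                pair_similarity(ann.terms_of(pa), ann.terms_of(pb), model.ic_table),
                abs=1e-12,
            )


class TestPermutation:
    def test_zero_observed_score_gives_p_one(self, diamond_ontology, small_cohort):
        table = ICTable.from_annotations(diamond_ontology, small_cohort)
        p = permutation_p(0.0, 2, small_cohort, table, n_samples=200, seed=1)
        assert p == 1.0

    def test_seed_reproducibility(self, diamond_ontology, small_cohort):
        model = PhenotypeSimilarityModel(diamond_ontology, small_cohort)
        r1 = model.fit(["p1", "p2", "p3"], n_samples=1000, seed=11)
        r2 = model.fit(["p1", "p2", "p3"], n_samples=1000, seed=11)
        assert r1.p_value == r2.p_value

    def test_query_larger_than_cohort_rejected(self, diamond_ontology,
                                               small_cohort):
        model = PhenotypeSimilarityModel(diamond_ontology, small_cohort)
        with pytest.raises(ValueError):
            model.fit([f"p{i}" for i in range(1, 8)], n_samples=10, seed=0)

    def test_model_matches_loop_reference_on_enumerable_cohort(
        self, diamond_ontology, small_cohort
    ):
        """Both permutation paths converge to the exact enumeration p."""
        model = PhenotypeSimilarityModel(diamond_ontology, small_cohort)
        ids = ["p1", "p2", "p4"]
        observed = model.set_score(ids)
        exact = np.mean(
            [
                model.set_score(list(combo)) >= observed - 1e-12
                for combo in itertools.combinations(small_cohort.proband_ids, 3)
            ]
        )
        n_samples = 4000
        se = math.sqrt(exact * (1 - exact) / n_samples)
        res = model.fit(ids, n_samples=n_samples, seed=3)
        p_loop = permutation_p(observed, 3, small_cohort, model.ic_table,
                               n_samples=2000, seed=4)
        assert abs(res.p_value - exact) <= 3 * se
        assert abs(p_loop - exact) <= 3 * math.sqrt(exact * (1 - exact) / 2000)


class TestSyndromeDetection:
    def test_shared_rare_term_yields_small_p(self):
        """Cohorts of 1,000 with a 5-proband set sharing a rare term (usage
        5/1,000): permutation p < 0.01 in >= 95% of replicates, while a random
        background set gives roughly uniform p."""
        n_rep = 100
        hits = 0
        random_ps = []
        for seed in range(n_rep):
            onto, ann, info = gen_ontology_and_annotations(
                OntologySimConfig(depth=3, branching=3, n_probands=1000,
                                  terms_per_proband=3, syndrome_size=5,
                                  seed=seed)
            )
            model = PhenotypeSimilarityModel(onto, ann)
            res = model.fit(info["syndrome_probands"], n_samples=10_000,
                            seed=seed + 1)
            hits += res.p_value < 0.01
            rng = np.random.default_rng(seed + 2)
            random_ids = [f"P{i:05d}" for i in
                          rng.choice(np.arange(500, 1000), size=5, replace=False)]
            random_ps.append(
                model.fit(random_ids, n_samples=2000, seed=seed + 3).p_value
            )
        assert hits / n_rep >= 0.95
        assert 0.38 <= float(np.mean(random_ps)) <= 0.62
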