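"""Information content and Resnik / best-match-average similarity."""

import math
import random

import pytest

from phenodrug.annotations import GenePhenotypeAnnotations
from phenodrug.errors import UndefinedMetricError, ValidationError
from phenodrug.profiles import PhenotypeProfile
from phenodrug.similarity import (
    TermSimilarityCache,
    compute_ic,
    directed_similarity,
    profile_similarity,
    term_similarity,
)

from conftest import make_ontology, parents_of, random_dag, random_gene_terms
from oracles import brute_directed_sim, brute_ic, brute_profile_sim, brute_term_sim


def annotations_from(direct, ontology):
    return GenePhenotypeAnnotations.from_direct(direct, ontology)


@pytest.fixture
def five_term_corpus():
    """R <- {A, B}; A <- {A1, A2}; 4 genes annotated at the leaves."""
    ont = make_ontology({"A": {"R"}, "B": {"R"}, "A1": {"A"}, "A2": {"A"}})
    direct = {"g1": {"A1"}, "g2": {"A1"}, "g3": {"A2"}, "g4": {"B"}}
    return ont, annotations_from(direct, ont)


class TestComputeIC:
    def test_root_has_zero_ic(self, five_term_corpus):
        ont, ann = five_term_corpus
        table = compute_ic(ont, ann)
        assert table.frequency["R"] == 4
        assert table.ic["R"] == 0.0

    def test_hand_counted_fixture(self, five_term_corpus):
        # closure: A in propagated sets of g1, g2, g3 -> p = 3/4
        # A1 in g1, g2 -> p = 2/4
        ont, ann = five_term_corpus
        table = compute_ic(ont, ann)
        assert table.ic["A"] == pytest.approx(-math.log(0.75))
        assert table.ic["A1"] == pytest.approx(-math.log(0.5), abs=1e-12)
        assert table.ic["B"] == pytest.approx(-math.log(0.25))

    def test_unannotated_term_has_no_entry(self, five_term_corpus):
        ont, _ = five_term_corpus
        ann = annotations_from({"g1": {"A1"}}, ont)
        table = compute_ic(ont, ann)
        assert "B" not in table.ic

    def test_empty_universe_is_error(self, five_term_corpus):
        ont, _ = five_term_corpus
        with pytest.raises(ValidationError):
            compute_ic(ont, GenePhenotypeAnnotations(direct={}, propagated={}))

    def test_random_frequencies_match_brute_force(self, rng):
        ont = random_dag(rng, 50)
        gene_terms = random_gene_terms(rng, ont, 20)
        ann = annotations_from(gene_terms, ont)
        table = compute_ic(ont, ann)
        expected = brute_ic(parents_of(ont), gene_terms)
        assert set(table.ic) == set(expected)
        for t, v in expected.items():
            assert table.ic[t] == pytest.approx(v, abs=1e-12)

    def test_child_ic_at_least_parent_ic(self, rng):
        ont = random_dag(rng, 50)
        ann = annotations_from(random_gene_terms(rng, ont, 20), ont)
        table = compute_ic(ont, ann)
        for child, term in ont.terms.items():
            for parent in term.parent_ids:
                if child in table.ic and parent in table.ic:
                    assert table.ic[child] >= table.ic[parent] - 1e-12


class TestTermSimilarity:
    def test_self_similarity_equals_own_ic(self, five_term_corpus):
        ont, ann = five_term_corpus
        table = compute_ic(ont, ann)
        for t in table.ic:
            assert term_similarity(t, t, table, ont) == pytest.approx(table.ic[t])

    def test_siblings_under_root_only_score_zero(self, five_term_corpus):
        ont, ann = five_term_corpus
        table = compute_ic(ont, ann)
        assert term_similarity("A", "B", table, ont) == 0.0

    def test_cache_does_not_change_results(self, rng):
        ont = random_dag(rng, 30)
        ann = annotations_from(random_gene_terms(rng, ont, 15), ont)
        table = compute_ic(ont, ann)
        cache = TermSimilarityCache()
        terms = sorted(table.ic)
        for t1, t2 in zip(rng.sample(terms, 10), rng.sample(terms, 10)):
            plain = term_similarity(t1, t2, table, ont)
            assert term_similarity(t1, t2, table, ont, cache) == plain
            assert term_similarity(t2, t1, table, ont, cache) == plain  # cache hit


class TestProfileSimilarity:
    def test_self_directed_similarity_is_mean_ic(self, five_term_corpus):
        ont, ann = five_term_corpus
        table = compute_ic(ont, ann)
        prof = PhenotypeProfile("d", {"A1": 1, "B": 2})
        expected = (table.ic["A1"] + table.ic["B"]) / 2
        assert directed_similarity(prof, prof, table, ont) == pytest.approx(expected)
        assert profile_similarity(prof, prof, table, ont) == pytest.approx(expected)

    def test_disjoint_single_term_profiles_score_zero(self, five_term_corpus):
        ont, ann = five_term_corpus
        table = compute_ic(ont, ann)
        p1 = PhenotypeProfile("x", {"A1": 1})
        p2 = PhenotypeProfile("y", {"B": 1})
        assert profile_similarity(p1, p2, table, ont) == 0.0

    def test_symmetric_combination_arithmetic(self, five_term_corpus):
        ont, ann = five_term_corpus
        table = compute_ic(ont, ann)
        p1 = PhenotypeProfile("x", {"A1": 1, "A2": 1})
        p2 = PhenotypeProfile("y", {"A1": 1})
        fwd = directed_similarity(p1, p2, table, ont)
        rev = directed_similarity(p2, p1, table, ont)
        assert profile_similarity(p1, p2, table, ont) == pytest.approx(
            0.5 * fwd + 0.5 * rev
        )

    def test_empty_profile_raises_undefined(self, five_term_corpus):
        ont, ann = five_term_corpus
        table = compute_ic(ont, ann)
        empty = PhenotypeProfile("e", {})
        full = PhenotypeProfile("f", {"A1": 1})
        with pytest.raises(UndefinedMetricError):
            directed_similarity(empty, full, table, ont)
        with pytest.raises(UndefinedMetricError):
            profile_similarity(full, empty, table, ont)

    def test_terms_without_ic_are_skipped_not_zeroed(self, five_term_corpus):
        ont, _ = five_term_corpus
        ann = annotations_from({"g1": {"A1"}, "g2": {"A2"}}, ont)
        table = compute_ic(ont, ann)  # B never annotated -> no IC entry
        p1 = PhenotypeProfile("x", {"A1": 1, "B": 1})
        p2 = PhenotypeProfile("y", {"A1": 1})
        # if B were treated as ic=0 the mean would be halved
        assert directed_similarity(p1, p2, table, ont) == pytest.approx(table.ic["A1"])

    @pytest.mark.parametrize("seed", [100, 200, 300, 400, 500])
    def test_random_profiles_match_triple_loop_oracle(self, seed):
        rng = random.Random(seed)
        ont = random_dag(rng, 50)
        gene_terms = random_gene_terms(rng, ont, 20)
        ann = annotations_from(gene_terms, ont)
        table = compute_ic(ont, ann)
        parents = parents_of(ont)
        oracle_ic = brute_ic(parents, gene_terms)
        terms = sorted(table.ic)
        p1_terms = set(rng.sample(terms, min(10, len(terms))))
        p2_terms = set(rng.sample(terms, min(8, len(terms))))
        p1 = PhenotypeProfile("p1", {t: 1.0 for t in p1_terms})
        p2 = PhenotypeProfile("p2", {t: 1.0 for t in p2_terms})
        got = profile_similarity(p1, p2, table, ont)
        want = brute_profile_sim(parents, oracle_ic, p1_terms, p2_terms)
        assert got == pytest.approx(want, abs=1e-12)
        # symmetry, exact
        assert profile_similarity(p2, p1, table, ont) == got

    def test_weighted_mode_uses_profile_weights(self, five_term_corpus):
        ont, ann = five_term_corpus
        table = compute_ic(ont, ann)
        p1 = PhenotypeProfile("x", {"A1": 3.0, "B": 1.0})
        p2 = PhenotypeProfile("y", {"A1": 1.0})
        best_a1 = table.ic["A1"]
        best_b = term_similarity("B", "A1", table, ont)
        expected = (3.0 * best_a1 + 1.0 * best_b) / 4.0
        got = directed_similarity(p1, p2, table, ont, weighted=True)
        assert got == pytest.approx(expected)


def test_log_base_rescales_ic_globally(rng):
    ont = random_dag(rng, 40)
    ann = annotations_from(random_gene_terms(rng, ont, 20), ont)
    nat = compute_ic(ont, ann)
    base2 = compute_ic(ont, ann, log_base=2)
    factor = math.log(2)
    for t, v in nat.ic.items():
        assert base2.ic[t] * factor == pytest.approx(v, abs=1e-12)
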