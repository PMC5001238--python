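"""Shared fixtures: tiny hand-built ontologies and seeded random DAGs."""

from __future__ import annotations

import random

import pytest

from phenodrug.ontology import Ontology, OntologyTerm


def make_ontology(edges: dict[str, set[str]]) -> Ontology:
    """Build an ontology from a child -> parents mapping (plus implied root)."""
    all_ids = set(edges) | {p for ps in edges.values() for p in ps}
    terms = [OntologyTerm(t, name=t, parent_ids=set(edges.get(t, set()))) for t in sorted(all_ids)]
    return Ontology.from_terms(terms)


def random_dag(rng: random.Random, n_terms: int) -> Ontology:
    """Random rooted DAG: term i picks 1-3 parents among terms 0..i-1.

    Independent of the package's synthetic generator by construction.
    """
    edges: dict[str, set[str]] = {"T0": set()}
    for i in range(1, n_terms):
        k = rng.randint(1, min(3, i))
        parents = rng.sample(range(i), k)
        edges[f"T{i}"] = {f"T{j}" for j in parents}
    return make_ontology(edges)


def parents_of(ontology: Ontology) -> dict[str, set[str]]:
    return {t: set(term.parent_ids) for t, term in ontology.terms.items()}


def random_gene_terms(rng: random.Random, ontology: Ontology, n_genes: int,
                      max_terms: int = 5) -> dict[str, set[str]]:
    candidates = sorted(set(ontology.terms) - {ontology.root_id}) or [ontology.root_id]
    return {
        f"g{i}": set(rng.sample(candidates, rng.randint(1, min(max_terms, len(candidates)))))
        for i in range(n_genes)
    }


@pytest.fixture
def chain_ontology() -> Ontology:
    """R <- A <- B linear chain."""
    return make_ontology({"A": {"R"}, "B": {"A"}})


@pytest.fixture
def diamond_ontology() -> Ontology:
    """Root with two categories; leaf L under both (multi-inheritance)."""
    return make_ontology({"C1": {"R"}, "C2": {"R"}, "M": {"C1"}, "L": {"M", "C2"}})


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240901)
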