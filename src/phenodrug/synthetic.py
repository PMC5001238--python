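"""Seeded synthetic inputs for the full pipeline.

Generates, deterministically from one integer seed: a single-root layered
is-a DAG standing in for a phenotype ontology; a gene–phenotype annotation
corpus in which deeper (more specific) terms are rarer, so information
content grows with depth the way it does in real curated corpora; a disease
gene set; and a drug–target table with *planted positives* — drugs whose
targets are drawn largely from the disease genes, so a working similarity
pipeline should rank them near the top.

The writers emit exactly the file dialects the loaders read (OBO plus
three TSVs and a gene list), so loader tests, round-trip tests, and the
end-to-end pipeline all share one fixture path.  Everything here is
synthetic benchmark data; no attempt is made to imitate real MGI term names
or STITCH identifier schemes beyond column structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .annotations import DrugTargetTable, GenePhenotypeAnnotations
from .errors import ConfigError
from .ontology import Ontology, OntologyTerm

# geometric decay of per-term annotation probability per ontology level;
# combined with layers that widen with depth, each individual deep term is
# rare (high IC) while most annotation mass still lands on specific terms,
# as in real curated corpora
DEPTH_DECAY = 0.8

# layer-size growth factor: each layer holds ~3x the terms of the one above,
# mimicking the branching of real phenotype ontologies
LAYER_GROWTH = 3.0

# minimum width of the layer directly under the root, so a scaled-down
# ontology still has several phenotype categories
TOP_LEVEL_MIN = 6


@dataclass
class SyntheticConfig:
    """Shape of the synthetic benchmark.

    Defaults define the standard planted-positive benchmark: a 200-term
    ontology, 500 annotated genes, 100 drugs of which 10 are positives
    drawing 80 % of their targets from the 30 disease genes.
    """

    seed: int = 42
    n_terms: int = 200
    n_layers: int = 6
    max_parents: int = 2
    n_genes: int = 500
    annotations_per_gene: float = 4.0
    n_disease_genes: int = 10
    n_drugs: int = 100
    n_positive_drugs: int = 10
    targets_per_drug: int = 5
    positive_overlap_fraction: float = 0.8
    confidence_range: tuple[float, float] = (0.4, 1.0)

    def __post_init__(self) -> None:
        for name in ("n_terms", "n_layers", "max_parents", "n_genes",
                     "n_disease_genes", "n_drugs", "targets_per_drug"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.positive_overlap_fraction <= 1.0:
            raise ConfigError("positive_overlap_fraction must lie in [0, 1]")
        if self.n_positive_drugs > self.n_drugs:
            raise ConfigError("n_positive_drugs exceeds n_drugs")
        if self.n_positive_drugs < 0:
            raise ConfigError("n_positive_drugs must be non-negative")
        lo, hi = self.confidence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("confidence_range must satisfy 0 <= low <= high <= 1")


@dataclass
class SyntheticTruth:
    """Which drugs carry planted signal, and how much."""

    positive_drug_ids: frozenset[str]
    overlap_counts: dict[str, int]
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _term_id(i: int) -> str:
    return f"SP:{i:07d}"


def generate_ontology(config: SyntheticConfig) -> Ontology:
    """Layered single-root DAG: each non-root term gets 1..max_parents
    parents drawn uniformly from the layer above."""
    n = config.n_terms
    if n == 1:
        return Ontology.from_terms([OntologyTerm(_term_id(0), name="root")])
    if config.n_layers < 2:
        raise ConfigError("n_layers must be >= 2 for a multi-term ontology")
    if n < config.n_layers:
        raise ConfigError("n_terms must be >= n_layers (one term per layer minimum)")
    rng = np.random.default_rng(config.seed)
    # layer 0 = root alone; layer sizes below it grow geometrically with
    # depth so the DAG widens toward the leaves like a real ontology
    n_below = config.n_layers - 1
    raw = np.array([LAYER_GROWTH ** k for k in range(n_below)])
    sizes = np.maximum(1, np.round(raw / raw.sum() * (n - 1)).astype(int))
    # keep the top level wide enough that category scoring is meaningful,
    # as in real phenotype ontologies whose root has dozens of children
    sizes[0] = min(max(sizes[0], TOP_LEVEL_MIN), max(1, (n - 1) - (n_below - 1)))
    while sizes.sum() > n - 1:  # rounding overshoot: trim the widest layer
        sizes[int(np.argmax(sizes))] -= 1
    while sizes.sum() < n - 1:
        sizes[int(np.argmax(raw))] += 1
    layer_of = np.zeros(n, dtype=int)
    pos = 1
    for lay, size in enumerate(sizes, start=1):
        layer_of[pos:pos + size] = lay
        pos += size
    terms: list[OntologyTerm] = [OntologyTerm(_term_id(0), name="root")]
    by_layer: dict[int, list[int]] = {0: [0]}
    order = sorted(range(1, n), key=lambda i: (layer_of[i], i))
    for i in order:
        lay = int(layer_of[i])
        above = by_layer.get(lay - 1)
        while not above:  # parent layer may be empty if reshuffled; climb up
            lay -= 1
            above = by_layer.get(lay - 1)
        k = int(rng.integers(1, config.max_parents + 1))
        k = min(k, len(above))
        idx = rng.choice(len(above), size=k, replace=False)
        parents = {_term_id(above[j]) for j in sorted(int(x) for x in idx)}
        terms.append(OntologyTerm(_term_id(i), name=f"synthetic term {i}", parent_ids=parents))
        by_layer.setdefault(int(layer_of[i]), []).append(i)
    return Ontology.from_terms(terms)


def generate_annotations(
    ontology: Ontology, config: SyntheticConfig
) -> GenePhenotypeAnnotations:
    """Annotate each gene with depth-biased term draws.

    Per-gene annotation counts are Poisson(annotations_per_gene) floored at
    1; terms are sampled without replacement with probability proportional
    to DEPTH_DECAY ** depth, so specific terms are rare and their
    information content is high.
    """
    rng = np.random.default_rng(config.seed + 1)
    candidates = sorted(t for t in ontology.terms if t != ontology.root_id)
    if not candidates:
        candidates = [ontology.root_id]
    weights = np.array([DEPTH_DECAY ** ontology.depth(t) for t in candidates])
    weights /= weights.sum()
    direct: dict[str, set[str]] = {}
    for g in range(config.n_genes):
        k = max(1, int(rng.poisson(config.annotations_per_gene)))
        k = min(k, len(candidates))
        idx = rng.choice(len(candidates), size=k, replace=False, p=weights)
        direct[f"gene{g:05d}"] = {candidates[int(i)] for i in idx}
    return GenePhenotypeAnnotations.from_direct(direct, ontology)


def generate_disease_and_drugs(
    annotations: GenePhenotypeAnnotations, config: SyntheticConfig
) -> tuple[frozenset[str], DrugTargetTable, SyntheticTruth]:
    """Sample disease genes and build a drug–target table with planted
    positives.

    Positive drugs draw ``positive_overlap_fraction`` of their targets from
    the disease gene set (rounded to the nearest whole target); negatives
    and the remaining positive targets come from non-disease genes.
    Confidences are uniform in ``confidence_range``.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = sorted(annotations.direct)
    if config.n_disease_genes > len(genes):
        raise ConfigError("n_disease_genes exceeds the number of annotated genes")
    disease_idx = rng.choice(len(genes), size=config.n_disease_genes, replace=False)
    disease_genes = frozenset(genes[int(i)] for i in disease_idx)
    background = sorted(set(genes) - disease_genes)
    disease_sorted = sorted(disease_genes)
    if not background and config.positive_overlap_fraction < 1.0:
        raise ConfigError("no non-disease genes left to draw negative targets from")

    pos_idx = set(int(i) for i in rng.choice(config.n_drugs, size=config.n_positive_drugs,
                                             replace=False))
    lo, hi = config.confidence_range
    links: dict[str, list[tuple[str, float]]] = {}
    overlap_counts: dict[str, int] = {}
    positive_ids: set[str] = set()
    for d in range(config.n_drugs):
        drug_id = f"drug{d:04d}"
        k = config.targets_per_drug
        if d in pos_idx:
            n_overlap = round(config.positive_overlap_fraction * k)
            n_overlap = min(n_overlap, len(disease_sorted))
            positive_ids.add(drug_id)
        else:
            n_overlap = 0
        n_bg = min(k - n_overlap, len(background))
        targets: list[str] = []
        if n_overlap:
            idx = rng.choice(len(disease_sorted), size=n_overlap, replace=False)
            targets += [disease_sorted[int(i)] for i in idx]
        if n_bg:
            idx = rng.choice(len(background), size=n_bg, replace=False)
            targets += [background[int(i)] for i in idx]
        confs = rng.uniform(lo, hi, size=len(targets))
        links[drug_id] = sorted(zip(targets, (float(c) for c in confs)))
        overlap_counts[drug_id] = n_overlap
    truth = SyntheticTruth(
        positive_drug_ids=frozenset(positive_ids),
        overlap_counts=overlap_counts,
        config=config,
    )
    return disease_genes, DrugTargetTable(links=links), truth


# -- writers (the exact dialects the loaders read) -----------------------


def write_obo(ontology: Ontology, path) -> None:
    lines = ["format-version: 1.2", ""]
    for tid in sorted(ontology.terms):
        t = ontology.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {t.term_id}")
        if t.name:
            lines.append(f"name: {t.name}")
        for p in sorted(t.parent_ids):
            lines.append(f"is_a: {p} ! {ontology.terms[p].name}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def write_gene_phenotypes(annotations: GenePhenotypeAnnotations, path) -> None:
    lines = ["gene_id\tphenotype_id"]
    for g in sorted(annotations.direct):
        for t in sorted(annotations.direct[g]):
            lines.append(f"{g}\t{t}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_drug_targets(table: DrugTargetTable, path) -> None:
    # confidences written with full repr precision so reload is exact
    lines = ["drug_id\tgene_id\tscore"]
    for d in sorted(table.links):
        for gene, conf in sorted(table.links[d]):
            lines.append(f"{d}\t{gene}\t{conf!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_gene_list(genes: frozenset[str], path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n", encoding="utf-8")


def write_evaluation_sets(truth: SyntheticTruth, path) -> None:
    """Render the planted positives as the 'potential' evaluation set.

    Drug types cycle deterministically through the three-type vocabulary so
    per-type metrics are exercised.
    """
    types = ("non_targeted_cancer", "targeted_cancer", "non_cancer")
    lines = ["drug_id\tset_label\tdrug_type"]
    for i, d in enumerate(sorted(truth.positive_drug_ids)):
        lines.append(f"{d}\tpotential\t{types[i % 3]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "positive_drug_ids": sorted(truth.positive_drug_ids),
        "overlap_counts": dict(sorted(truth.overlap_counts.items())),
        "config": asdict(truth.config) if truth.config else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def simulate(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Generate the full benchmark and write every input file.

    Returns the path of each written file keyed by role: ontology,
    annotations, targets, genes, eval_sets, truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ontology = generate_ontology(config)
    annotations = generate_annotations(ontology, config)
    disease_genes, targets, truth = generate_disease_and_drugs(annotations, config)
    paths = {
        "ontology": outdir / "ontology.obo",
        "annotations": outdir / "gene_phenotypes.tsv",
        "targets": outdir / "drug_targets.tsv",
        "genes": outdir / "disease_genes.txt",
        "eval_sets": outdir / "evaluation_sets.tsv",
        "truth": outdir / "truth.json",
    }
    write_obo(ontology, paths["ontology"])
    write_gene_phenotypes(annotations, paths["annotations"])
    write_drug_targets(targets, paths["targets"])
    write_gene_list(disease_genes, paths["genes"])
    write_evaluation_sets(truth, paths["eval_sets"])
    write_truth(truth, paths["truth"])
    return paths
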