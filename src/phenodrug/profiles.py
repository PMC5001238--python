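"""Weighted phenotype profiles for a disease and for candidate drugs.

A disease profile weights each phenotype term by the number of disease
genes annotated with it; a drug profile weights each term by the sum of
confidence scores of the drug's target genes annotated with it.  Profiles
use DIRECT annotations only — the ancestor closure enters the pipeline
through information-content computation, not through profile membership,
so profiles are not flooded with generic ancestor terms.

The disease profile is pruned with a median filter: terms whose weight
falls strictly below the median weight are removed, keeping the best
supported (most gene-recurrent) half of the phenotype signature.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .annotations import DrugTargetTable, GenePhenotypeAnnotations
from .errors import LookupError_, ValidationError
from .ontology import Ontology


@dataclass
class PhenotypeProfile:
    """Owner (disease or drug) plus term → positive weight mapping."""

    owner_id: str
    weights: dict[str, float]
    source: str = "disease"  # "disease" | "drug"

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.weights)

    def __len__(self) -> int:
        return len(self.weights)

    def __bool__(self) -> bool:
        return bool(self.weights)


@dataclass
class CategoryScores:
    """Per-category weight sums and the descending-score ranking."""

    scores: dict[str, float]
    ranking: list[str]


def build_disease_profile(
    genes: frozenset[str] | set[str],
    annotations: GenePhenotypeAnnotations,
    owner_id: str = "disease",
) -> PhenotypeProfile:
    """Weight each phenotype term by how many disease genes carry it.

    Terms annotated to no disease gene are absent.  Genes with no
    annotations contribute nothing; if *no* disease gene has any
    annotation the profile would be empty and a ValidationError is raised.
    """
    if not genes:
        raise ValidationError("disease gene set is empty")
    counts: dict[str, int] = {}
    for g in genes:
        for t in annotations.direct.get(g, ()):
            counts[t] = counts.get(t, 0) + 1
    if not counts:
        raise ValidationError("no disease gene carries any phenotype annotation")
    return PhenotypeProfile(owner_id=owner_id, weights=dict(counts), source="disease")


def filter_by_median(profile: PhenotypeProfile) -> PhenotypeProfile:
    """Drop terms whose weight is strictly below the profile's median weight.

    The median is computed once on the unfiltered weights (even counts take
    the midpoint mean); terms at exactly the median survive, so at most
    ⌊n/2⌋ terms are ever removed.
    """
    if not profile:
        raise ValidationError("cannot median-filter an empty profile")
    med = statistics.median(profile.weights.values())
    kept = {t: w for t, w in profile.weights.items() if w >= med}
    return PhenotypeProfile(owner_id=profile.owner_id, weights=kept, source=profile.source)


def build_drug_profile(
    drug: str,
    targets: DrugTargetTable,
    annotations: GenePhenotypeAnnotations,
) -> PhenotypeProfile:
    """Weight each term by the summed confidences of target genes carrying it.

    A drug whose targets have no phenotype annotations yields an *empty*
    profile; ranking treats such drugs as unscorable rather than scoring
    them zero.
    """
    if drug not in targets.links:
        raise LookupError_(f"drug {drug!r} not present in the target table")
    weights: dict[str, float] = {}
    for gene, conf in targets.links[drug]:
        for t in annotations.direct.get(gene, ()):
            weights[t] = weights.get(t, 0.0) + conf
    return PhenotypeProfile(owner_id=drug, weights=weights, source="drug")


def score_categories(profile: PhenotypeProfile, ontology: Ontology) -> CategoryScores:
    """Sum profile weights into top-level phenotype categories.

    Each term's full weight is added to *every* category it maps to
    (multi-inheritance counts toward each); categories receiving no weight
    are omitted.  Ranking is by descending score with lexicographic
    tie-break on category id.
    """
    if not profile:
        raise ValidationError("cannot score categories of an empty profile")
    scores: dict[str, float] = {}
    for term, w in profile.weights.items():
        for cat in ontology.term_categories(term):
            scores[cat] = scores.get(cat, 0.0) + w
    ranking = sorted(scores, key=lambda c: (-scores[c], c))
    return CategoryScores(scores=scores, ranking=ranking)
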