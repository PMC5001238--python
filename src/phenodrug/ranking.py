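"""Rank every candidate drug by phenotype-profile similarity to the disease.

Drugs are sorted by descending symmetric best-match-average similarity.
Tied scores share the average of their positional ranks, and each drug's
percentile is rank / n_candidates × 100, matching the "top X %" reporting
convention.  Drugs whose profiles are empty after IC filtering have no
defined similarity; they are reported in ``excluded`` rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import UndefinedMetricError, ValidationError
from .ontology import Ontology
from .profiles import PhenotypeProfile
from .similarity import ICTable, TermSimilarityCache, profile_similarity


@dataclass
class RankedEntry:
    drug_id: str
    score: float
    rank: float
    percentile: float


@dataclass
class RankedDrugList:
    """Descending-score drug ranking with average-rank ties.

    ``excluded`` lists drugs with undefined similarity; when a full-length
    list is needed (e.g. worst-rank imputation in evaluation) the convention
    is rank = n_candidates for excluded drugs, recorded in metadata by the
    writers, never silently applied here.
    """

    entries: list[RankedEntry]
    excluded: list[str] = field(default_factory=list)

    @property
    def n_candidates(self) -> int:
        return len(self.entries)

    def percentiles(self) -> dict[str, float]:
        return {e.drug_id: e.percentile for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.rank, e.drug_id, e.score, e.percentile) for e in self.entries],
            columns=["rank", "drug_id", "score", "percentile"],
        )


def rank_from_scores(scores: dict[str, float], excluded: Iterable[str] = ()) -> RankedDrugList:
    """Build a ranked list from precomputed drug → score values."""
    if not scores:
        raise ValidationError("no scorable drugs to rank")
    s = pd.Series(scores, dtype=float)
    ranks = s.rank(ascending=False, method="average")
    n = len(s)
    order = sorted(s.index, key=lambda d: (-s[d], d))
    entries = [
        RankedEntry(drug_id=d, score=float(s[d]), rank=float(ranks[d]),
                    percentile=float(ranks[d]) / n * 100.0)
        for d in order
    ]
    return RankedDrugList(entries=entries, excluded=sorted(excluded))


def rank_drugs(
    disease_profile: PhenotypeProfile,
    drug_profiles: Iterable[PhenotypeProfile],
    ic: ICTable,
    ontology: Ontology,
    weighted: bool = False,
) -> RankedDrugList:
    """Score every drug profile against the disease profile and rank.

    Input order of the drug profiles never affects the result; ties and
    ordering depend only on scores and drug ids.
    """
    if not disease_profile:
        raise ValidationError("disease profile is empty")
    cache = TermSimilarityCache()
    scores: dict[str, float] = {}
    excluded: list[str] = []
    for dp in drug_profiles:
        try:
            scores[dp.owner_id] = profile_similarity(
                disease_profile, dp, ic, ontology, cache, weighted=weighted
            )
        except UndefinedMetricError:
            excluded.append(dp.owner_id)
    if not scores:
        raise ValidationError("no drug has a defined similarity to the disease profile")
    return rank_from_scores(scores, excluded=excluded)
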