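"""Information content and semantic similarity between phenotype profiles.

The information content of a term t is IC(t) = −log p(t), where p(t) is
the fraction of annotated genes whose ancestor-closed annotation set
contains t.  Natural logarithm by default; any base rescales every score
by a constant and leaves all rankings unchanged.

Term–term similarity is Resnik's measure: the maximum IC over the common
ancestors of the two terms (the reflexive closure makes sim(t, t) = IC(t)).
Profile–profile similarity is the symmetric best-match average: each term
of one profile is matched to its most similar term in the other, the
matches are averaged in each direction, and the two directed averages are
averaged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .annotations import GenePhenotypeAnnotations
from .errors import UndefinedMetricError, ValidationError
from .ontology import Ontology
from .profiles import PhenotypeProfile

logger = logging.getLogger(__name__)


@dataclass
class ICTable:
    """Term → information content, with the underlying closure frequencies.

    ``ic[t] = -log(frequency[t] / universe)`` for every term annotated (under
    closure) to at least one gene; unannotated terms carry no entry.
    """

    ic: dict[str, float]
    frequency: dict[str, int]
    universe: int
    log_base: float | None = None  # None = natural log

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]


def compute_ic(
    ontology: Ontology,
    annotations: GenePhenotypeAnnotations,
    log_base: float | None = None,
) -> ICTable:
    """Compute closure-based term frequencies and information content.

    frequency(t) counts genes whose propagated annotation set contains t;
    the denominator is the total number of annotated genes.  The root ends
    up with p = 1 and IC = 0 whenever every annotated gene reaches it.
    """
    universe = annotations.gene_universe_size
    if universe == 0:
        raise ValidationError("annotation corpus contains no annotated genes")
    frequency: dict[str, int] = {}
    for terms in annotations.propagated.values():
        for t in terms:
            frequency[t] = frequency.get(t, 0) + 1
    log = math.log if log_base is None else (lambda x: math.log(x, log_base))
    ic = {t: max(0.0, -log(n / universe)) for t, n in frequency.items()}
    return ICTable(ic=ic, frequency=frequency, universe=universe, log_base=log_base)


@dataclass
class TermSimilarityCache:
    """Memoizes term-pair similarities across a drug screen.

    Purely a performance device: results are identical with or without it.
    The key is the unordered term pair (the measure is symmetric).
    """

    _store: dict[frozenset[str], float] = field(default_factory=dict)

    def get(self, t1: str, t2: str) -> float | None:
        return self._store.get(frozenset((t1, t2)))

    def put(self, t1: str, t2: str, value: float) -> None:
        self._store[frozenset((t1, t2))] = value


def term_similarity(
    t1: str,
    t2: str,
    ic: ICTable,
    ontology: Ontology,
    cache: TermSimilarityCache | None = None,
) -> float:
    """Resnik similarity: max IC over the common ancestors of t1 and t2.

    Restricted to ancestors with IC entries; if none has one (possible only
    under virtual-root grafting with disjoint annotation corpora) the
    similarity is 0 with a logged warning.
    """
    if cache is not None:
        hit = cache.get(t1, t2)
        if hit is not None:
            return hit
    best = -1.0
    for a in ontology.common_ancestors(t1, t2):
        v = ic.ic.get(a)
        if v is not None and v > best:
            best = v
    if best < 0.0:
        logger.warning("no common ancestor of %s and %s has an IC entry", t1, t2)
        best = 0.0
    if cache is not None:
        cache.put(t1, t2, best)
    return best


def _ic_terms(profile: PhenotypeProfile, ic: ICTable) -> list[str]:
    """Profile terms that have IC entries; skipped terms are counted in logs."""
    kept = [t for t in sorted(profile.weights) if t in ic.ic]
    skipped = len(profile.weights) - len(kept)
    if skipped:
        logger.info(
            "profile %s: skipped %d/%d terms with no IC entry",
            profile.owner_id, skipped, len(profile.weights),
        )
    return kept


def directed_similarity(
    p1: PhenotypeProfile,
    p2: PhenotypeProfile,
    ic: ICTable,
    ontology: Ontology,
    cache: TermSimilarityCache | None = None,
    weighted: bool = False,
) -> float:
    """Best-match average from p1 toward p2.

    For each term in p1, take its best Resnik match in p2, then average.
    The default is the unweighted mean over p1's terms; ``weighted=True``
    instead averages with p1's profile weights (normalized within the
    profile).  Terms without IC entries are skipped; if p1 retains no term
    the similarity is undefined (raised, not returned as 0).
    """
    t1s = _ic_terms(p1, ic)
    t2s = _ic_terms(p2, ic)
    if not t1s or not t2s:
        raise UndefinedMetricError(
            f"directed similarity {p1.owner_id}->{p2.owner_id} undefined: "
            "a profile is empty after IC filtering"
        )
    total = 0.0
    wsum = 0.0
    for t1 in t1s:
        best = max(term_similarity(t1, t2, ic, ontology, cache) for t2 in t2s)
        w = p1.weights[t1] if weighted else 1.0
        total += w * best
        wsum += w
    return total / wsum


def profile_similarity(
    p1: PhenotypeProfile,
    p2: PhenotypeProfile,
    ic: ICTable,
    ontology: Ontology,
    cache: TermSimilarityCache | None = None,
    weighted: bool = False,
) -> float:
    """Symmetric best-match average: ½ sim(p1→p2) + ½ sim(p2→p1)."""
    fwd = directed_similarity(p1, p2, ic, ontology, cache, weighted)
    rev = directed_similarity(p2, p1, ic, ontology, cache, weighted)
    return 0.5 * fwd + 0.5 * rev
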