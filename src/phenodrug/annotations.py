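"""Readers for the pipeline's tabular inputs.

Four inputs besides the ontology: gene–phenotype annotations (MGI-style
two-column TSV), drug–target links with confidence scores (STITCH-style
TSV), a disease gene list (one id per line), and labeled evaluation drug
sets.  Gene and drug identifiers are opaque strings and must already agree
across files; no identifier mapping is performed.

Annotation propagation follows the true-path rule: a gene annotated with a
term is also annotated with every ancestor of that term.  The propagated
sets drive information-content computation; the direct sets drive profile
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, ValidationError
from .ontology import Ontology

logger = logging.getLogger(__name__)

SET_LABELS = ("approved", "potential", "off_label")
DRUG_TYPES = ("non_targeted_cancer", "targeted_cancer", "non_cancer")


@dataclass
class GenePhenotypeAnnotations:
    """Gene → phenotype-term annotations, direct and ancestor-closed.

    ``gene_universe_size`` is the number of distinct genes with at least one
    surviving annotation; it is the denominator of the term frequency p(t)
    in information-content computation.
    """

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    n_dropped_rows: int = 0

    @property
    def gene_universe_size(self) -> int:
        return sum(1 for s in self.direct.values() if s)

    @classmethod
    def from_direct(
        cls, direct: dict[str, set[str]], ontology: Ontology, n_dropped_rows: int = 0
    ) -> "GenePhenotypeAnnotations":
        """Build the ancestor-closed (propagated) variant from direct sets."""
        frozen = {g: frozenset(ts) for g, ts in direct.items() if ts}
        propagated = {
            g: frozenset().union(*(ontology.ancestors(t, reflexive=True) for t in ts))
            for g, ts in frozen.items()
        }
        return cls(direct=frozen, propagated=propagated, n_dropped_rows=n_dropped_rows)


@dataclass
class DrugTargetTable:
    """Drug → [(target gene, confidence)] links, confidences in [0, 1]."""

    links: dict[str, list[tuple[str, float]]]

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.links)


@dataclass
class EvaluationSets:
    """Labeled drug sets for rank-based evaluation.

    ``membership`` assigns each evaluation drug to exactly one set label
    (approved | potential | off_label); a drug listed as approved is removed
    from the other two sets so the novel-drug sets contain no already
    approved therapy.  ``drug_type`` carries an orthogonal classification
    (non-targeted cancer / targeted cancer / non-cancer drug).
    """

    membership: dict[str, str]
    drug_type: dict[str, str] = field(default_factory=dict)

    def drugs_in(self, set_label: str) -> frozenset[str]:
        return frozenset(d for d, s in self.membership.items() if s == set_label)

    def drugs_of_type(self, type_label: str) -> frozenset[str]:
        return frozenset(d for d, t in self.drug_type.items() if t == type_label)

    @property
    def all_drugs(self) -> frozenset[str]:
        return frozenset(self.membership)


def _read_tsv(path, columns: tuple[str, ...], header: bool = True) -> pd.DataFrame:
    try:
        if header:
            df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        else:
            df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=list(columns), comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty input file: {path}") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    if df.empty:
        raise ValidationError(f"no data rows in {path}")
    return df


def load_gene_phenotypes(path, ontology: Ontology, header: bool = True) -> GenePhenotypeAnnotations:
    """Load an MGI-style gene→phenotype TSV (columns gene_id, phenotype_id).

    Rows citing terms unknown to the ontology (and not resolvable through an
    alt id) are dropped with a logged count; rows citing an alt id resolve to
    the primary term.  The propagated mapping is computed on load.
    """
    df = _read_tsv(path, ("gene_id", "phenotype_id"), header=header)
    direct: dict[str, set[str]] = {}
    dropped = 0
    for gene, term in zip(df["gene_id"], df["phenotype_id"]):
        resolved = ontology.resolve(term)
        if resolved is None:
            dropped += 1
            continue
        direct.setdefault(gene, set()).add(resolved)
    if dropped:
        logger.warning("%s: dropped %d rows citing unknown/obsolete terms", path, dropped)
    if not direct:
        raise ValidationError(f"{path}: no annotation row references a known ontology term")
    return GenePhenotypeAnnotations.from_direct(direct, ontology, n_dropped_rows=dropped)


def load_drug_targets(
    path,
    score_scale: float = 1.0,
    min_confidence: float = 0.0,
    header: bool = True,
) -> DrugTargetTable:
    """Load a STITCH-style drug→target TSV (columns drug_id, gene_id, score).

    Raw scores are divided by ``score_scale`` (1000 for the STITCH integer
    dialect, 1 for unit-real scores); links below ``min_confidence`` after
    scaling are removed; duplicate (drug, gene) pairs collapse to the
    maximum confidence.
    """
    if score_scale <= 0:
        raise FormatError(f"score_scale must be positive, got {score_scale}")
    df = _read_tsv(path, ("drug_id", "gene_id", "score"), header=header)
    best: dict[tuple[str, str], float] = {}
    for i, (drug, gene, raw) in enumerate(zip(df["drug_id"], df["gene_id"], df["score"])):
        try:
            conf = float(raw) / score_scale
        except ValueError:
            raise FormatError(f"{path} row {i}: non-numeric score {raw!r}") from None
        if not 0.0 <= conf <= 1.0:
            raise FormatError(
                f"{path} row {i} ({drug}, {gene}): scaled confidence {conf} outside [0, 1]"
            )
        key = (drug, gene)
        if conf > best.get(key, -1.0):
            best[key] = conf
    links: dict[str, list[tuple[str, float]]] = {}
    for (drug, gene), conf in sorted(best.items()):
        if conf >= min_confidence:
            links.setdefault(drug, []).append((gene, conf))
    return DrugTargetTable(links=links)


def load_gene_list(path) -> frozenset[str]:
    """Load a plain-text gene list: one id per line, '#' comments ignored."""
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    if not genes:
        raise ValidationError(f"{path}: no gene ids found")
    return frozenset(genes)


def load_evaluation_sets(path, header: bool = True) -> EvaluationSets:
    """Load the evaluation TSV (columns drug_id, set_label, drug_type).

    A drug appearing in the approved set is removed from the potential and
    off-label sets, so those sets measure the recovery of *novel* therapies
    only.
    """
    df = _read_tsv(path, ("drug_id", "set_label", "drug_type"), header=header)
    labels: dict[str, set[str]] = {}
    drug_type: dict[str, str] = {}
    for i, (drug, set_label, dtype) in enumerate(
        zip(df["drug_id"], df["set_label"], df["drug_type"])
    ):
        if set_label not in SET_LABELS:
            raise FormatError(f"{path} row {i}: unknown set label {set_label!r}")
        if dtype not in DRUG_TYPES:
            raise FormatError(f"{path} row {i}: unknown drug type {dtype!r}")
        labels.setdefault(drug, set()).add(set_label)
        drug_type[drug] = dtype
    membership: dict[str, str] = {}
    for drug, lbls in labels.items():
        if "approved" in lbls:
            if len(lbls) > 1:
                logger.info(
                    "%s: drug %s listed as approved; removed from %s",
                    path, drug, sorted(lbls - {"approved"}),
                )
            membership[drug] = "approved"
        else:
            # potential takes precedence over off_label if both appear
            membership[drug] = "potential" if "potential" in lbls else "off_label"
    return EvaluationSets(membership=membership, drug_type=drug_type)
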