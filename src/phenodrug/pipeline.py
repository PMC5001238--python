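"""End-to-end orchestration: files in, ranked list and report out.

Thin glue over the library modules, shared by the CLI subcommands and the
``run-all`` command so their composition is identical by construction.
All output files are deterministic functions of the inputs and flags; run
provenance (timestamps, checksums) goes to a separate metadata sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .annotations import (
    load_drug_targets,
    load_evaluation_sets,
    load_gene_list,
    load_gene_phenotypes,
)
from .evaluation import EvaluationReport, evaluate, report_to_dict
from .ontology import Ontology, parse_obo
from .profiles import (
    CategoryScores,
    build_disease_profile,
    build_drug_profile,
    filter_by_median,
    score_categories,
)
from .ranking import RankedDrugList, rank_drugs, rank_from_scores
from .similarity import compute_ic
from .errors import FormatError

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    ranked: RankedDrugList
    report: EvaluationReport | None
    categories: CategoryScores
    n_profile_terms: int


def run_pipeline(
    ontology_path,
    annotations_path,
    targets_path,
    genes_path,
    eval_sets_path=None,
    comparator_path=None,
    score_scale: float = 1.0,
    min_confidence: float = 0.0,
    median_filter: bool = True,
    weighted: bool = False,
    allow_virtual_root: bool = False,
) -> PipelineResult:
    """Run the full screen: profiles → IC → similarity ranking → evaluation."""
    ontology = parse_obo(ontology_path, allow_virtual_root=allow_virtual_root)
    annotations = load_gene_phenotypes(annotations_path, ontology)
    targets = load_drug_targets(targets_path, score_scale=score_scale,
                                min_confidence=min_confidence)
    disease_genes = load_gene_list(genes_path)

    profile = build_disease_profile(disease_genes, annotations)
    if median_filter:
        profile = filter_by_median(profile)
    categories = score_categories(profile, ontology)

    ic = compute_ic(ontology, annotations)
    drug_profiles = [
        build_drug_profile(d, targets, annotations) for d in targets.drug_ids
    ]
    ranked = rank_drugs(profile, drug_profiles, ic, ontology, weighted=weighted)

    report = None
    if eval_sets_path is not None:
        sets = load_evaluation_sets(eval_sets_path)
        comparator = load_ranked_list(comparator_path) if comparator_path else None
        report = evaluate(ranked, sets, comparator=comparator)
    return PipelineResult(
        ranked=ranked, report=report, categories=categories,
        n_profile_terms=len(profile),
    )


# -- ranked-list I/O ----------------------------------------------------


def write_ranked_list(ranked: RankedDrugList, path) -> None:
    lines = ["rank\tdrug_id\tscore\tpercentile"]
    for e in ranked.entries:
        lines.append(f"{e.rank!r}\t{e.drug_id}\t{e.score!r}\t{e.percentile!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_ranked_list(path) -> RankedDrugList:
    """Read a ranked list TSV (ours or a comparator's: rank, drug_id, score...).

    Only drug ids and scores are used; ranks and percentiles are recomputed
    so external lists with different conventions are normalized.
    """
    scores: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            di, si = header.index("drug_id"), header.index("score")
        except ValueError:
            raise FormatError(f"{path}: header must contain drug_id and score columns") from None
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= max(di, si):
                continue
            scores[parts[di]] = float(parts[si])
    return rank_from_scores(scores)


def write_category_scores(categories: CategoryScores, ontology: Ontology, path) -> None:
    lines = ["rank\tcategory_id\tcategory_name\tscore"]
    for i, cat in enumerate(categories.ranking, start=1):
        name = ontology.terms[cat].name if cat in ontology.terms else ""
        lines.append(f"{i}\t{cat}\t{name}\t{categories.scores[cat]!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_report(report: EvaluationReport, path) -> None:
    Path(path).write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def write_pr_curve(report: EvaluationReport, path) -> None:
    lines = ["recall\tprecision"]
    for r, p in report.pr_curve:
        lines.append(f"{r!r}\t{p!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_metadata(path, config_echo: dict, input_paths: dict) -> None:
    """Provenance sidecar: flags, input checksums, version, timestamp."""
    checksums = {}
    for role, p in input_paths.items():
        if p is None:
            continue
        p = Path(p)
        if p.exists():
            checksums[role] = hashlib.sha256(p.read_bytes()).hexdigest()
    meta = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config_echo,
        "input_sha256": checksums,
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
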