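"""Rank-based evaluation of a drug screen against labeled drug sets.

Metrics follow standard ranked-retrieval practice: per-set and per-type
median percentile ranks (the median resists the influence of individual
very poor ranks, which an average would not), a paired Student's t-test on
percentile differences over the drugs two methods share, and the
precision–recall curve with its average precision (single query, so mean
average precision equals AP).
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field

from scipy import stats

from .annotations import DRUG_TYPES, SET_LABELS, EvaluationSets
from .errors import UndefinedMetricError
from .ranking import RankedDrugList

logger = logging.getLogger(__name__)


@dataclass
class PairedTestResult:
    t: float
    p: float
    n: int


@dataclass
class EvaluationReport:
    """All metrics for one ranked list, optionally against a comparator.

    ``per_set_median`` and ``per_type_median`` hold None where a metric is
    undefined (no evaluation drug found); report writers render these as NA.
    ``approved_percentiles`` lists approved drugs individually — with only a
    handful of approved therapies, individual ranks are more informative
    than their median.
    """

    per_set_median: dict[str, float | None]
    per_type_median: dict[str, float | None]
    combined_median: float | None
    approved_percentiles: dict[str, float]
    pr_curve: list[tuple[float, float]]
    average_precision: float | None
    paired_tests: dict[str, PairedTestResult] = field(default_factory=dict)
    n_missing: dict[str, int] = field(default_factory=dict)
    rank_scale: str = "percentile"  # paired tests compare percentiles, not raw ranks


def median_percentile(ranked: RankedDrugList, drugs: frozenset[str] | set[str]) -> float:
    """Median of the percentile ranks of the given drugs within the list.

    Drugs absent from the list are excluded (and logged); an even count
    takes the midpoint mean.  Raises if no drug is found.
    """
    pct = ranked.percentiles()
    found = [pct[d] for d in sorted(drugs) if d in pct]
    missing = len(drugs) - len(found)
    if missing:
        logger.info("median_percentile: %d/%d evaluation drugs absent from list",
                    missing, len(drugs))
    if not found:
        raise UndefinedMetricError("no evaluation drug present in the ranked list")
    return statistics.median(found)


def paired_rank_test(
    ranks_a: dict[str, float], ranks_b: dict[str, float]
) -> PairedTestResult:
    """Two-sided paired Student's t-test on percentile differences.

    Computed only over drugs present in BOTH mappings.  All-zero differences
    give t = 0, p = 1 by convention; zero-variance nonzero differences give
    p = 0 (the degenerate limit of the t distribution).
    """
    overlap = sorted(set(ranks_a) & set(ranks_b))
    n = len(overlap)
    if n < 2:
        raise UndefinedMetricError(f"paired test needs >= 2 overlapping drugs, got {n}")
    diffs = [ranks_a[d] - ranks_b[d] for d in overlap]
    if all(d == 0.0 for d in diffs):
        return PairedTestResult(t=0.0, p=1.0, n=n)
    sd = statistics.stdev(diffs)
    if sd == 0.0:
        mean = statistics.fmean(diffs)
        return PairedTestResult(t=math.copysign(math.inf, mean), p=0.0, n=n)
    res = stats.ttest_rel([ranks_a[d] for d in overlap], [ranks_b[d] for d in overlap])
    return PairedTestResult(t=float(res.statistic), p=float(res.pvalue), n=n)


def precision_recall(
    ranked: RankedDrugList, positives: frozenset[str] | set[str]
) -> tuple[list[tuple[float, float]], float]:
    """Raw step precision–recall curve and its average precision.

    Walking the list from rank 1, record (recall, precision) at each
    positive hit; AP is the mean of the recorded precisions.  Positives
    absent from the list are excluded from the metric (consistent with the
    exclusion policy for medians), with a logged count.  No interpolation
    is applied.
    """
    present = [e.drug_id for e in ranked.entries]
    found = set(positives) & set(present)
    n_pos = len(found)
    if n_pos == 0:
        raise UndefinedMetricError("no positive drug present in the ranked list")
    if n_pos < len(positives):
        logger.info("precision_recall: %d/%d positives absent from list",
                    len(positives) - n_pos, len(positives))
    curve: list[tuple[float, float]] = []
    hits = 0
    precisions: list[float] = []
    for i, drug in enumerate(present, start=1):
        if drug in found:
            hits += 1
            precision = hits / i
            curve.append((hits / n_pos, precision))
            precisions.append(precision)
    ap = sum(precisions) / n_pos
    return curve, ap


def _safe_median(ranked: RankedDrugList, drugs: frozenset[str]) -> float | None:
    if not drugs:
        return None
    try:
        return median_percentile(ranked, drugs)
    except UndefinedMetricError:
        return None


def evaluate(
    ranked: RankedDrugList,
    sets: EvaluationSets,
    comparator: RankedDrugList | None = None,
) -> EvaluationReport:
    """Full evaluation report for one ranked list.

    Per-set medians (approved drugs additionally reported individually),
    per-type medians, the combined-set median, the PR curve and AP over the
    union of all evaluation drugs, and — when a comparator list is supplied —
    paired t-tests per set, per type, and combined, each restricted to drugs
    both lists rank.
    """
    pct = ranked.percentiles()
    per_set = {lbl: _safe_median(ranked, sets.drugs_in(lbl)) for lbl in SET_LABELS}
    per_type = {t: _safe_median(ranked, sets.drugs_of_type(t)) for t in DRUG_TYPES}
    combined = _safe_median(ranked, sets.all_drugs)
    approved = {d: pct[d] for d in sorted(sets.drugs_in("approved")) if d in pct}

    try:
        curve, ap = precision_recall(ranked, sets.all_drugs)
    except UndefinedMetricError:
        curve, ap = [], None

    n_missing = {"primary": sum(1 for d in sets.all_drugs if d not in pct)}
    paired: dict[str, PairedTestResult] = {}
    if comparator is not None:
        cmp_pct = comparator.percentiles()
        n_missing["comparator"] = sum(1 for d in sets.all_drugs if d not in cmp_pct)
        groups: dict[str, frozenset[str]] = {
            **{lbl: sets.drugs_in(lbl) for lbl in SET_LABELS},
            **{t: sets.drugs_of_type(t) for t in DRUG_TYPES},
            "combined": sets.all_drugs,
        }
        for name, drugs in groups.items():
            a = {d: pct[d] for d in drugs if d in pct}
            b = {d: cmp_pct[d] for d in drugs if d in cmp_pct}
            try:
                paired[name] = paired_rank_test(a, b)
            except UndefinedMetricError:
                pass  # rendered as NA downstream

    return EvaluationReport(
        per_set_median=per_set,
        per_type_median=per_type,
        combined_median=combined,
        approved_percentiles=approved,
        pr_curve=curve,
        average_precision=ap,
        paired_tests=paired,
        n_missing=n_missing,
    )


def report_to_dict(report: EvaluationReport) -> dict:
    """JSON-serializable rendering of a report; undefined metrics become None."""
    return {
        "per_set_median": report.per_set_median,
        "per_type_median": report.per_type_median,
        "combined_median": report.combined_median,
        "approved_percentiles": report.approved_percentiles,
        "average_precision": report.average_precision,
        "pr_curve": [[r, p] for r, p in report.pr_curve],
        "paired_tests": {
            k: {"t": v.t, "p": v.p, "n": v.n} for k, v in report.paired_tests.items()
        },
        "n_missing": report.n_missing,
        "rank_scale": report.rank_scale,
    }
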