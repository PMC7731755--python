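"""Comparison metrics for the linking methods.

Three metrics summarize each method: how many clusters were linked at all
(data retained), how many facilities each linked cluster was joined to
(precision of the linkage), and the share of modern-contraception users
whose cluster was linked to at least one facility of the *type* they last
reported receiving their method from (appropriateness -- an upper bound on
linkage to the facility actually used).  On synthetic landscapes a fourth,
oracle metric is available: the share of women whose *true* source unit is
in the link set.

Appropriateness matches the four linkable source categories against the
(kind, operator) pairs present anywhere in a linked unit: government
hospital / health center / health post require that exact pair; CHAM
matches a CHAM-operated member of any level, since CHAM facilities are
collapsed into a single source type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .model import (
    FacilityKind,
    FacilityUnit,
    IntegrityError,
    LastSource,
    LINKABLE_SOURCES,
    LinkageResult,
    Operator,
    Respondent,
    ValidationError,
)

#: match requirement per linkable source category; None kind = any level
SOURCE_MATCH = {
    LastSource.GOV_HOSPITAL: (FacilityKind.HOSPITAL, Operator.GOVERNMENT),
    LastSource.GOV_HEALTH_CENTER: (FacilityKind.HEALTH_CENTER, Operator.GOVERNMENT),
    LastSource.GOV_HEALTH_POST: (FacilityKind.HEALTH_POST, Operator.GOVERNMENT),
    LastSource.CHAM: (None, Operator.CHAM),
}


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero to the table's printed precision (applied
    at render time only)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def clusters_linked(result: LinkageResult) -> tuple[int, float]:
    """Number and percent of clusters linked to at least one facility."""
    n = result.n_clusters()
    if n == 0:
        raise ValidationError("linkage result covers zero clusters")
    n_linked = len(result.linked_ids())
    return n_linked, 100.0 * n_linked / n


def links_per_cluster(result: LinkageResult, linked_only: bool = True) -> tuple[float, float]:
    """Mean and population SD of link-set sizes.

    The headline figure counts linked clusters only; pass
    ``linked_only=False`` to include zero-link clusters.
    """
    sizes = [len(s) for s in result.links.values() if s or not linked_only]
    if not sizes:
        raise ValidationError("no linked clusters; links-per-cluster undefined")
    mean = sum(sizes) / len(sizes)
    var = sum((s - mean) ** 2 for s in sizes) / len(sizes)
    return mean, math.sqrt(var)


def _matches(source: LastSource, unit: FacilityUnit) -> bool:
    kind, operator = SOURCE_MATCH[source]
    if kind is None:
        return unit.offers_operator(operator)
    return unit.offers(kind, operator)


def _eligible(respondents: Sequence[Respondent]) -> list[Respondent]:
    return [r for r in respondents if r.modern_user and r.last_source in LINKABLE_SOURCES]


def appropriateness(
    result: LinkageResult,
    respondents: Sequence[Respondent],
    units: Sequence[FacilityUnit],
) -> tuple[dict[LastSource, tuple[int, float]], float]:
    """Per-source (n_women, pct_appropriate) and the overall percentage.

    Restricted to modern users with a linkable last source.  The overall
    rate is the count-weighted average of the per-source rates (an exact
    identity before rounding).
    """
    unit_by_id = {u.facility_id: u for u in units}
    counts = {s: 0 for s in LINKABLE_SOURCES}
    matched = {s: 0 for s in LINKABLE_SOURCES}
    for r in _eligible(respondents):
        if r.cluster_id not in result.links:
            raise IntegrityError(f"respondent {r.id!r} in cluster {r.cluster_id!r} absent from linkage result")
        counts[r.last_source] += 1
        linked = result.links[r.cluster_id]
        if any(_matches(r.last_source, unit_by_id[f]) for f in linked if f in unit_by_id):
            matched[r.last_source] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("no eligible (linkable) respondents")
    per_source = {
        s: (counts[s], 100.0 * matched[s] / counts[s] if counts[s] else float("nan"))
        for s in LINKABLE_SOURCES
    }
    overall = 100.0 * sum(matched.values()) / total
    return per_source, overall


def weighted_overall(per_source: dict[LastSource, tuple[int, float]]) -> float:
    """Count-weighted average of per-source appropriateness rates -- the
    arithmetic identity that ties a report's Overall row to its body."""
    total = sum(n for n, _ in per_source.values())
    if total == 0:
        raise ValidationError("empty per-source table")
    return sum(n * pct for n, pct in per_source.values() if n) / total


def true_source_linked(
    result: LinkageResult,
    ground_truth: dict[str, str],
    respondents: Sequence[Respondent],
) -> float:
    """Percent of eligible women whose *true* source unit is in their
    cluster's link set (synthetic landscapes only)."""
    if not ground_truth:
        raise ValidationError("ground truth unavailable")
    eligible = [r for r in _eligible(respondents) if r.id in ground_truth]
    if not eligible:
        raise ValidationError("no eligible respondents with ground truth")
    hit = sum(1 for r in eligible if ground_truth[r.id] in result.links.get(r.cluster_id, frozenset()))
    return 100.0 * hit / len(eligible)


def contraceptive_mix(respondents: Sequence[Respondent]) -> pd.DataFrame:
    """Column-percent contraceptive mix for eligible vs ineligible modern
    users (mirrors the inclusion-comparison table)."""
    users = [r for r in respondents if r.modern_user and r.method]
    if not users:
        raise ValidationError("no modern users with method labels")
    rows = []
    eligible_ids = {r.id for r in _eligible(respondents)}
    for r in users:
        rows.append({"method": r.method, "stratum": "included" if r.id in eligible_ids else "ineligible"})
    df = pd.DataFrame(rows)
    out = df.value_counts(["stratum", "method"]).unstack("stratum", fill_value=0)
    for col in ("included", "ineligible"):
        if col not in out.columns:
            out[col] = 0
        out[f"{col}_pct"] = 100.0 * out[col] / out[col].sum() if out[col].sum() else 0.0
    return out.sort_values("included", ascending=False).reset_index()


@dataclass
class MethodReport:
    method: str
    n_clusters: int
    n_linked: int
    pct_linked: float
    mean_links: float
    sd_links: float
    mean_links_all: float
    sd_links_all: float
    per_source: dict[LastSource, tuple[int, float]]
    overall_pct_appropriate: float
    pct_true_source_linked: Optional[float] = None


def method_report(
    result: LinkageResult,
    respondents: Sequence[Respondent],
    units: Sequence[FacilityUnit],
    ground_truth: Optional[dict[str, str]] = None,
) -> MethodReport:
    n_linked, pct = clusters_linked(result)
    mean_l, sd_l = links_per_cluster(result, linked_only=True)
    mean_a, sd_a = links_per_cluster(result, linked_only=False)
    per_source, overall = appropriateness(result, respondents, units)
    truth_pct = None
    if ground_truth:
        truth_pct = true_source_linked(result, ground_truth, respondents)
    return MethodReport(
        method=result.method.value,
        n_clusters=result.n_clusters(),
        n_linked=n_linked,
        pct_linked=pct,
        mean_links=mean_l,
        sd_links=sd_l,
        mean_links_all=mean_a,
        sd_links_all=sd_a,
        per_source=per_source,
        overall_pct_appropriate=overall,
        pct_true_source_linked=truth_pct,
    )


def compare_methods(
    results: Sequence[LinkageResult],
    respondents: Sequence[Respondent],
    units: Sequence[FacilityUnit],
    ground_truth: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """One report row per method, in the layout of the published summary
    tables (cluster linkage counts, links per cluster, per-source and
    overall appropriateness)."""
    cluster_sets = {frozenset(r.links) for r in results}
    if len(cluster_sets) > 1:
        raise IntegrityError("linkage results cover different cluster sets")
    rows = []
    for res in results:
        rep = method_report(res, respondents, units, ground_truth)
        row = {
            "method": rep.method,
            "n_clusters": rep.n_clusters,
            "n_linked": rep.n_linked,
            "pct_linked": round_half_up(rep.pct_linked, 1),
            "mean_links": round_half_up(rep.mean_links, 1),
            "sd_links": round_half_up(rep.sd_links, 2),
            "mean_links_all": round_half_up(rep.mean_links_all, 1),
            "sd_links_all": round_half_up(rep.sd_links_all, 2),
        }
        label = {
            LastSource.GOV_HOSPITAL: "hospitals",
            LastSource.GOV_HEALTH_CENTER: "health_centers",
            LastSource.GOV_HEALTH_POST: "health_posts",
            LastSource.CHAM: "cham",
        }
        for s, (n, pct) in rep.per_source.items():
            row[f"n_{label[s]}"] = n
            row[f"pct_appropriate_{label[s]}"] = round_half_up(pct, 1) if n else float("nan")
        row["overall_pct_appropriate"] = round_half_up(rep.overall_pct_appropriate, 1)
        if rep.pct_true_source_linked is not None:
            row["pct_true_source_linked"] = round_half_up(rep.pct_true_source_linked, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def render_text(report: pd.DataFrame) -> str:
    """Aligned text rendering of the comparison report."""
    return report.to_string(index=False, na_rep="--")
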