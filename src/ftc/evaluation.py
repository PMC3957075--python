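"""Precision/recall of an FTC build against ATC gold annotations.

The unit of scoring is the *evaluation point*: a curator-asserted
equivalence between one FTC category and one or more ATC codes (at any
level; ATC levels are code prefixes).  Scoring is restricted to a drug
universe present in both classifications.  For each point,

    TP: drugs in the FTC category (direct or indirect) AND under a matching
        ATC prefix;
    FN: drugs under the ATC prefix but missing from the FTC category;
    FP: drugs in the FTC category but outside every matching ATC prefix.

Drugs without any ATC code are outside the universe and can never be false
positives — such extra memberships are repurposing hypotheses, not errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .classifier import FtcBuild
from .ontology_io import AtcAnnotation, EvaluationPoint


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def precision(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def recall(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


@dataclass
class PointResult:
    point: EvaluationPoint
    counts: ConfusionCounts
    tp_drugs: frozenset[str] = frozenset()
    fp_drugs: frozenset[str] = frozenset()
    fn_drugs: frozenset[str] = frozenset()
    error: str | None = None


@dataclass
class EvaluationReport:
    points: list[PointResult]
    totals: ConfusionCounts
    precision: float
    recall: float
    covered_drugs: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "totals": {"tp": self.totals.tp, "fp": self.totals.fp, "fn": self.totals.fn},
            "precision": self.precision,
            "recall": self.recall,
            "precision_pct": round(100 * self.precision),
            "recall_pct": round(100 * self.recall),
            "covered_drugs": self.covered_drugs,
            "n_points": len(self.points),
            "notes": list(self.notes),
            "points": [
                {
                    "ftc_category_id": r.point.ftc_category_id,
                    "atc_codes": sorted(r.point.atc_codes),
                    "tp": r.counts.tp,
                    "fp": r.counts.fp,
                    "fn": r.counts.fn,
                    "error": r.error,
                }
                for r in self.points
            ],
        }


def _atc_match(ann: AtcAnnotation | None, prefixes: frozenset[str]) -> bool:
    if ann is None:
        return False
    return any(code.startswith(p) for code in ann.atc_codes for p in prefixes)


def evaluate_point(
    point: EvaluationPoint,
    build: FtcBuild,
    atc: Mapping[str, AtcAnnotation],
    universe: set[str],
) -> PointResult:
    """Score one evaluation point over the given drug universe."""
    if point.ftc_category_id not in build.taxonomy.categories:
        raise KeyError(f"unknown FTC category {point.ftc_category_id}")
    in_category = {
        m.drug_id for m in build.memberships if m.category_id == point.ftc_category_id
    }
    ftc_pos = in_category & universe
    atc_pos = {d for d in universe if _atc_match(atc.get(d), point.atc_codes)}
    tp = ftc_pos & atc_pos
    fp = ftc_pos - atc_pos
    fn = atc_pos - ftc_pos
    return PointResult(
        point=point,
        counts=ConfusionCounts(len(tp), len(fp), len(fn)),
        tp_drugs=frozenset(tp),
        fp_drugs=frozenset(fp),
        fn_drugs=frozenset(fn),
    )


def aggregate_and_score(point_results: Sequence[PointResult]) -> EvaluationReport:
    """Sum counts across points and derive overall precision/recall.

    A drug participating in several points is counted once per point in the
    totals; ``covered_drugs`` counts unique drugs touched by any point.
    """
    totals = ConfusionCounts()
    covered: set[str] = set()
    notes: list[str] = []
    for r in point_results:
        if r.error:
            notes.append(f"{r.point.ftc_category_id}: {r.error}")
            continue
        totals = totals + r.counts
        covered |= r.tp_drugs | r.fp_drugs | r.fn_drugs
    if not point_results:
        notes.append("no evaluation performed")
    return EvaluationReport(
        points=list(point_results),
        totals=totals,
        precision=precision(totals),
        recall=recall(totals),
        covered_drugs=len(covered),
        notes=notes,
    )


def evaluate_build(
    build: FtcBuild,
    atc: Mapping[str, AtcAnnotation],
    points: Sequence[EvaluationPoint],
    universe: set[str] | None = None,
) -> EvaluationReport:
    """Score a build against all evaluation points.

    The default universe is the intersection of the build's drugs with the
    drugs carrying at least one ATC code.  A point referencing an unknown
    FTC category is reported as an error and the remaining points are still
    scored.
    """
    if universe is None:
        universe = {d.drug_id for d in build.drugs} & set(atc)
    results: list[PointResult] = []
    for point in points:
        try:
            results.append(evaluate_point(point, build, atc, universe))
        except KeyError as exc:
            results.append(
                PointResult(point=point, counts=ConfusionCounts(), error=str(exc))
            )
    return aggregate_and_score(results)
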