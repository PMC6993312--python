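"""Evaluation against gold labels and facility-level stratification.

Metrics follow the standard screening definitions: sensitivity
tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp), NPV tn/(tn+fn).
A metric whose denominator is zero is reported as ``None`` (undefined),
never silently as 0 or 1 — degenerate cohorts (e.g. no gold negatives)
are common in high-compliance settings and must not masquerade as perfect
performance.

Facility stratification reports, for every facility meeting a minimum
procedure volume (default 50), the fraction of its procedures flagged
positive, banded as high (> 80%), middle (60–80%, both bounds included)
or low (< 60%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detector import AlgorithmVariant, ProcedureFlagResult, classify_cohort
from .emr_model import Cohort, GoldLabel
from .errors import ValidationError
from .lexicon import Lexicon

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "FacilityComplianceRow",
    "confusion",
    "compute_metrics",
    "evaluate",
    "variant_sweep",
    "stratify_by_facility",
    "compliance_band",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_gold_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_gold_negative(self) -> int:
        return self.tn + self.fp

    @property
    def flagged_count(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    flagged_count: int
    flagged_fraction: float | None
    n_total: int
    n_gold_positive: int
    n_gold_negative: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "flagged_count": self.flagged_count,
            "flagged_fraction": self.flagged_fraction,
            "n_total": self.n_total,
            "n_gold_positive": self.n_gold_positive,
            "n_gold_negative": self.n_gold_negative,
        }


def confusion(
    results: Sequence[ProcedureFlagResult],
    labels: Iterable[GoldLabel] | Mapping[str, bool],
) -> ConfusionCounts:
    """Tally the confusion matrix of flags against gold labels.

    Every result's procedure must carry exactly one label; missing labels
    raise with the offending ids listed.
    """
    if isinstance(labels, Mapping):
        label_map = dict(labels)
    else:
        label_map = {}
        for lab in labels:
            if lab.procedure_id in label_map:
                raise ValidationError(
                    f"multiple gold labels for procedure {lab.procedure_id!r}"
                )
            label_map[lab.procedure_id] = lab.prophylaxis_given
    missing = sorted(r.procedure_id for r in results if r.procedure_id not in label_map)
    if missing:
        raise ValidationError(f"unlabeled procedure(s): {missing[:20]}")
    tp = fp = tn = fn = 0
    for r in results:
        gold = label_map[r.procedure_id]
        if r.final_flag and gold:
            tp += 1
        elif r.final_flag and not gold:
            fp += 1
        elif not r.final_flag and not gold:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(counts: ConfusionCounts, n_total: int | None = None) -> MetricsReport:
    """Derive the four screening metrics (and flagged fraction) from counts."""
    if n_total is not None and n_total != counts.n_total:
        raise ValidationError(
            f"n_total={n_total} inconsistent with counts (sum={counts.n_total})"
        )
    n = counts.n_total
    return MetricsReport(
        sensitivity=_ratio(counts.tp, counts.n_gold_positive),
        specificity=_ratio(counts.tn, counts.n_gold_negative),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
        flagged_count=counts.flagged_count,
        flagged_fraction=_ratio(counts.flagged_count, n),
        n_total=n,
        n_gold_positive=counts.n_gold_positive,
        n_gold_negative=counts.n_gold_negative,
    )


def evaluate(
    cohort: Cohort, lexicon: Lexicon, variant: AlgorithmVariant
) -> tuple[ConfusionCounts, MetricsReport]:
    """Classify a labeled cohort under one variant and score it."""
    if cohort.labels is None:
        raise ValidationError("evaluation requires gold labels")
    results = classify_cohort(cohort, lexicon, variant)
    counts = confusion(results, cohort.labels)
    return counts, compute_metrics(counts)


def variant_sweep(
    cohort: Cohort,
    lexicon: Lexicon,
    variants: Sequence[tuple[str, AlgorithmVariant]] | Mapping[str, AlgorithmVariant],
) -> pd.DataFrame:
    """Score several variants on one labeled cohort (development-table style).

    Returns one row per variant in input order with counts and the four
    metrics; undefined metrics appear as NaN in the frame.
    """
    items = list(variants.items()) if isinstance(variants, Mapping) else list(variants)
    rows = []
    for name, variant in items:
        counts, metrics = evaluate(cohort, lexicon, variant)
        rows.append(
            {
                "variant": name,
                "flagged_n": metrics.flagged_count,
                "flagged_pct": (
                    100 * metrics.flagged_fraction
                    if metrics.flagged_fraction is not None
                    else float("nan")
                ),
                "ppv": metrics.ppv,
                "npv": metrics.npv,
                "sensitivity": metrics.sensitivity,
                "specificity": metrics.specificity,
                "tp": counts.tp,
                "fp": counts.fp,
                "tn": counts.tn,
                "fn": counts.fn,
            }
        )
    return pd.DataFrame(rows)


def compliance_band(rate: float) -> str:
    """Band a facility compliance rate: high > 0.8, middle [0.6, 0.8], low < 0.6."""
    if rate > 0.8:
        return "high"
    if rate >= 0.6:
        return "middle"
    return "low"


@dataclass(frozen=True)
class FacilityComplianceRow:
    facility_id: str
    n_procedures: int
    compliance_rate: float
    band: str


def stratify_by_facility(
    results: Sequence[ProcedureFlagResult],
    cohort: Cohort,
    min_volume: int = 50,
) -> list[FacilityComplianceRow]:
    """Per-facility flagged fraction, restricted to facilities with volume
    >= ``min_volume``; rows sorted by facility_id."""
    facility_of = {p.procedure_id: p.facility_id for p in cohort.procedures}
    missing = sorted(r.procedure_id for r in results if r.procedure_id not in facility_of)
    if missing:
        raise ValidationError(f"results not in cohort: {missing[:20]}")
    totals: dict[str, int] = {}
    flagged: dict[str, int] = {}
    for r in results:
        fac = facility_of[r.procedure_id]
        totals[fac] = totals.get(fac, 0) + 1
        if r.final_flag:
            flagged[fac] = flagged.get(fac, 0) + 1
    rows = []
    for fac in sorted(totals):
        n = totals[fac]
        if n < min_volume:
            continue
        rate = flagged.get(fac, 0) / n
        rows.append(
            FacilityComplianceRow(
                facility_id=fac,
                n_procedures=n,
                compliance_rate=rate,
                band=compliance_band(rate),
            )
        )
    return rows


def facility_frame(rows: Sequence[FacilityComplianceRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "facility_id": r.facility_id,
                "n": r.n_procedures,
                "rate": r.compliance_rate,
                "band": r.band,
            }
            for r in rows
        ]
    )
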