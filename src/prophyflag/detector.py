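"""Per-procedure prophylaxis detection: the core flagging algorithm.

A procedure is flagged as having received pre-incisional antimicrobial
prophylaxis when any enabled data source produces a hit:

* **text** — a searchable clinical note signed within the lookback window
  (7 days before through the procedure date, inclusive) contains an
  antimicrobial name from the note lexicon;
* **orders** — a computerized-entry medication order for a filter-surviving
  agent falls in the window, optionally capped at < 24 h duration and cut
  at the procedure time on the procedure day;
* **administration** — a bar-code medication administration of a
  filter-surviving agent occurs in the window, strictly before the
  procedure time.

The refinement filters (oral-only exclusion, common-prophylaxis
restriction, order-duration cap, same-day post-procedure order exclusion,
day-of-procedure note exclusion, "prophylaxis" pseudo-term) are all
switchable per :class:`AlgorithmVariant`; :data:`FINAL_VARIANT` is the
configuration that performed best in development (text + orders with all
order-side filters on).

Window semantics: note windows compare calendar dates; order windows use
calendar dates for the in-window test and timestamps only for the same-day
post-procedure cut; administration windows use the timestamp upper bound
(post-procedure administration is guideline-discordant and never counts).
All bounds are inclusive.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Sequence

from .emr_model import (
    ClinicalNote,
    Cohort,
    MedicationAdministration,
    MedicationOrder,
    Procedure,
)
from .errors import ValidationError
from .lexicon import Lexicon, TermMatch, TermMatcher, build_matcher, normalize_term

logger = logging.getLogger(__name__)

__all__ = [
    "AlgorithmVariant",
    "FINAL_VARIANT",
    "VARIANT_PRESETS",
    "ProcedureFlagResult",
    "OrderEvidence",
    "AdminEvidence",
    "flag_text",
    "flag_orders",
    "flag_admin",
    "classify_procedure",
    "classify_cohort",
    "save_results",
    "variant_from_dict",
]


@dataclass(frozen=True)
class AlgorithmVariant:
    """One configuration of data sources and filter rules."""

    use_text: bool = True
    use_orders: bool = False
    use_admin: bool = False
    exclude_oral_only: bool = False
    restrict_common_prophylaxis: bool = False
    max_order_duration_hours: float | None = None
    exclude_same_day_post_procedure_orders: bool = False
    exclude_day_of_procedure_notes: bool = False
    include_prophylaxis_term: bool = False
    window_days: int = 7
    #: Policy for procedures recorded without a time-of-day: treat same-day
    #: orders/administrations as pre-procedure (True, default) or as
    #: indeterminate and excluded (False).
    missing_time_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (self.use_text or self.use_orders or self.use_admin):
            raise ValidationError("variant enables no data source")
        if self.window_days < 1:
            raise ValidationError("window_days must be >= 1")


#: The production configuration: note text + orders, oral-only agents and
#: rarely-prophylactic agents excluded, orders capped at < 24 h and cut at
#: the procedure time on the procedure day, 7-day lookback.
FINAL_VARIANT = AlgorithmVariant(
    use_text=True,
    use_orders=True,
    use_admin=False,
    exclude_oral_only=True,
    restrict_common_prophylaxis=True,
    max_order_duration_hours=24,
    exclude_same_day_post_procedure_orders=True,
    exclude_day_of_procedure_notes=False,
    include_prophylaxis_term=False,
    window_days=7,
)

#: Named presets covering each development-stage configuration: the single
#: sources, their combinations, and the round-2 refinements.
VARIANT_PRESETS: dict[str, AlgorithmVariant] = {
    "text": AlgorithmVariant(use_text=True),
    "orders": AlgorithmVariant(use_text=False, use_orders=True),
    "administration": AlgorithmVariant(use_text=False, use_admin=True),
    "text+orders": AlgorithmVariant(use_text=True, use_orders=True),
    "text+administration": AlgorithmVariant(use_text=True, use_admin=True),
    "orders+administration": AlgorithmVariant(
        use_text=False, use_orders=True, use_admin=True
    ),
    "text+orders+administration": AlgorithmVariant(
        use_text=True, use_orders=True, use_admin=True
    ),
    "round2-exclude-oral": AlgorithmVariant(
        use_text=True, use_orders=True, exclude_oral_only=True
    ),
    "round2-common-agents": FINAL_VARIANT,
    "round2-exclude-day-of-notes": replace(
        FINAL_VARIANT, exclude_day_of_procedure_notes=True
    ),
    "round2-prophylaxis-term": replace(FINAL_VARIANT, include_prophylaxis_term=True),
    "final": FINAL_VARIANT,
}


def variant_from_dict(data: dict) -> AlgorithmVariant:
    """Build a variant from a config mapping (unknown keys rejected)."""
    allowed = set(AlgorithmVariant.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown variant field(s) {sorted(unknown)}")
    return AlgorithmVariant(**data)


@dataclass(frozen=True)
class OrderEvidence:
    order_id: str
    canonical_name: str
    drug_name: str


@dataclass(frozen=True)
class AdminEvidence:
    admin_id: str
    canonical_name: str
    drug_name: str


@dataclass(frozen=True)
class ProcedureFlagResult:
    procedure_id: str
    text_hit: bool
    order_hit: bool
    admin_hit: bool
    final_flag: bool
    evidence: tuple = ()


def _note_window(procedure: Procedure, variant: AlgorithmVariant) -> tuple[date, date]:
    hi = procedure.procedure_date
    if variant.exclude_day_of_procedure_notes:
        hi = hi - timedelta(days=1)
    lo = procedure.procedure_date - timedelta(days=variant.window_days)
    return lo, hi


def flag_text(
    procedure: Procedure,
    notes: Iterable[ClinicalNote],
    matcher: TermMatcher,
    variant: AlgorithmVariant,
) -> tuple[bool, list[TermMatch]]:
    """Search the patient's searchable in-window notes for lexicon hits."""
    lo, hi = _note_window(procedure, variant)
    evidence: list[TermMatch] = []
    for note in notes:
        if note.patient_id != procedure.patient_id:
            continue
        if not note.is_searchable:
            continue  # scanned paper/PDF notes are opaque to text search
        if not (lo <= note.signed_date <= hi):
            continue
        evidence.extend(matcher.find(note.text, source_id=note.note_id))
    return bool(evidence), evidence


def flag_orders(
    procedure: Procedure,
    orders: Iterable[MedicationOrder],
    lexicon: Lexicon,
    variant: AlgorithmVariant,
) -> tuple[bool, list[OrderEvidence]]:
    """Flag from computerized-entry orders, applying the variant's filters."""
    alias_map = lexicon.structured_alias_map(variant)
    lo = procedure.procedure_date - timedelta(days=variant.window_days)
    hi = procedure.procedure_date
    evidence: list[OrderEvidence] = []
    for o in orders:
        if o.patient_id != procedure.patient_id:
            continue
        canonical = alias_map.get(normalize_term(o.drug_name))
        if canonical is None:
            continue
        odate = o.order_datetime.date()
        if not (lo <= odate <= hi):
            continue
        if variant.exclude_same_day_post_procedure_orders and odate == hi:
            if procedure.time_known:
                if o.order_datetime > procedure.procedure_datetime:
                    continue
            elif not variant.missing_time_inclusive:
                continue
        if variant.max_order_duration_hours is not None:
            if o.stop_datetime is None:
                # Single pre-op doses often lack a stop time; they pass the
                # duration cap rather than being discarded wholesale.
                logger.warning(
                    "order %s has no stop_datetime; duration cap not applied",
                    o.order_id,
                )
            else:
                hours = (o.stop_datetime - o.order_datetime) / timedelta(hours=1)
                if hours >= variant.max_order_duration_hours:
                    continue
        evidence.append(OrderEvidence(o.order_id, canonical, o.drug_name))
    return bool(evidence), evidence


def flag_admin(
    procedure: Procedure,
    administrations: Iterable[MedicationAdministration],
    lexicon: Lexicon,
    variant: AlgorithmVariant,
) -> tuple[bool, list[AdminEvidence]]:
    """Flag from bar-code administrations; post-procedure ones never count."""
    alias_map = lexicon.structured_alias_map(variant)
    lo = procedure.procedure_date - timedelta(days=variant.window_days)
    evidence: list[AdminEvidence] = []
    for a in administrations:
        if a.patient_id != procedure.patient_id:
            continue
        canonical = alias_map.get(normalize_term(a.drug_name))
        if canonical is None:
            continue
        adate = a.admin_datetime.date()
        if adate < lo:
            continue
        if procedure.time_known:
            if a.admin_datetime > procedure.procedure_datetime:
                continue
        else:
            if adate > procedure.procedure_date:
                continue
            if adate == procedure.procedure_date and not variant.missing_time_inclusive:
                continue
        evidence.append(AdminEvidence(a.admin_id, canonical, a.drug_name))
    return bool(evidence), evidence


def classify_procedure(
    procedure: Procedure,
    cohort: Cohort,
    lexicon: Lexicon,
    variant: AlgorithmVariant,
    *,
    matcher: TermMatcher | None = None,
) -> ProcedureFlagResult:
    """Classify one procedure; disabled sources report False with no evidence."""
    if matcher is None and variant.use_text:
        matcher = build_matcher(lexicon, variant)
    text_hit, text_ev = (False, [])
    order_hit, order_ev = (False, [])
    admin_hit, admin_ev = (False, [])
    if variant.use_text:
        text_hit, text_ev = flag_text(procedure, cohort.notes, matcher, variant)
    if variant.use_orders:
        order_hit, order_ev = flag_orders(procedure, cohort.orders, lexicon, variant)
    if variant.use_admin:
        admin_hit, admin_ev = flag_admin(
            procedure, cohort.administrations, lexicon, variant
        )
    return ProcedureFlagResult(
        procedure_id=procedure.procedure_id,
        text_hit=text_hit,
        order_hit=order_hit,
        admin_hit=admin_hit,
        final_flag=text_hit or order_hit or admin_hit,
        evidence=tuple((*text_ev, *order_ev, *admin_ev)),
    )


def classify_cohort(
    cohort: Cohort,
    lexicon: Lexicon,
    variant: AlgorithmVariant = FINAL_VARIANT,
) -> list[ProcedureFlagResult]:
    """Classify every procedure; results are ordered by procedure_id.

    Deterministic and order-independent: shuffling the input records does
    not change the result multiset.
    """
    matcher = build_matcher(lexicon, variant) if variant.use_text else None
    notes_by_pt: dict[str, list[ClinicalNote]] = {}
    for n in cohort.notes:
        notes_by_pt.setdefault(n.patient_id, []).append(n)
    orders_by_pt: dict[str, list[MedicationOrder]] = {}
    for o in cohort.orders:
        orders_by_pt.setdefault(o.patient_id, []).append(o)
    admins_by_pt: dict[str, list[MedicationAdministration]] = {}
    for a in cohort.administrations:
        admins_by_pt.setdefault(a.patient_id, []).append(a)

    results = []
    for proc in sorted(cohort.procedures, key=lambda p: p.procedure_id):
        text_hit, text_ev = (False, [])
        order_hit, order_ev = (False, [])
        admin_hit, admin_ev = (False, [])
        if variant.use_text:
            text_hit, text_ev = flag_text(
                proc,
                sorted(notes_by_pt.get(proc.patient_id, []), key=lambda n: n.note_id),
                matcher,
                variant,
            )
        if variant.use_orders:
            order_hit, order_ev = flag_orders(
                proc,
                sorted(orders_by_pt.get(proc.patient_id, []), key=lambda o: o.order_id),
                lexicon,
                variant,
            )
        if variant.use_admin:
            admin_hit, admin_ev = flag_admin(
                proc,
                sorted(admins_by_pt.get(proc.patient_id, []), key=lambda a: a.admin_id),
                lexicon,
                variant,
            )
        results.append(
            ProcedureFlagResult(
                procedure_id=proc.procedure_id,
                text_hit=text_hit,
                order_hit=order_hit,
                admin_hit=admin_hit,
                final_flag=text_hit or order_hit or admin_hit,
                evidence=tuple((*text_ev, *order_ev, *admin_ev)),
            )
        )
    return results


def save_results(
    results: Sequence[ProcedureFlagResult], directory: str | Path
) -> tuple[Path, Path]:
    """Write per-procedure flags as CSV plus a JSON evidence sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    flags_path = d / "flags.csv"
    with open(flags_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["procedure_id", "text_hit", "order_hit", "admin_hit", "final_flag", "evidence_count"]
        )
        for r in results:
            writer.writerow(
                [
                    r.procedure_id,
                    str(r.text_hit).lower(),
                    str(r.order_hit).lower(),
                    str(r.admin_hit).lower(),
                    str(r.final_flag).lower(),
                    len(r.evidence),
                ]
            )
    evidence_path = d / "evidence.json"
    sidecar = {
        r.procedure_id: [
            {"kind": type(e).__name__, **asdict(e)} for e in r.evidence
        ]
        for r in results
    }
    with open(evidence_path, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return flags_path, evidence_path
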