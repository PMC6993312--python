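"""Synthetic EMR cohort generator with ground-truth prophylaxis labels.

Real pre-incisional-prophylaxis data cannot be redistributed, so testing
relies on synthetic cohorts whose *documentation styles* — not clinical
language — reproduce the misclassification mechanisms observed when the
algorithm was validated against manual chart review.  Each generated case
is drawn from a fixed scenario taxonomy; every scenario is constructed so
that, instantiated on its own and classified under
:data:`~prophyflag.detector.FINAL_VARIANT`, it lands deterministically in a
known confusion-matrix cell:

======================  ====  ========  =============================================
scenario                gold  outcome   documentation mechanism
======================  ====  ========  =============================================
clean_note              yes   TP        drug name typed in an in-window note
order_only              yes   TP        note says "prophylaxis administered", no
                                        drug name; short pre-procedure IV order
undocumented_agent      yes   FN        "antibiotics given" note, no name, no order
scanned_note            yes   FN        drug name only in a scanned (unsearchable) note
late_note               yes   FN        drug-name note signed >= 1 day post-procedure
stale_order             yes   FN        order placed 8–60 days pre-procedure
wrong_date              yes   FN        recorded procedure date shifted; real
                                        documentation falls outside the window
wrong_procedure_type    yes   EXCLUDED  miscoded as cardiac catheterization; removed
                                        by scope filtering before classification
no_documentation        no    TN        nothing anywhere
no_prophylaxis_note     no    TN        procedure note without antimicrobial terms
post_procedure_mention  no    FP        note recommends post-procedure doses by name
unrelated_treatment     no    FP        agent named in note as ongoing treatment;
                                        long-duration order (caught by the 24 h cap,
                                        not by text search)
flush_wash              no    FP        antimicrobial pocket wash named in the note
allergy_mention         no    TN        penicillin allergy documented (agent is
                                        excluded from note searches)
======================  ====  ========  =============================================

One patient per procedure; a single numpy Generator seeded once per cohort,
with per-case draws consumed in fixed order, so equal seeds give
byte-identical cohorts on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Callable, Mapping

import numpy as np

from .emr_model import (
    ClinicalNote,
    Cohort,
    GoldLabel,
    MedicationAdministration,
    MedicationOrder,
    Procedure,
)
from .errors import ValidationError

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "CohortSpec",
    "DEFAULT_POSITIVE_MIX",
    "DEFAULT_NEGATIVE_MIX",
    "ExpectedConfusion",
    "generate_cohort",
    "expected_confusion",
    "single_scenario_spec",
    "spec_from_dict",
]


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: str
    gold_label: bool
    #: Confusion cell under FINAL_VARIANT: TP/FP/TN/FN, or EXCLUDED for
    #: cases removed by scope filtering before classification.
    expected_outcome: str
    description: str = ""


SCENARIOS: dict[str, ScenarioSpec] = {
    s.scenario_id: s
    for s in [
        ScenarioSpec("clean_note", True, "TP", "drug name typed in an in-window note"),
        ScenarioSpec("order_only", True, "TP", "nonspecific note plus pre-procedure order"),
        ScenarioSpec("undocumented_agent", True, "FN", "prophylaxis noted without name or order"),
        ScenarioSpec("scanned_note", True, "FN", "drug name only in scanned paper note"),
        ScenarioSpec("late_note", True, "FN", "drug-name note entered after the procedure date"),
        ScenarioSpec("stale_order", True, "FN", "order placed more than 7 days pre-procedure"),
        ScenarioSpec("wrong_date", True, "FN", "incorrect recorded procedure date"),
        ScenarioSpec("wrong_procedure_type", True, "EXCLUDED", "miscoded procedure type"),
        ScenarioSpec("no_documentation", False, "TN", "no documentation at all"),
        ScenarioSpec("no_prophylaxis_note", False, "TN", "note without antimicrobial terms"),
        ScenarioSpec("post_procedure_mention", False, "FP", "post-procedure doses named in note"),
        ScenarioSpec("unrelated_treatment", False, "FP", "agent named as unrelated treatment"),
        ScenarioSpec("flush_wash", False, "FP", "non-systemic antimicrobial wash named"),
        ScenarioSpec("allergy_mention", False, "TN", "penicillin allergy documented"),
    ]
}

#: Default scenario mixes, grounded in the chart-reviewed development
#: cohort's discordance audit: among 2056 gold positives there were 39
#: false negatives (27 prophylaxis-noted-without-name, 4 stale orders,
#: 3 late-entered notes, 1 scanned-only, 1 wrong date), and among 46 gold
#: negatives 27 false positives (post-procedure mentions dominant, plus
#: unrelated treatment courses and non-systemic washes).  The split of the
#: concordant mass between clean notes and order-only documentation, and
#: among the true-negative mechanisms, is not reported and is set to
#: plausible round values.
DEFAULT_POSITIVE_MIX: dict[str, float] = {
    "clean_note": 0.9000,
    "order_only": 0.0810,
    "undocumented_agent": 0.0130,
    "stale_order": 0.0020,
    "late_note": 0.0015,
    "scanned_note": 0.0015,
    "wrong_date": 0.0010,
}
DEFAULT_NEGATIVE_MIX: dict[str, float] = {
    "post_procedure_mention": 0.40,
    "unrelated_treatment": 0.07,
    "flush_wash": 0.10,
    "no_prophylaxis_note": 0.20,
    "no_documentation": 0.13,
    "allergy_mention": 0.10,
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``prevalence`` defaults to 0.978, the gold-positive fraction observed in
    the algorithm's chart-reviewed development cohort.  ``facility_effects``
    maps a facility id to a scenario id forced on every gold-positive case
    at that facility (e.g. a "paper-notes facility" where positives are
    documented only in scanned notes).
    """

    n_procedures: int = 2000
    n_facilities: int = 10
    prevalence: float = 0.978
    positive_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POSITIVE_MIX)
    )
    negative_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NEGATIVE_MIX)
    )
    facility_effects: Mapping[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_procedures < 0:
            raise ValidationError("n_procedures must be non-negative")
        if self.n_facilities < 1:
            raise ValidationError("n_facilities must be >= 1")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValidationError("prevalence must lie in [0, 1]")
        for label, mix in ((True, self.positive_mix), (False, self.negative_mix)):
            for sid, p in mix.items():
                if sid not in SCENARIOS:
                    raise ValidationError(f"unknown scenario {sid!r}")
                if SCENARIOS[sid].gold_label is not label:
                    raise ValidationError(
                        f"scenario {sid!r} is not a gold-{'positive' if label else 'negative'} scenario"
                    )
                if p < 0:
                    raise ValidationError(f"negative probability for {sid!r}")
            if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValidationError("scenario mix must sum to 1 within its stratum")
        if self.facility_effects:
            facilities = set(facility_ids(self.n_facilities))
            for fac, sid in self.facility_effects.items():
                if fac not in facilities:
                    raise ValidationError(f"facility_effects names unknown facility {fac!r}")
                if sid not in SCENARIOS or not SCENARIOS[sid].gold_label:
                    raise ValidationError(
                        f"facility_effects must force a gold-positive scenario, got {sid!r}"
                    )


def facility_ids(n_facilities: int) -> list[str]:
    return [f"F{i:03d}" for i in range(1, n_facilities + 1)]


def spec_from_dict(data: Mapping) -> CohortSpec:
    allowed = set(CohortSpec.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown cohort-spec field(s) {sorted(unknown)}")
    return CohortSpec(**data)


def single_scenario_spec(scenario_id: str, seed: int = 0) -> CohortSpec:
    """A one-case cohort spec that deterministically instantiates one scenario."""
    scenario = SCENARIOS[scenario_id]
    if scenario.gold_label:
        return CohortSpec(
            n_procedures=1,
            n_facilities=1,
            prevalence=1.0,
            positive_mix={scenario_id: 1.0},
            negative_mix={},
            seed=seed,
        )
    return CohortSpec(
        n_procedures=1,
        n_facilities=1,
        prevalence=0.0,
        positive_mix={},
        negative_mix={scenario_id: 1.0},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scenario builders

# Agents that survive the final variant's filters, with surface-form
# variants used in note text and order fields.
_IV_AGENT_FORMS: dict[str, list[str]] = {
    "cefazolin": ["cefazolin", "Cefazolin", "CEFAZOLIN", "Ancef", "cefazolen"],
    "cefuroxime": ["cefuroxime", "Cefuroxime", "Zinacef"],
    "ceftriaxone": ["ceftriaxone", "Ceftriaxone", "Rocephin"],
    "vancomycin": ["vancomycin", "Vancomycin", "VANCOMYCIN", "vanco"],
    "clindamycin": ["clindamycin", "Clindamycin", "Cleocin"],
    "gentamicin": ["gentamicin", "Gentamicin"],
}
_IV_AGENTS = sorted(_IV_AGENT_FORMS)

_OPENERS = [
    "Patient brought to the EP lab.",
    "Pre-procedure checklist completed.",
    "Consent obtained and timeout performed.",
    "Pacemaker generator change performed today.",
    "Dual-chamber device implantation.",
]
_CLOSERS = [
    "Patient tolerated the procedure well.",
    "No immediate complications.",
    "Hemostasis achieved; pressure dressing applied.",
    "Will monitor overnight.",
    "Follow-up in device clinic in one week.",
]


def _pick(rng: np.random.Generator, items: list[str]) -> str:
    return items[int(rng.integers(0, len(items)))]


def _agent(rng: np.random.Generator) -> tuple[str, str]:
    canonical = _pick(rng, _IV_AGENTS)
    return canonical, _pick(rng, _IV_AGENT_FORMS[canonical])


@dataclass
class _Case:
    procedure: Procedure
    notes: list[ClinicalNote] = field(default_factory=list)
    orders: list[MedicationOrder] = field(default_factory=list)
    administrations: list[MedicationAdministration] = field(default_factory=list)


def _note(case: _Case, idx: int, signed: date, text: str, searchable: bool = True) -> None:
    case.notes.append(
        ClinicalNote(
            note_id=f"{case.procedure.procedure_id}-N{idx}",
            patient_id=case.procedure.patient_id,
            signed_date=signed,
            text=text,
            is_searchable=searchable,
        )
    )


def _order(
    case: _Case,
    idx: int,
    drug: str,
    start: datetime,
    duration_hours: int | None,
    route: str = "IV",
) -> None:
    case.orders.append(
        MedicationOrder(
            order_id=f"{case.procedure.procedure_id}-O{idx}",
            patient_id=case.procedure.patient_id,
            drug_name=drug,
            order_datetime=start,
            stop_datetime=(
                start + timedelta(hours=duration_hours) if duration_hours else None
            ),
            route=route,
        )
    )


def _admin(case: _Case, idx: int, drug: str, when: datetime) -> None:
    case.administrations.append(
        MedicationAdministration(
            admin_id=f"{case.procedure.procedure_id}-A{idx}",
            patient_id=case.procedure.patient_id,
            drug_name=drug,
            admin_datetime=when,
        )
    )


def _build_clean_note(rng: np.random.Generator, case: _Case) -> None:
    canonical, surface = _agent(rng)
    dt = case.procedure.procedure_datetime
    offset = int(rng.integers(0, 3))  # signed 0-2 days before the procedure
    text = (
        f"{_pick(rng, _OPENERS)} {surface} 1 g IV administered prior to incision. "
        f"{_pick(rng, _CLOSERS)}"
    )
    _note(case, 1, case.procedure.procedure_date - timedelta(days=offset), text)
    if rng.random() < 0.5:  # often an order accompanies the note
        hours_before = int(rng.integers(1, 48))
        _order(case, 1, canonical, dt - timedelta(hours=hours_before), int(rng.integers(1, 8)))
        _admin(case, 1, canonical, dt - timedelta(minutes=int(rng.integers(20, 90))))


def _build_order_only(rng: np.random.Generator, case: _Case) -> None:
    canonical, surface = _agent(rng)
    dt = case.procedure.procedure_datetime
    text = (
        f"{_pick(rng, _OPENERS)} Pre-procedure antimicrobial prophylaxis "
        f"administered prior to incision per protocol. {_pick(rng, _CLOSERS)}"
    )
    _note(case, 1, case.procedure.procedure_date, text)
    hours_before = int(rng.integers(2, 140))  # within 7 days, before proc time
    _order(case, 1, surface, dt - timedelta(hours=hours_before), int(rng.integers(1, 8)))


def _build_undocumented_agent(rng: np.random.Generator, case: _Case) -> None:
    text = (
        f"{_pick(rng, _OPENERS)} Antibiotics administered prior to incision; "
        f"see anesthesia record for details. {_pick(rng, _CLOSERS)}"
    )
    _note(case, 1, case.procedure.procedure_date, text)


def _build_scanned_note(rng: np.random.Generator, case: _Case) -> None:
    _, surface = _agent(rng)
    text = (
        f"[scanned anesthesia record] {surface} 1 g IV given before incision. "
        f"{_pick(rng, _CLOSERS)}"
    )
    _note(case, 1, case.procedure.procedure_date, text, searchable=False)


def _build_late_note(rng: np.random.Generator, case: _Case) -> None:
    _, surface = _agent(rng)
    lag = int(rng.integers(1, 4))  # entered 1-3 days after the procedure
    text = (
        f"Procedure note (late entry). {surface} 1 g IV was administered prior "
        f"to incision. {_pick(rng, _CLOSERS)}"
    )
    _note(case, 1, case.procedure.procedure_date + timedelta(days=lag), text)


def _build_stale_order(rng: np.random.Generator, case: _Case) -> None:
    canonical, _ = _agent(rng)
    dt = case.procedure.procedure_datetime
    days_before = int(rng.integers(8, 61))  # strictly outside the 7-day window
    _order(case, 1, canonical, dt - timedelta(days=days_before), int(rng.integers(1, 8)))
    text = f"{_pick(rng, _OPENERS)} Antibiotics per prior order. {_pick(rng, _CLOSERS)}"
    _note(case, 1, case.procedure.procedure_date, text)


def _build_wrong_date(rng: np.random.Generator, case: _Case) -> None:
    # Documentation exists around the *actual* date; the recorded procedure
    # date is shifted forward so the documentation falls outside the window.
    _, surface = _agent(rng)
    actual_date = case.procedure.procedure_date
    shift = int(rng.integers(10, 31))
    case.procedure = replace(
        case.procedure,
        procedure_datetime=case.procedure.procedure_datetime + timedelta(days=shift),
    )
    text = (
        f"{_pick(rng, _OPENERS)} {surface} 1 g IV administered prior to incision. "
        f"{_pick(rng, _CLOSERS)}"
    )
    _note(case, 1, actual_date, text)


def _build_wrong_procedure_type(rng: np.random.Generator, case: _Case) -> None:
    case.procedure = replace(case.procedure, procedure_type="cardiac catheterization")
    _build_clean_note(rng, case)


def _build_no_documentation(rng: np.random.Generator, case: _Case) -> None:
    pass


def _build_no_prophylaxis_note(rng: np.random.Generator, case: _Case) -> None:
    text = (
        f"{_pick(rng, _OPENERS)} Procedure completed without complications; "
        f"no antimicrobials given. {_pick(rng, _CLOSERS)}"
    )
    _note(case, 1, case.procedure.procedure_date, text)


def _build_post_procedure_mention(rng: np.random.Generator, case: _Case) -> None:
    canonical, surface = _agent(rng)
    dt = case.procedure.procedure_datetime
    text = (
        f"{_pick(rng, _OPENERS)} {_pick(rng, _CLOSERS)} Plan: give {surface} 1 g IV "
        f"x 3 doses post-procedure, then Keflex x 5 days."
    )
    _note(case, 1, case.procedure.procedure_date, text)
    # administration happens after the procedure, so it can never count
    _admin(case, 1, canonical, dt + timedelta(hours=int(rng.integers(1, 7))))


def _build_unrelated_treatment(rng: np.random.Generator, case: _Case) -> None:
    # Vancomycin course for an unrelated infection: the long-duration order
    # is caught by the 24 h cap, but the note mention still fires.
    dt = case.procedure.procedure_datetime
    surface = _pick(rng, _IV_AGENT_FORMS["vancomycin"])
    text = (
        f"{_pick(rng, _OPENERS)} Patient on {surface} for treatment of "
        f"bacteremia; continue current course. {_pick(rng, _CLOSERS)}"
    )
    _note(case, 1, case.procedure.procedure_date - timedelta(days=int(rng.integers(0, 3))), text)
    start = dt - timedelta(days=int(rng.integers(1, 6)))
    _order(case, 1, "vancomycin", start, int(rng.integers(5, 11)) * 24)


def _build_flush_wash(rng: np.random.Generator, case: _Case) -> None:
    surface = _pick(rng, _IV_AGENT_FORMS["vancomycin"])
    text = (
        f"{_pick(rng, _OPENERS)} Pocket irrigated with {surface} wash; no "
        f"systemic antimicrobials administered. {_pick(rng, _CLOSERS)}"
    )
    _note(case, 1, case.procedure.procedure_date, text)


def _build_allergy_mention(rng: np.random.Generator, case: _Case) -> None:
    form = _pick(rng, ["penicillin", "Penicillin", "PCN"])
    text = (
        f"{_pick(rng, _OPENERS)} Allergies: {form} (rash). "
        f"{_pick(rng, _CLOSERS)}"
    )
    _note(case, 1, case.procedure.procedure_date, text)


_BUILDERS: dict[str, Callable[[np.random.Generator, _Case], None]] = {
    "clean_note": _build_clean_note,
    "order_only": _build_order_only,
    "undocumented_agent": _build_undocumented_agent,
    "scanned_note": _build_scanned_note,
    "late_note": _build_late_note,
    "stale_order": _build_stale_order,
    "wrong_date": _build_wrong_date,
    "wrong_procedure_type": _build_wrong_procedure_type,
    "no_documentation": _build_no_documentation,
    "no_prophylaxis_note": _build_no_prophylaxis_note,
    "post_procedure_mention": _build_post_procedure_mention,
    "unrelated_treatment": _build_unrelated_treatment,
    "flush_wash": _build_flush_wash,
    "allergy_mention": _build_allergy_mention,
}


def _draw_scenario(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    ids = sorted(mix)
    probs = np.array([mix[s] for s in ids], dtype=float)
    probs = probs / probs.sum()
    return ids[int(rng.choice(len(ids), p=probs))]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Instantiate a synthetic cohort from a :class:`CohortSpec`.

    Deterministic for a fixed seed.  The returned cohort carries gold
    labels (``review_source="synthetic"``) and per-case scenario
    annotations in ``case_annotations``.
    """
    rng = np.random.default_rng(spec.seed)
    facilities = facility_ids(spec.n_facilities)
    effects = dict(spec.facility_effects or {})
    base = date(2016, 1, 1)

    cases: list[_Case] = []
    labels: list[GoldLabel] = []
    annotations: dict[str, str] = {}
    for i in range(spec.n_procedures):
        pid = f"PT{i:06d}"
        proc_id = f"PR{i:06d}"
        facility = facilities[int(rng.integers(0, len(facilities)))]
        proc_date = base + timedelta(days=int(rng.integers(0, 365)))
        proc_dt = datetime(
            proc_date.year,
            proc_date.month,
            proc_date.day,
            int(rng.integers(7, 18)),
            int(rng.integers(0, 60)),
        )
        gold = bool(rng.random() < spec.prevalence)
        if gold:
            if facility in effects:
                scenario = effects[facility]
            elif not spec.positive_mix:
                raise ValidationError("gold-positive case drawn but positive_mix is empty")
            else:
                scenario = _draw_scenario(rng, spec.positive_mix)
        else:
            if not spec.negative_mix:
                raise ValidationError("gold-negative case drawn but negative_mix is empty")
            scenario = _draw_scenario(rng, spec.negative_mix)
        case = _Case(
            procedure=Procedure(
                procedure_id=proc_id,
                patient_id=pid,
                facility_id=facility,
                procedure_datetime=proc_dt,
            )
        )
        _BUILDERS[scenario](rng, case)
        cases.append(case)
        labels.append(GoldLabel(proc_id, gold, review_source="synthetic"))
        annotations[proc_id] = scenario

    return Cohort(
        procedures=[c.procedure for c in cases],
        notes=[n for c in cases for n in c.notes],
        orders=[o for c in cases for o in c.orders],
        administrations=[a for c in cases for a in c.administrations],
        labels=labels,
        case_annotations=annotations,
    )


@dataclass(frozen=True)
class ExpectedConfusion:
    """Analytic expectation of the confusion matrix (real-valued)."""

    tp: float
    fp: float
    tn: float
    fn: float
    excluded: float = 0.0

    def cell(self, name: str) -> float:
        return getattr(self, name.lower())


def _effective_positive_mix(spec: CohortSpec) -> dict[str, float]:
    """Positive-scenario distribution marginalized over facility effects.

    Facilities are assigned uniformly, so a facility override replaces the
    mix with a point mass for 1/n_facilities of the probability.
    """
    effects = dict(spec.facility_effects or {})
    n_fac = spec.n_facilities
    p_plain = (n_fac - len(effects)) / n_fac
    mix: dict[str, float] = {
        sid: p * p_plain for sid, p in spec.positive_mix.items()
    }
    for sid in effects.values():
        mix[sid] = mix.get(sid, 0.0) + 1.0 / n_fac
    return mix


def expected_confusion(spec: CohortSpec) -> ExpectedConfusion:
    """Expected confusion cells under FINAL_VARIANT, from the scenario mix.

    Every scenario maps deterministically to a cell, so the expectation is
    linear: n × prevalence × mix for gold positives, n × (1 − prevalence) ×
    mix for gold negatives.  Cases excluded by scope filtering are tracked
    separately and contribute to no cell.
    """
    cells = {"TP": 0.0, "FP": 0.0, "TN": 0.0, "FN": 0.0, "EXCLUDED": 0.0}
    n = spec.n_procedures
    for sid, p in _effective_positive_mix(spec).items():
        cells[SCENARIOS[sid].expected_outcome] += n * spec.prevalence * p
    for sid, p in spec.negative_mix.items():
        cells[SCENARIOS[sid].expected_outcome] += n * (1.0 - spec.prevalence) * p
    return ExpectedConfusion(
        tp=cells["TP"],
        fp=cells["FP"],
        tn=cells["TN"],
        fn=cells["FN"],
        excluded=cells["EXCLUDED"],
    )
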