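"""EMR record types, cohort container, readers/writers and deduplication.

Four record roles feed the detection algorithm: procedures, free-text
clinical notes, computerized-entry medication orders, and bar-code
medication administrations.  Notes carry a *calendar date* (they are
windowed by signed day); orders and administrations carry full timestamps
(needed for the same-day post-procedure exclusions).  All datetimes are
naive local timestamps — a single-institution assumption; there is no
timezone arithmetic.

Files are exchanged as UTF-8 CSV (header required, ISO-8601 datetimes,
empty string = absent) or JSONL (one record per line, null = absent).
Malformed rows are collected into a rejects report rather than silently
dropped; structural problems (missing columns, duplicate procedure ids)
raise :class:`~prophyflag.errors.ValidationError`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Any, Iterable, Mapping

from .errors import SchemaError, ValidationError

__all__ = [
    "Procedure",
    "ClinicalNote",
    "MedicationOrder",
    "MedicationAdministration",
    "GoldLabel",
    "Cohort",
    "RejectedRow",
    "RemovalRecord",
    "read_cohort",
    "write_cohort",
    "dedupe_procedures",
    "DEFAULT_TARGET_TYPES",
]

#: Procedure types the algorithm is scoped to; anything else is excluded
#: during deduplication (mirrors removal of miscoded non-device procedures).
DEFAULT_TARGET_TYPES = ("cardiac device",)


def parse_datetime(value: str) -> tuple[datetime, bool]:
    """Parse ISO-8601; returns (datetime, time_known).

    ``YYYY-MM-DD`` yields midnight with ``time_known=False``;
    ``YYYY-MM-DDTHH:MM[:SS]`` (or space-separated) yields the full
    timestamp with ``time_known=True``.
    """
    v = value.strip()
    if "T" in v or " " in v:
        return datetime.fromisoformat(v), True
    d = date.fromisoformat(v)
    return datetime(d.year, d.month, d.day), False


def format_datetime(dt: datetime, time_known: bool = True) -> str:
    if not time_known:
        return dt.date().isoformat()
    return dt.isoformat(timespec="minutes")


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _parse_bool(value: Any) -> bool:
    if isinstance(value, bool):
        return value
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


@dataclass(frozen=True)
class Procedure:
    procedure_id: str
    patient_id: str
    facility_id: str
    procedure_datetime: datetime
    procedure_type: str = "cardiac device"
    #: False when the source recorded a date without a time-of-day.
    time_known: bool = True

    @property
    def procedure_date(self) -> date:
        return self.procedure_datetime.date()


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    patient_id: str
    signed_date: date
    text: str
    #: False for scanned paper/PDF notes: the text is opaque and never matched.
    is_searchable: bool = True


@dataclass(frozen=True)
class MedicationOrder:
    order_id: str
    patient_id: str
    drug_name: str
    order_datetime: datetime
    stop_datetime: datetime | None = None
    route: str | None = None

    def __post_init__(self) -> None:
        if self.stop_datetime is not None and self.stop_datetime < self.order_datetime:
            raise ValidationError(
                f"order {self.order_id}: stop_datetime precedes order_datetime"
            )


@dataclass(frozen=True)
class MedicationAdministration:
    admin_id: str
    patient_id: str
    drug_name: str
    admin_datetime: datetime


@dataclass(frozen=True)
class GoldLabel:
    procedure_id: str
    prophylaxis_given: bool
    review_source: str = "chart-review"


@dataclass(frozen=True)
class RejectedRow:
    table: str
    line: int
    raw: str
    reason: str


@dataclass(frozen=True)
class RemovalRecord:
    procedure_id: str
    reason: str


@dataclass
class Cohort:
    """Container for one EMR extract, with validation bookkeeping."""

    procedures: list[Procedure] = field(default_factory=list)
    notes: list[ClinicalNote] = field(default_factory=list)
    orders: list[MedicationOrder] = field(default_factory=list)
    administrations: list[MedicationAdministration] = field(default_factory=list)
    labels: list[GoldLabel] | None = None
    #: procedure_id → free-form annotation (e.g. synthetic scenario id).
    case_annotations: dict[str, str] | None = None
    orphan_patient_ids: set[str] = field(default_factory=set, compare=False)
    rejects: list[RejectedRow] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for p in self.procedures:
            if p.procedure_id in seen:
                raise ValidationError(f"duplicate procedure_id {p.procedure_id!r}")
            seen.add(p.procedure_id)
        if self.labels is not None:
            lseen: set[str] = set()
            for lab in self.labels:
                if lab.procedure_id in lseen:
                    raise ValidationError(
                        f"multiple gold labels for procedure {lab.procedure_id!r}"
                    )
                lseen.add(lab.procedure_id)
        patients = {p.patient_id for p in self.procedures}
        self.orphan_patient_ids = {
            r.patient_id
            for r in (*self.notes, *self.orders, *self.administrations)
            if r.patient_id not in patients
        }

    def label_map(self) -> dict[str, bool]:
        if self.labels is None:
            raise ValidationError("cohort carries no gold labels")
        return {l.procedure_id: l.prophylaxis_given for l in self.labels}


# ---------------------------------------------------------------------------
# readers / writers

_SCHEMAS: dict[str, tuple[str, ...]] = {
    "procedures": (
        "procedure_id",
        "patient_id",
        "facility_id",
        "procedure_datetime",
        "procedure_type",
    ),
    "notes": ("note_id", "patient_id", "signed_date", "text", "is_searchable"),
    "orders": (
        "order_id",
        "patient_id",
        "drug_name",
        "route",
        "order_datetime",
        "stop_datetime",
    ),
    "administrations": ("admin_id", "patient_id", "drug_name", "admin_datetime"),
    "labels": ("procedure_id", "prophylaxis_given", "review_source"),
    "annotations": ("procedure_id", "scenario_id"),
}

TABLE_FILENAMES = {
    "procedures": "procedures",
    "notes": "notes",
    "orders": "orders",
    "administrations": "administrations",
    "labels": "labels",
    "annotations": "annotations",
}


def _row_to_procedure(row: Mapping[str, Any]) -> Procedure:
    dt, known = parse_datetime(str(row["procedure_datetime"]))
    return Procedure(
        procedure_id=str(row["procedure_id"]),
        patient_id=str(row["patient_id"]),
        facility_id=str(row["facility_id"]),
        procedure_datetime=dt,
        procedure_type=str(row["procedure_type"]),
        time_known=known,
    )


def _row_to_note(row: Mapping[str, Any]) -> ClinicalNote:
    return ClinicalNote(
        note_id=str(row["note_id"]),
        patient_id=str(row["patient_id"]),
        signed_date=date.fromisoformat(str(row["signed_date"]).strip()),
        text=str(row["text"]),
        is_searchable=_parse_bool(row["is_searchable"]),
    )


def _absent(value: Any) -> bool:
    return value is None or (isinstance(value, str) and value.strip() == "")


def _row_to_order(row: Mapping[str, Any]) -> MedicationOrder:
    stop = None
    if not _absent(row.get("stop_datetime")):
        stop, _ = parse_datetime(str(row["stop_datetime"]))
    route = None if _absent(row.get("route")) else str(row["route"])
    start, _ = parse_datetime(str(row["order_datetime"]))
    return MedicationOrder(
        order_id=str(row["order_id"]),
        patient_id=str(row["patient_id"]),
        drug_name=str(row["drug_name"]),
        order_datetime=start,
        stop_datetime=stop,
        route=route,
    )


def _row_to_admin(row: Mapping[str, Any]) -> MedicationAdministration:
    dt, _ = parse_datetime(str(row["admin_datetime"]))
    return MedicationAdministration(
        admin_id=str(row["admin_id"]),
        patient_id=str(row["patient_id"]),
        drug_name=str(row["drug_name"]),
        admin_datetime=dt,
    )


def _row_to_label(row: Mapping[str, Any]) -> GoldLabel:
    return GoldLabel(
        procedure_id=str(row["procedure_id"]),
        prophylaxis_given=_parse_bool(row["prophylaxis_given"]),
        review_source=str(row.get("review_source") or "chart-review"),
    )


_PARSERS = {
    "procedures": _row_to_procedure,
    "notes": _row_to_note,
    "orders": _row_to_order,
    "administrations": _row_to_admin,
    "labels": _row_to_label,
}


def _iter_rows(path: Path, table: str, dialect: str):
    """Yield (line_number, row_mapping); raises SchemaError on bad headers."""
    required = _SCHEMAS[table]
    if dialect == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in required if c not in header]
            if missing:
                raise SchemaError(f"{path}: missing column(s) {missing}")
            yield from enumerate(reader, start=2)
    elif dialect == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if line.strip():
                    yield i, json.loads(line)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")


def _read_table(path: Path, table: str, dialect: str, rejects: list[RejectedRow]):
    parser = _PARSERS[table]
    required = _SCHEMAS[table]
    records = []
    for line_no, row in _iter_rows(path, table, dialect):
        missing = [c for c in required if c not in row]
        if missing and dialect == "jsonl":
            rejects.append(
                RejectedRow(table, line_no, json.dumps(row), f"missing keys {missing}")
            )
            continue
        try:
            records.append(parser(row))
        except (ValueError, KeyError) as exc:
            rejects.append(RejectedRow(table, line_no, repr(dict(row)), str(exc)))
    return records


def read_cohort(
    paths: Mapping[str, str | Path], dialect: str = "csv"
) -> Cohort:
    """Load a cohort from per-table files.

    ``paths`` maps table names (``procedures``, ``notes``, ``orders``,
    ``administrations``, optionally ``labels`` and ``annotations``) to file
    paths.  Missing optional tables are simply absent from the cohort;
    missing required tables raise ``FileNotFoundError``.
    """
    rejects: list[RejectedRow] = []
    tables: dict[str, list] = {}
    for table in ("procedures", "notes", "orders", "administrations"):
        if table not in paths:
            tables[table] = []
            continue
        p = Path(paths[table])
        if not p.exists():
            raise FileNotFoundError(p)
        tables[table] = _read_table(p, table, dialect, rejects)

    labels = None
    if "labels" in paths and Path(paths["labels"]).exists():
        labels = _read_table(Path(paths["labels"]), "labels", dialect, rejects)

    annotations = None
    if "annotations" in paths and Path(paths["annotations"]).exists():
        annotations = {}
        for _, row in _iter_rows(Path(paths["annotations"]), "annotations", dialect):
            annotations[str(row["procedure_id"])] = str(row["scenario_id"])

    return Cohort(
        procedures=tables["procedures"],
        notes=tables["notes"],
        orders=tables["orders"],
        administrations=tables["administrations"],
        labels=labels,
        case_annotations=annotations,
        rejects=rejects,
    )


def cohort_paths(directory: str | Path, dialect: str = "csv") -> dict[str, Path]:
    """Conventional per-table paths inside a cohort directory."""
    ext = "csv" if dialect == "csv" else "jsonl"
    d = Path(directory)
    return {t: d / f"{fn}.{ext}" for t, fn in TABLE_FILENAMES.items()}


def read_cohort_dir(directory: str | Path, dialect: str = "csv") -> Cohort:
    paths = cohort_paths(directory, dialect)
    present = {
        t: p
        for t, p in paths.items()
        if p.exists() or t in ("procedures", "notes", "orders", "administrations")
    }
    return read_cohort(present, dialect=dialect)


def _serialize(cohort: Cohort) -> dict[str, list[dict[str, Any]]]:
    gold = {l.procedure_id: l.prophylaxis_given for l in (cohort.labels or [])}
    out: dict[str, list[dict[str, Any]]] = {
        "procedures": [
            {
                "procedure_id": p.procedure_id,
                "patient_id": p.patient_id,
                "facility_id": p.facility_id,
                "procedure_datetime": format_datetime(p.procedure_datetime, p.time_known),
                "procedure_type": p.procedure_type,
            }
            for p in cohort.procedures
        ],
        "notes": [
            {
                "note_id": n.note_id,
                "patient_id": n.patient_id,
                "signed_date": n.signed_date.isoformat(),
                "text": n.text,
                "is_searchable": "true" if n.is_searchable else "false",
            }
            for n in cohort.notes
        ],
        "orders": [
            {
                "order_id": o.order_id,
                "patient_id": o.patient_id,
                "drug_name": o.drug_name,
                "route": o.route or "",
                "order_datetime": format_datetime(o.order_datetime),
                "stop_datetime": (
                    format_datetime(o.stop_datetime) if o.stop_datetime else ""
                ),
            }
            for o in cohort.orders
        ],
        "administrations": [
            {
                "admin_id": a.admin_id,
                "patient_id": a.patient_id,
                "drug_name": a.drug_name,
                "admin_datetime": format_datetime(a.admin_datetime),
            }
            for a in cohort.administrations
        ],
    }
    if cohort.labels is not None:
        out["labels"] = [
            {
                "procedure_id": l.procedure_id,
                "prophylaxis_given": "true" if l.prophylaxis_given else "false",
                "review_source": l.review_source,
            }
            for l in cohort.labels
        ]
    if cohort.case_annotations is not None:
        out["annotations"] = [
            {
                "procedure_id": pid,
                "scenario_id": sid,
                "gold_label": "true" if gold.get(pid) else "false",
            }
            for pid, sid in cohort.case_annotations.items()
        ]
    return out


def write_cohort(cohort: Cohort, directory: str | Path, dialect: str = "csv") -> dict[str, Path]:
    """Write a cohort's tables into *directory*; returns the paths written."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ext = "csv" if dialect == "csv" else "jsonl"
    written: dict[str, Path] = {}
    serialized = _serialize(cohort)
    for table, rows in serialized.items():
        path = d / f"{TABLE_FILENAMES[table]}.{ext}"
        columns = list(_SCHEMAS[table])
        if table == "annotations":
            columns = ["procedure_id", "scenario_id", "gold_label"]
        if dialect == "csv":
            with open(path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.DictWriter(fh, fieldnames=columns)
                writer.writeheader()
                writer.writerows(rows)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                for row in rows:
                    fh.write(json.dumps(row, sort_keys=True) + "\n")
        written[table] = path
    return written


def write_rejects(cohort: Cohort, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["table", "line", "raw", "reason"])
        for r in cohort.rejects:
            writer.writerow([r.table, r.line, r.raw, r.reason])


# ---------------------------------------------------------------------------
# deduplication / scope filtering

def dedupe_procedures(
    cohort: Cohort,
    target_types: Iterable[str] | None = DEFAULT_TARGET_TYPES,
) -> tuple[Cohort, list[RemovalRecord]]:
    """Collapse duplicate procedures and drop out-of-scope procedure types.

    Procedures identical on (patient_id, procedure_datetime, procedure_type)
    collapse to the one with the smallest procedure_id.  When
    ``target_types`` is given, procedures of any other type are removed.
    Idempotent; every removal is reported with its reason.
    """
    targets = None if target_types is None else {t.lower() for t in target_types}
    removals: list[RemovalRecord] = []
    survivors: dict[tuple, Procedure] = {}
    for p in sorted(cohort.procedures, key=lambda p: p.procedure_id):
        if targets is not None and p.procedure_type.lower() not in targets:
            removals.append(
                RemovalRecord(p.procedure_id, f"out-of-scope type {p.procedure_type!r}")
            )
            continue
        key = (p.patient_id, p.procedure_datetime, p.procedure_type)
        if key in survivors:
            removals.append(
                RemovalRecord(
                    p.procedure_id,
                    f"duplicate of {survivors[key].procedure_id}",
                )
            )
            continue
        survivors[key] = p
    kept_ids = {p.procedure_id for p in survivors.values()}
    original_order = [p for p in cohort.procedures if p.procedure_id in kept_ids]
    deduped = Cohort(
        procedures=original_order,
        notes=cohort.notes,
        orders=cohort.orders,
        administrations=cohort.administrations,
        labels=cohort.labels,
        case_annotations=cohort.case_annotations,
        rejects=cohort.rejects,
    )
    return deduped, removals
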