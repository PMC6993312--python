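"""Small record factories shared across the test modules."""

from datetime import date, datetime

from prophyflag import (
    ClinicalNote,
    Cohort,
    GoldLabel,
    MedicationAdministration,
    MedicationOrder,
    Procedure,
)

PROC_DT = datetime(2016, 6, 15, 10, 30)


def make_procedure(pid="PR1", patient="PT1", facility="F001", dt=PROC_DT,
                   ptype="cardiac device", time_known=True):
    return Procedure(
        procedure_id=pid,
        patient_id=patient,
        facility_id=facility,
        procedure_datetime=dt,
        procedure_type=ptype,
        time_known=time_known,
    )


def make_note(nid="N1", patient="PT1", signed=date(2016, 6, 15),
              text="cefazolin 1 g IV given", searchable=True):
    return ClinicalNote(
        note_id=nid,
        patient_id=patient,
        signed_date=signed,
        text=text,
        is_searchable=searchable,
    )


def make_order(oid="O1", patient="PT1", drug="cefazolin",
               start=datetime(2016, 6, 15, 8, 0), stop=None, route="IV"):
    return MedicationOrder(
        order_id=oid,
        patient_id=patient,
        drug_name=drug,
        order_datetime=start,
        stop_datetime=stop,
        route=route,
    )


def make_admin(aid="A1", patient="PT1", drug="cefazolin",
               when=datetime(2016, 6, 15, 9, 0)):
    return MedicationAdministration(
        admin_id=aid,
        patient_id=patient,
        drug_name=drug,
        admin_datetime=when,
    )


def make_cohort(procedures, notes=(), orders=(), admins=(), labels=None):
    return Cohort(
        procedures=list(procedures),
        notes=list(notes),
        orders=list(orders),
        administrations=list(admins),
        labels=None if labels is None else list(labels),
    )


def label(pid, positive):
    return GoldLabel(procedure_id=pid, prophylaxis_given=positive, review_source="test")
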