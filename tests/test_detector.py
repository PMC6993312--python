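"""Per-source flagging rules, window semantics, and variant composition."""

import dataclasses
from datetime import date, datetime, timedelta

import pytest

import prophyflag as pf
from helpers import PROC_DT, make_admin, make_cohort, make_note, make_order, make_procedure
from prophyflag.detector import (
    FINAL_VARIANT,
    AlgorithmVariant,
    classify_cohort,
    classify_procedure,
    flag_admin,
    flag_orders,
    flag_text,
)
from prophyflag.errors import ValidationError
from prophyflag.lexicon import build_matcher

TEXT_ONLY = AlgorithmVariant(use_text=True)
ORDERS_ONLY = AlgorithmVariant(use_text=False, use_orders=True)
ADMIN_ONLY = AlgorithmVariant(use_text=False, use_admin=True)
PROC = make_procedure()  # 2016-06-15T10:30


class TestVariantValidation:
    def test_no_source_rejected(self):
        with pytest.raises(ValidationError):
            AlgorithmVariant(use_text=False)

    def test_zero_window_rejected(self):
        with pytest.raises(ValidationError):
            AlgorithmVariant(use_text=True, window_days=0)

    def test_final_variant_configuration(self):
        v = FINAL_VARIANT
        assert v.use_text and v.use_orders and not v.use_admin
        assert v.exclude_oral_only and v.restrict_common_prophylaxis
        assert v.max_order_duration_hours == 24
        assert v.exclude_same_day_post_procedure_orders
        assert not v.exclude_day_of_procedure_notes
        assert not v.include_prophylaxis_term
        assert v.window_days == 7


@pytest.fixture(scope="module")
def matcher(lexicon):
    return build_matcher(lexicon, TEXT_ONLY)


class TestFlagText:
    @pytest.mark.parametrize(
        "signed,expected",
        [
            (date(2016, 6, 15), True),   # procedure date included
            (date(2016, 6, 8), True),    # window lower bound (7 days)
            (date(2016, 6, 7), False),   # one day too early
            (date(2016, 6, 16), False),  # post-procedure note never counts
        ],
    )
    def test_note_window(self, lexicon, matcher, signed, expected):
        hit, _ = flag_text(PROC, [make_note(signed=signed)], matcher, TEXT_ONLY)
        assert hit is expected

    def test_day_of_procedure_exclusion(self, matcher):
        variant = dataclasses.replace(TEXT_ONLY, exclude_day_of_procedure_notes=True)
        note = make_note(signed=date(2016, 6, 15))
        assert flag_text(PROC, [note], matcher, TEXT_ONLY)[0]
        assert not flag_text(PROC, [note], matcher, variant)[0]

    def test_scanned_note_is_opaque(self, matcher):
        note = make_note(searchable=False)
        hit, evidence = flag_text(PROC, [note], matcher, TEXT_ONLY)
        assert not hit and evidence == []

    def test_evidence_lists_all_matches(self, matcher):
        notes = [
            make_note("N1", text="ancef given"),
            make_note("N2", text="then vancomycin and cefazolin"),
        ]
        hit, evidence = flag_text(PROC, notes, matcher, TEXT_ONLY)
        assert hit and len(evidence) == 3
        assert {e.source_id for e in evidence} == {"N1", "N2"}


class TestFlagOrders:
    def test_stale_order_outside_window(self, lexicon):
        order = make_order(start=PROC_DT - timedelta(days=10))
        assert not flag_orders(PROC, [order], lexicon, ORDERS_ONLY)[0]

    def test_same_day_post_procedure_exclusion(self, lexicon):
        order = make_order(start=PROC_DT + timedelta(hours=2))
        assert flag_orders(PROC, [order], lexicon, ORDERS_ONLY)[0]
        variant = dataclasses.replace(ORDERS_ONLY, exclude_same_day_post_procedure_orders=True)
        assert not flag_orders(PROC, [order], lexicon, variant)[0]

    def test_duration_cap(self, lexicon):
        order = make_order(start=PROC_DT - timedelta(days=1), stop=PROC_DT + timedelta(hours=48))
        assert flag_orders(PROC, [order], lexicon, ORDERS_ONLY)[0]
        assert not flag_orders(PROC, [order], lexicon, FINAL_VARIANT)[0]

    def test_missing_stop_passes_duration_cap(self, lexicon):
        order = make_order(start=PROC_DT - timedelta(days=1), stop=None)
        assert flag_orders(PROC, [order], lexicon, FINAL_VARIANT)[0]

    def test_oral_only_agent_filtered(self, lexicon):
        order = make_order(drug="Keflex", start=PROC_DT - timedelta(days=1))
        assert flag_orders(PROC, [order], lexicon, ORDERS_ONLY)[0]
        assert not flag_orders(PROC, [order], lexicon, FINAL_VARIANT)[0]

    def test_rarely_prophylactic_agent_filtered(self, lexicon):
        order = make_order(drug="levofloxacin", start=PROC_DT - timedelta(days=1))
        assert flag_orders(PROC, [order], lexicon, ORDERS_ONLY)[0]
        variant = dataclasses.replace(ORDERS_ONLY, restrict_common_prophylaxis=True)
        assert not flag_orders(PROC, [order], lexicon, variant)[0]

    def test_drug_name_needs_exact_normalized_match(self, lexicon):
        order = make_order(drug="cefazolin 1g in NS", start=PROC_DT - timedelta(days=1))
        assert not flag_orders(PROC, [order], lexicon, ORDERS_ONLY)[0]

    def test_missing_procedure_time_policy(self, lexicon):
        proc = make_procedure(dt=datetime(2016, 6, 15), time_known=False)
        order = make_order(start=datetime(2016, 6, 15, 14, 0))
        variant = dataclasses.replace(ORDERS_ONLY, exclude_same_day_post_procedure_orders=True)
        assert flag_orders(proc, [order], lexicon, variant)[0]
        strict = dataclasses.replace(variant, missing_time_inclusive=False)
        assert not flag_orders(proc, [order], lexicon, strict)[0]


class TestFlagAdmin:
    def test_in_window_pre_procedure_administration(self, lexicon):
        admin = make_admin(when=PROC_DT - timedelta(days=1))
        assert flag_admin(PROC, [admin], lexicon, ADMIN_ONLY)[0]

    def test_post_procedure_administration_never_counts(self, lexicon):
        admin = make_admin(when=PROC_DT + timedelta(hours=1))
        assert not flag_admin(PROC, [admin], lexicon, ADMIN_ONLY)[0]

    def test_matches_exhaustive_scan_oracle(self, lexicon):
        cohort = pf.generate_cohort(pf.CohortSpec(n_procedures=150, seed=2))
        alias_map = lexicon.structured_alias_map(ADMIN_ONLY)
        for proc in cohort.procedures:
            expected = any(
                a.patient_id == proc.patient_id
                and pf.lexicon.normalize_term(a.drug_name) in alias_map
                and a.admin_datetime <= proc.procedure_datetime
                and a.admin_datetime.date()
                >= proc.procedure_date - timedelta(days=ADMIN_ONLY.window_days)
                for a in cohort.administrations
            )
            got, _ = flag_admin(proc, cohort.administrations, lexicon, ADMIN_ONLY)
            assert got == expected


class TestClassify:
    def test_disabled_sources_report_false_with_no_evidence(self, lexicon):
        cohort = make_cohort([PROC], orders=[make_order(start=PROC_DT - timedelta(hours=2))])
        result = classify_procedure(PROC, cohort, lexicon, FINAL_VARIANT)
        assert result.order_hit and not result.text_hit and not result.admin_hit
        assert result.final_flag
        assert result.evidence

    def test_all_sources_miss(self, lexicon):
        cohort = make_cohort([PROC])
        result = classify_procedure(PROC, cohort, lexicon, FINAL_VARIANT)
        assert not result.final_flag and result.evidence == ()

    def test_empty_cohort(self, lexicon):
        assert classify_cohort(make_cohort([]), lexicon, FINAL_VARIANT) == []

    def test_final_flag_is_or_of_recomputed_source_flags(self, lexicon):
        cohort = pf.generate_cohort(pf.CohortSpec(n_procedures=300, seed=7))
        variant = AlgorithmVariant(use_text=True, use_orders=True, use_admin=True)
        results = {r.procedure_id: r for r in classify_cohort(cohort, lexicon, variant)}
        matcher = build_matcher(lexicon, variant)
        for proc in cohort.procedures:
            t = flag_text(proc, cohort.notes, matcher, variant)[0]
            o = flag_orders(proc, cohort.orders, lexicon, variant)[0]
            a = flag_admin(proc, cohort.administrations, lexicon, variant)[0]
            r = results[proc.procedure_id]
            assert (r.text_hit, r.order_hit, r.admin_hit) == (t, o, a)
            assert r.final_flag == (t or o or a)

    def test_result_multiset_invariant_under_input_shuffle(self, lexicon):
        cohort = pf.generate_cohort(pf.CohortSpec(n_procedures=120, seed=13))
        shuffled = pf.Cohort(
            procedures=list(reversed(cohort.procedures)),
            notes=list(reversed(cohort.notes)),
            orders=list(reversed(cohort.orders)),
            administrations=list(reversed(cohort.administrations)),
            labels=cohort.labels,
        )
        a = classify_cohort(cohort, lexicon, FINAL_VARIANT)
        b = classify_cohort(shuffled, lexicon, FINAL_VARIANT)
        strip = lambda rs: [(r.procedure_id, r.final_flag, r.text_hit, r.order_hit) for r in rs]
        assert strip(a) == strip(b)

    def test_determinism(self, lexicon):
        cohort = pf.generate_cohort(pf.CohortSpec(n_procedures=100, seed=21))
        assert classify_cohort(cohort, lexicon, FINAL_VARIANT) == classify_cohort(
            cohort, lexicon, FINAL_VARIANT
        )


def flagged_ids(cohort, lexicon, variant):
    return {r.procedure_id for r in classify_cohort(cohort, lexicon, variant) if r.final_flag}


@pytest.fixture(scope="module")
def cohort():
    return pf.generate_cohort(pf.CohortSpec(n_procedures=400, seed=17))


class TestMonotonicity:
    def test_enabling_a_source_never_decreases_flags(self, cohort, lexicon):
        text = flagged_ids(cohort, lexicon, TEXT_ONLY)
        orders = flagged_ids(cohort, lexicon, ORDERS_ONLY)
        both = flagged_ids(cohort, lexicon, AlgorithmVariant(use_text=True, use_orders=True))
        assert text <= both and orders <= both
        everything = flagged_ids(
            cohort, lexicon, AlgorithmVariant(use_text=True, use_orders=True, use_admin=True)
        )
        assert both <= everything

    @pytest.mark.parametrize(
        "filter_field,value",
        [
            ("exclude_oral_only", True),
            ("restrict_common_prophylaxis", True),
            ("max_order_duration_hours", 24),
            ("exclude_same_day_post_procedure_orders", True),
            ("exclude_day_of_procedure_notes", True),
        ],
    )
    def test_adding_a_filter_never_increases_flags(self, cohort, lexicon, filter_field, value):
        base = AlgorithmVariant(use_text=True, use_orders=True)
        filtered = dataclasses.replace(base, **{filter_field: value})
        assert flagged_ids(cohort, lexicon, filtered) <= flagged_ids(cohort, lexicon, base)

    def test_window_monotonicity(self, cohort, lexicon):
        wide = dataclasses.replace(FINAL_VARIANT, window_days=7)
        narrow = dataclasses.replace(FINAL_VARIANT, window_days=1)
        assert flagged_ids(cohort, lexicon, narrow) <= flagged_ids(cohort, lexicon, wide)

    def test_scanned_note_blindness(self, cohort, lexicon):
        blinded = pf.Cohort(
            procedures=cohort.procedures,
            notes=[dataclasses.replace(n, is_searchable=False) for n in cohort.notes],
            orders=[],
            administrations=[],
            labels=cohort.labels,
        )
        results = classify_cohort(blinded, lexicon, TEXT_ONLY)
        assert all(not r.text_hit for r in results)
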