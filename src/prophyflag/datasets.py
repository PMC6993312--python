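"""Published confusion counts from the algorithm's original validation study.

The algorithm was developed against a manually chart-reviewed national
cohort of 2102 cardiac device procedures at 38 facilities (2056 of them,
97.8%, with pre-incisional prophylaxis) and then applied to a national
validation cohort of 18,903 procedures at 65 facilities, of which a random
100 (50 flagged positive, 50 flagged negative) were manually re-reviewed.
The raw per-variant confusion counts from those studies are reproduced here
as worked-example fixtures so the metric arithmetic can be checked end to
end without access to the original (non-redistributable) patient data.

Counts are stated as tp/fp/tn/fn; derived percentages are never stored —
they are always recomputed through :func:`prophyflag.evaluation.compute_metrics`.
"""

from __future__ import annotations

from .evaluation import ConfusionCounts

__all__ = [
    "DEVELOPMENT_N",
    "DEVELOPMENT_GOLD_POSITIVE",
    "DEVELOPMENT_GOLD_NEGATIVE",
    "DEVELOPMENT_TABLE",
    "VALIDATION_N",
    "VALIDATION_FLAGGED",
    "VALIDATION_REVIEW_COUNTS",
]

#: Development cohort size and gold-label split (manual chart review).
DEVELOPMENT_N = 2102
DEVELOPMENT_GOLD_POSITIVE = 2056
DEVELOPMENT_GOLD_NEGATIVE = 46

#: Per-variant confusion counts from the development stage.  Keys match the
#: preset names in :data:`prophyflag.detector.VARIANT_PRESETS`.  Two cells in
#: the published table are internally inconsistent at the printed level
#: (the orders-row PPV denominator and the day-of-notes flagged count); the
#: splits below are the unique ones consistent with each row's sensitivity,
#: specificity and the 2056/46 gold margins.
DEVELOPMENT_TABLE: dict[str, ConfusionCounts] = {
    "text": ConfusionCounts(tp=1930, fp=24, tn=22, fn=126),
    "orders": ConfusionCounts(tp=1883, fp=16, tn=30, fn=173),
    "administration": ConfusionCounts(tp=150, fp=0, tn=46, fn=1906),
    "text+orders": ConfusionCounts(tp=2019, fp=29, tn=17, fn=37),
    "text+administration": ConfusionCounts(tp=1931, fp=24, tn=22, fn=125),
    "orders+administration": ConfusionCounts(tp=1885, fp=16, tn=30, fn=171),
    "text+orders+administration": ConfusionCounts(tp=2019, fp=29, tn=17, fn=37),
    "round2-exclude-oral": ConfusionCounts(tp=1928, fp=22, tn=24, fn=128),
    "round2-common-agents": ConfusionCounts(tp=2017, fp=27, tn=19, fn=39),
    "round2-exclude-day-of-notes": ConfusionCounts(tp=823, fp=2, tn=44, fn=1233),
    "round2-prophylaxis-term": ConfusionCounts(tp=2019, fp=29, tn=17, fn=37),
}

#: Validation cohort: all cardiac device procedures FY16–17 at facilities
#: with volume >= 50 cases.
VALIDATION_N = 18903
VALIDATION_FLAGGED = 16606

#: Manual re-review of 50 positively and 50 negatively flagged validation
#: cases: 48/50 positives confirmed, 10/50 negatives confirmed.  Because the
#: subsample was drawn per *flag* stratum, the directly estimable quantities
#: are flag-conditional: 48/50 is the PPV and 10/50 the NPV of the subsample
#: (the study reports them under the labels "sensitivity" and "specificity").
VALIDATION_REVIEW_COUNTS = ConfusionCounts(tp=48, fp=2, tn=10, fn=40)
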