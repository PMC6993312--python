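# Methods

## Problem and approach

Pre-incisional antimicrobial prophylaxis for procedures such as cardiac
device (CIED) implantation is usually dispensed directly in the procedure
lab, so it leaves no single reliable structured trace in the EMR. Its
documentation is scattered across four sources: computerized-entry
medication orders, bar-code administration records, typed (searchable)
clinical notes, and scanned paper notes that are not electronically
searchable. `prophyflag` classifies each procedure by OR-combining
rule-based detectors over the first three sources; scanned notes are, by
construction, invisible to it — this is the algorithm's main structural
blind spot and the dominant false-negative mechanism wherever paper
anesthesia records persist.

## Detection rules and their parameters

All detectors share a lookback window of `window_days` (default **7**,
chosen to span the common practice of entering the prophylaxis order at a
pre-procedure clinic visit; longer windows sharply increase false
positives from intervening unrelated prescriptions).

* **Text**: a note contributes when `is_searchable` is true and its signed
  *calendar date* lies in `[procedure_date − window, procedure_date]`
  (upper bound drops to the day before under
  `exclude_day_of_procedure_notes`). Matching is case-insensitive,
  whole-word (alphanumeric boundaries), longest-alias-first,
  non-overlapping. There is no negation, allergy or section detection:
  the allergy false-positive problem is handled solely by excluding
  penicillin (`text_search_excluded`) from the note lexicon, so an allergy
  mention of a retained agent *will* match — a documented limitation.
* **Orders**: the fielded `drug_name` must normalize (lowercase, collapsed
  whitespace) to a lexicon alias of an agent surviving the variant's
  agent filters — `exclude_oral_only` and `restrict_common_prophylaxis`
  drop oral-only and rarely-prophylactic agents. The order date must lie
  in the same calendar-date window; under
  `exclude_same_day_post_procedure_orders`, a same-day order placed after
  the procedure time is rejected. Under `max_order_duration_hours`
  (final value **24**), orders with `stop − start` at or above the cap are
  rejected; orders with *no* stop time pass the cap with a logged warning,
  since single pre-op doses frequently lack stop times and rejecting them
  would discard the dominant structured signal.
* **Administrations**: same agent filters and date lower bound, but the
  upper bound is the procedure *timestamp* — post-procedure administration
  is guideline-discordant and never counts, regardless of variant.

The window semantics are deliberately asymmetric: notes are windowed by
signed day (their only reliable timestamp), orders by day with a
time-of-day cut only for the same-day exclusion, administrations by
timestamp. Datetimes are naive local times (single-institution
assumption). Procedures recorded without a time-of-day follow the
`missing_time_inclusive` policy (default: same-day orders/administrations
count as pre-procedure; set false to treat them as indeterminate and
excluded).

`FINAL_VARIANT` — text + orders, both agent filters, 24 h cap, same-day
post-procedure exclusion, 7-day window — is the configuration that
performed best in the development study (sensitivity 98.1%, specificity
41.3% against 2102 chart-reviewed procedures). The "prophylaxis"
pseudo-term variant exists but is off by default: the bare word also
matches "no prophylaxis given" and adds essentially no sensitivity.

## Default lexicon

The original search-term appendix is not public, so the shipped lexicon
(`data/default_lexicon.csv`) is a guideline-derived reconstruction:
cefazolin, cefuroxime, ceftriaxone, vancomycin, clindamycin and gentamicin
as prophylaxis agents (with brand names and misspelling variants),
cephalexin/amoxicillin as oral-only, fluoroquinolones, azithromycin and
bacitracin as rarely-prophylactic, and penicillin as rarely-prophylactic
and text-search-excluded. It is fully replaceable via `load_lexicon`
(CSV, one row per alias, or JSON, one object per agent). Misspellings are
covered only by explicit aliases; there is no fuzzy matching.

## Evaluation conventions

Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), PPV = tp/(tp+fp),
NPV = tn/(tn+fn); any metric with a zero denominator is reported as
`None`, never coerced to 0 or 1, because near-degenerate cohorts (gold
negatives are ~2% of cases) are the norm here. Facility compliance bands
use closed-open semantics: high > 0.80, middle [0.60, 0.80], low < 0.60,
computed only for facilities with ≥ `min_volume` (default 50) procedures.

Two quirks of the published counts, preserved rather than smoothed over:
(1) three printed cells of the development grid are internally
inconsistent with their own row's counts (the orders-row PPV denominator,
the day-of-notes flagged count, and that row's NPV); the packaged fixtures
use the unique tp/fp/tn/fn splits consistent with each row's sensitivity,
specificity and the 2056/46 gold margins, and the tests skip exactly those
three cells. (2) The validation re-review sampled 50 cases per *flag*
stratum, so its reported 96%/20% "sensitivity/specificity" are
flag-conditional accuracies — the subsample's PPV and NPV in standard
nomenclature — and are computed as such. The development narrative's
"correctly classified 2048 (97.4%)" equals the flagged count (tp+fp), not
tp+tn; the package treats 97.4% as the flagged fraction.

## Synthetic cohorts

`synthgen` emulates *documentation styles*, not clinical language: note
text is templated with randomized filler around drug surface forms drawn
from the active lexicon (mixed case, brand names, misspellings), one
patient per procedure, procedure dates uniform over a year with
business-hours times. The scenario taxonomy (14 scenarios, table in the
module docstring) maps one-to-one onto the misclassification mechanisms
identified by manual review of discordant cases, and each scenario is
constructed so its confusion-cell outcome under `FINAL_VARIANT` is
deterministic — e.g. stale orders are placed 8–60 days out, late notes
1–3 days post-procedure, wrong-date cases shift the recorded date 10–30
days. The `wrong_procedure_type` scenario (miscoded as cardiac
catheterization) is removed by `dedupe_procedures` before classification,
so its expected outcome is `EXCLUDED` rather than a confusion cell.

Default mix: prevalence 0.978 (the development cohort's gold-positive
fraction); among positives 1.9% are false-negative scenarios split
27:4:3:1:1 (undocumented agent : stale order : late note : scanned :
wrong date) as observed in the development discordance audit, with the
concordant mass split 0.90/0.081 between clean-note and order-only
documentation; among negatives, 57% are false-positive scenarios
(post-procedure mention dominant), matching the audit's 27-of-46
proportion approximately. The split among true-negative mechanisms and
between clean-note and order-only documentation is not reported anywhere
and uses plausible round values. `expected_confusion` returns the exact
linear expectation n × prevalence × mix (marginalizing uniform facility
assignment over any `facility_effects` overrides), so empirical confusion
converges to it by the law of large numbers; the acceptance test checks
agreement within 3 binomial standard errors per cell at n = 5000.

What passing synthetic tests does **not** show: robustness to real
clinical language (negation, templated allergy lists, abbreviations
outside the alias set), to multi-procedure patients with overlapping
windows, or to realistic scenario frequencies outside the audited
discordant subset. The generator is a mechanism test bed, not an
epidemiologic simulation.

## Numerical and design choices

* Longest-alias-wins tie-break at equal offsets prevents a short alias
  (e.g. `vanco`) from shadowing a longer one at the same position.
* Duplicate procedures collapse on (patient, datetime, type) keeping the
  smallest procedure id; deduplication is idempotent and every removal is
  reported with a reason.
* Malformed input rows (unparseable datetimes, missing JSONL keys) become
  a rejects report; structural errors (missing columns, duplicate
  procedure ids, alias collisions) raise immediately.
* All randomness flows through one `numpy.random.Generator` seeded once
  per cohort with draws consumed in fixed order, so equal seeds give
  byte-identical cohorts on disk.
* Problem sizes in the test suite (up to 5000-case cohorts for the
  Monte-Carlo check, a few hundred elsewhere) were chosen as the smallest
  that give stable statistical verdicts for the properties under test.

## Known limitations

Beyond the scanned-note blindness and absent negation handling noted
above: order-side matching requires exact normalized alias equality, so a
compound fielded name ("cefazolin 1g in NS") does not match unless added
as an alias; the note window is date-granular, so a day-of-procedure note
written after the procedure still counts (extending text search past the
procedure date is deliberately not offered — post-procedure antimicrobial
use approaches 50% in this population and would flood the false
positives); no OCR, no HL7/FHIR ingestion, no machine-learning extension.
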