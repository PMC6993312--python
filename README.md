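# prophyflag

Electronic measurement of compliance with **pre-incisional antimicrobial
prophylaxis** from electronic medical record (EMR) extracts.

Antimicrobials given before the skin incision are a cornerstone of
procedure-related infection prevention (including cardiac device — CIED —
infections), but in most procedural settings they are dispensed in the lab
or operating room without a conventional medication order, so standard
medication-monitoring systems miss them and quality measurement has relied
on expensive manual chart review. `prophyflag` implements a rule-based
phenotyping algorithm that replaces that review: it combines **whole-word
lexicon searches of free-text clinical notes** with **temporally filtered
structured medication orders**, and flags each procedure as having (or not
having) documented pre-incisional prophylaxis. It is aimed at clinical
informaticists and quality-measurement teams working with tabular EMR
extracts (procedures, notes, orders, administrations).

## The algorithm

For a procedure at time *t* with lookback window *w* = 7 days, the final
algorithm variant flags the procedure when either source hits:

- **text**: a searchable (non-scanned) clinical note signed on a day in
  [*t* − *w*, *t*] contains an antimicrobial name from the lexicon
  (generic names, brand names, and misspelling variants; penicillin is
  excluded from note searches because it overwhelmingly appears in allergy
  documentation);
- **orders**: a medication order for a lexicon agent — excluding oral-only
  and rarely-prophylactic agents — is placed on a day in [*t* − *w*, *t*],
  not after the procedure time on the procedure day, with order duration
  < 24 h (long courses indicate treatment of an unrelated infection, not
  prophylaxis).

Administration (bar-code) records are supported as a third source but add
almost nothing where order data exist. Every configuration knob is an
`AlgorithmVariant` field, with named presets for each development-stage
configuration; performance is scored against gold labels as sensitivity,
specificity, PPV and NPV, and reported per facility (volume ≥ 50) in
> 80% / 60–80% / < 60% compliance bands.

Because real EMR cohorts cannot be redistributed, the package includes a
synthetic cohort generator (`prophyflag.synthgen`) whose scenario taxonomy
reproduces the documented misclassification mechanisms (scanned paper
notes, stale orders, post-procedure mentions, flush/wash use, allergy
documentation, ...), each landing deterministically in a known
confusion-matrix cell under the final variant.

## Worked example

```bash
prophyflag simulate --n 600 --seed 7 --out demo/cohort
prophyflag evaluate --cohort demo/cohort --variants text,orders,final --min-volume 1 --out demo/eval
```

prints

```
generated 600 procedures (587 gold-positive) across 10 facilities; wrote 6 tables to demo/cohort
variant  flagged_n  flagged_pct      ppv      npv  sensitivity  specificity  tp  fp  tn  fn
   text        530    88.333333 0.988679 0.100000     0.892675     0.538462 524   6   7  63
 orders        322    53.666667 0.996894 0.043165     0.546848     0.923077 321   1  12 266
  final        577    96.166667 0.989601 0.304348     0.972743     0.538462 571   6   7  16
```

Reading the grid: note searches alone find 89% of true prophylaxis cases
(facilities that order without documenting the drug name in the note are
missed), orders alone only 55%, and their OR-combination under the final
variant reaches 97% sensitivity — the central empirical point of the
method. Specificity is modest because post-procedure antimicrobial
mentions and non-systemic washes in procedure notes still fire the text
search; NPV is low simply because true negatives are rare at 97.8%
prevalence. `prophyflag flag` runs classification alone and writes
per-procedure flags (`flags.csv`) with a JSON evidence sidecar listing
every matched term, order and administration behind each flag.

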