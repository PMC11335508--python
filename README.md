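# piload

**How many clinical trials does each principal investigator actually run?**

Trial registries such as the Clinical Trials Registry—India (CTRI) identify
the responsible investigator only by a free-text contact block — there is no
stable PI identifier. The same person therefore appears as "Dr. A. K.
Sharma", "Anil Kumar Sharma" and "SHARMA, A K", while two different people
can share one spelling. Any attempt to measure investigator workload — a
question with direct participant-safety and governance implications, since
India once capped a PI at three concurrent trials — first has to solve this
identity-resolution problem, and then has to cope with registry records
whose completion dates are simply missing.

`piload` is a tested, reusable pipeline for exactly this analysis:

1. **Ingest** — read flattened registry dumps (CSV/TSV/JSONL) into typed
   records, with day-first date parsing, duration parsing, per-row rejection
   accounting and a missingness report.
2. **Cohort filter** — a five-stage funnel (interventional trial → eligible
   study types → non-thesis → recruiting in India → PI details present) with
   stage-by-stage conservation accounting.
3. **Name resolution** — normalize names (honorifics, punctuation, case),
   build two similarity matrices (normalized edit distance via `edlib`, and
   an initials-aware token-overlap score), propose candidate variant pairs
   above a threshold (default 0.85), and merge them only on strong
   contact-field evidence (shared email or phone/fax line). Identical
   spellings with conflicting evidence are split; irreducibly ambiguous
   names (multi-person fields, records torn between clusters) are set
   aside, never forced.
4. **Timeline** — one `[start, end]` activity interval per trial. A missing
   *Date of Study Completion* is imputed as
   `start + estimated duration + 3 months` (calendar arithmetic, day
   clamped); records with no start date or with a zero/absent duration and
   no completion date are excluded with explicit reasons.
5. **Summarize** — trials-per-PI histogram and the 1 / 2 / 3 / >3 buckets
   with half-away-from-zero rounded percentages, plus the high-burden table
   (PIs with ≥ 20 trials): per-calendar-year active-trial counts (a trial
   counts in every year its interval overlaps) and the peak year.
6. **Synthetic registry** — a seeded generator that emulates the dirty data
   this pipeline must survive (heavy-tailed trials-per-PI distribution,
   name-variant processes, partial evidence coverage, decoy ineligible
   records, missing timeline fields) together with ground-truth identity
   labels, so resolution quality is measurable as pairwise
   precision/recall/F1.

## Worked example

```python
from piload import GeneratorConfig, generate_registry, run_pipeline, evaluate_resolution

records, truth = generate_registry(GeneratorConfig(n_pis=200, seed=42))
result = run_pipeline(records)

for line in result.filter_report.stages:
    print(f"{line.stage:>11}: {line.input_count} -> {line.kept_count}")
res = result.resolution
print("unique PIs:", res.n_unique_pis, " variant names:", res.variant_count,
      " ambiguous:", len(res.ambiguous_record_ids))
print("pairwise F1:", round(evaluate_resolution(res, truth).f1, 4))
print("% single-trial PIs:", result.distribution.bucket_percentages["1"])
```

prints

```
 trial_type: 402 -> 384
 study_type: 384 -> 357
  pg_thesis: 357 -> 348
    country: 348 -> 339
 pi_present: 339 -> 327
unique PIs: 174  variant names: 54  ambiguous: 3
pairwise F1: 0.9969
% single-trial PIs: 81.0
```

Reading: of 402 generated records, 327 survive the funnel (each exclusion
attributed to its first failing stage). The resolver collapses 327 records
carrying 231 distinct raw spellings into 174 unique investigators by
absorbing 54 variant spellings, setting 3 records aside as ambiguous, and
agrees with the generator's ground-truth identities at pairwise F1 0.997.
81% of resolved investigators ran a single trial — the long-tailed pattern
the analysis is designed to expose.

The same pipeline runs from the shell, stage by stage:

```bash
pi-load simulate --seed 9 --out-dir sim
pi-load run --input sim/records.csv --out-dir out     # or ingest/filter/resolve/timeline/summarize
```

## Layout

```
src/piload/
  model.py       typed registry records (RawTrialRecord, PIContact, CalendarDuration)
  ingest.py      dump reading, date/duration dialects, load reports
  cohort.py      filter cascade + funnel report
  names.py       normalization, similarity matrices, evidence rules, resolver
  timeline.py    completion imputation, intervals, active years
  summarize.py   distribution buckets, percentages, high-burden table
  synthetic.py   seeded generator + ground truth + resolution scoring
  pipeline.py    end-to-end convenience wrapper
  cli.py         `pi-load` command group
```

See `docs/methods.md` for the model, parameter defaults and limitations.
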