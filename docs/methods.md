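# Methods

## The problem

A trial registry record names its responsible investigator in a free-text
contact block: a name plus (sometimes) email, phone, fax, affiliation,
address and postal code. There is no persistent investigator ID, so
counting trials per investigator requires record linkage under two
competing error modes: *splitting* one person across several spellings
(undercounting the busiest investigators — the quantity of interest) and
*lumping* different people who share a name (inventing workload that does
not exist). The pipeline is built to be conservative about lumping: merges
across different spellings require strong contact evidence, and anything
the rules cannot settle is set aside as ambiguous rather than guessed.

## Cohort filter

Five predicates applied as a funnel, in a fixed order: trial type equals
"Interventional"; the study-type set intersects {Biological, Preventive,
Dentistry, Drug, Stem Cell Therapy, Vaccine}; the postgraduate-thesis flag
is "No" or "NA" (an absent flag is treated as "NA" — in a flattened dump
the two are indistinguishable); "India" appears among the recruiting
countries; the PI name field is non-empty. Matching is case-insensitive
after trimming, with "N/A" normalized to "NA". Each record is attributed to
its *first* failing stage, which makes the report a funnel (each stage's
kept count is the next stage's input) while the final kept set is simply
the conjunction of all predicates — the ordering convention affects only
exclusion attribution, a property the tests verify against an independent
conjunction oracle.

## Name resolution

**Normalization.** Case-fold, replace punctuation by spaces, collapse
whitespace, and strip *leading* honorific tokens (dr, prof, mr, mrs, ms,
miss, shri, smt, sri, …; configurable). Stripping only from the front, and
never below one token, keeps normalization idempotent and avoids deleting
surname-like tokens that coincide with honorifics. The key retains the
token sequence and an initials signature.

**Similarity.** Two metrics over normalized names, both in [0, 1]:

* *edit* — `1 − Levenshtein/max(len)` (computed with edlib), which catches
  typos and spacing differences;
* *token* — a generalized Jaccard overlap in which tokens match when equal
  **or** when one is a single letter equal to the other's first letter
  ("k" ~ "kumar"), resolved as a maximum bipartite matching so the score is
  symmetric. Initialized given names are the single most common registry
  variant ("A K Sharma" for "Anil Kumar Sharma"); a plain token Jaccard
  scores that pair 0.2 and can never propose it, while the initials-aware
  form scores it 1.0. When no initials are involved the score reduces
  exactly to ordinary Jaccard.

Candidate variant pairs are those scoring at or above a threshold (default
0.85) under **either** metric. The threshold only *proposes*; it never
merges on its own.

**Evidence.** Contact fields canonicalize to an evidence profile: emails
lower-cased; phone and fax numbers reduced to digits and, when at least 8
digits long, compared on their trailing 8 digits (country and trunk
prefixes vary freely in Indian numbers); affiliations tokenized with
generic institution words removed; postal codes trimmed. A shared email or
phone/fax line is **strong** evidence (a fax line is the same kind of
contact identifier as a phone line and is treated identically); a shared
postal code or affiliation-token Jaccard ≥ 0.5 is **weak**.

**Resolution algorithm.**

1. Fields that appear to contain several person names (separators `/`, `;`,
   newline, "and", "&") go straight to the ambiguous set.
2. Records are blocked on identical normalized names. Within a block,
   records connected by strong *or* weak evidence unify; evidence-bearing
   records with no link to the rest become separate candidate persons
   (same spelling, different people). Records with *no* evidence at all
   join the block's single candidate under the default `merge` policy
   (a bare identical name is one person unless contradicted — configurable
   to `ambiguous`); if the block has already split into several
   evidence-distinct persons, a bare record cannot pick a side and is set
   aside.
3. Across distinct spellings, candidate pairs merge **iff** their evidence
   verdict is strong. Weak evidence never merges different spellings by
   default (configurable).
4. Merge decisions close under union-find (connected components), making
   cluster membership an equivalence relation.
5. A record whose strong identifiers tie it (through other records) to two
   or more clusters *other than its own* is contradictorily assigned; its
   raw spelling and that spelling's records are moved to the ambiguous
   set. A record tied to exactly one foreign cluster is *not* moved: that
   is the known "similar name, shared contact, but no name-rule support"
   case, which the pipeline leaves split (undercounting, the conservative
   direction) rather than inventing a merge.
6. Clusters get deterministic IDs by sorting on (canonical normalized name,
   smallest member record ID); the canonical name is the spelling-key
   carrying the most records. The whole procedure is seedless and
   deterministic: identical inputs give identical output, cluster IDs
   included.

**Accounting.** A *variant* is a raw spelling absorbed into a cluster
beyond the cluster's first spelling, so
`spellings-in-clusters = clusters + variants`, with ambiguous spellings
tallied separately. Counting per cluster keeps the tally meaningful (and
non-negative) when one spelling legitimately splits into several people.

## Timeline

A recorded *Date of Study Completion* is always used verbatim, even when it
disagrees with start + duration — the registry's explicit field outranks
any estimate. When it is absent, the end is imputed as
`start + (estimated duration + 3 months)`: the 3-month allowance for
recruitment delay extends the duration itself, and the extended duration is
applied to the start date in one calendar step — months first with
day-of-month clamping (Nov 30 + 6 months = May 30; Jan 31 + 1 month =
Feb 28/29), then the day component. This is calendar arithmetic, not a
90-day offset.

Records that cannot be placed on a timeline are excluded with exactly one
reason: `missing_start`; `zero_duration_no_completion` (the duration is
zero *or absent* and there is no completion date — an absent duration
leaves nothing to impute from); or `completion_before_start` (an internally
inconsistent record). Ambiguous-PI records are skipped silently — they are
already outside the per-PI analysis. Conservation holds exactly:
intervals + exclusions = clustered records.

A trial is *active* in every calendar year its `[start, end]` interval
overlaps — Gantt semantics, always a contiguous year range. Counting
trials *started* per year instead would be a one-line change in
`high_burden_table` (filter on `start.year`), but active-in-year is the
semantics that matches concurrent-workload questions, so it is the
implemented default.

## Summaries

Percentages are rounded half-away-from-zero using decimal arithmetic
(binary floats never decide a tie). The distribution table reports the
histogram plus counts and percentages for exactly 1, 2, 3, more than 3,
and at least `high_burden_threshold` (default 20) trials; the first four
buckets partition the investigators, which the table validates. The
high-burden table sorts by total trials descending (ties by cluster ID),
renders the year range [min start year, max end year] of its included
intervals with empty cells as 0, and reports each row's peak year (earliest
year on ties).

## Synthetic registry

The generator emulates, per record, the processes the pipeline must
survive; all defaults are the study conditions the package is tested
under:

| parameter | default | rationale |
|---|---|---|
| `n_pis` | 200 | resolver-scale dataset (~400 records) that keeps full runs sub-second |
| trials per PI | P(1)=.757, P(2)=.136, P(3)=.043; rest a k^−1.8 tail on 4…108 | head matches the reported single/double/triple fractions of a national registry; the tail produces rare high-burden PIs up to the reported maximum |
| variant rates | honorific .15, initials .10, typo .03, swap .03, case .10 | honorifics/initials dominate real spelling variation; typos are rarer |
| evidence coverage | email .90, phone .70, fax .10, affiliation .80, postal .60 | contact blocks are usually, not always, filled |
| `email_stability` | .90 | a PI occasionally registers under a second address |
| decoy rates | ~3–5% per filter stage | every funnel stage sees real exclusions |
| `completion_present_prob` | .40 | the completion date is the most commonly missing timeline field |
| sabotage rates | .004 missing start, .004 zero duration | a handful of records per dataset, mirroring how rare these pathologies are |

Names are assembled from a bundled synthetic lexicon (no real-person data);
canonical names are sampled distinct per investigator. Variant processes
apply structural edits (initials, swaps, typos) before decoration
(honorific, casing), as an honorific prefixed first would otherwise be
swallowed into the initials. Every variant process keeps its output within
similarity reach (≥ 0.85 under at least one metric) of the original, which
the tests assert per process.

What the generator does **not** model — and what passing tests therefore do
not demonstrate about real registry data: transliteration and script
variation, name changes over time (marriage, gender, religion), shared
sponsor/CRO contact addresses across genuinely different PIs, site-level
PI lists, and free-text affiliation drift. On real dumps the resolver's
conservative merge policy means reported trials-per-PI counts are best read
as lower bounds for the busiest investigators.

## Numerical and design notes

* Phone canonicalization uses the trailing-8-digit form everywhere, so
  phone comparison is an exact set intersection — one rule for pairwise
  verdicts and the cross-cluster contradiction index alike.
* Candidate-pair ordering (descending score, then lexicographic) and
  cluster-ID assignment are fully specified, so resolution output is
  reproducible byte for byte.
* `percent()` refuses denominator 0 and numerators outside [0, d];
  `CalendarDuration` refuses negative components; zero durations are
  preserved as zero (never collapsed to absent) because the zero case
  drives the timeline exclusion rule.
* The generator, and hence every test and the acceptance script, draws all
  randomness from one seeded NumPy generator; reruns are byte-identical.
* Scale choices: the acceptance run uses 200 investigators (~360 records);
  property suites use up to 1,000 records. These sizes exercise every code
  path, including high-burden investigators, while keeping the full suite
  under a few seconds.

## Known limitations

* The similarity threshold (0.85) and affiliation Jaccard cutoff (0.5) are
  declared defaults, not values fitted to any real dump; both are exposed
  in `ResolutionParams`.
* Cross-spelling merges require strong evidence, so a variant spelling
  whose records carry no shared email/phone stays a separate investigator
  (undercounting). The converse failure — lumping distinct PIs — requires
  them to share a canonicalized email or phone line, which the generator
  never produces and real data produces mainly through shared
  institutional contacts; on real data the ambiguous set should be
  reviewed, not discarded.
* Completion imputation is deliberately conservative; trials delayed beyond
  3 months are truncated, so per-year activity counts for some
  investigators are lower bounds.
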