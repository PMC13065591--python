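# Methods

This note documents the modelling assumptions, parameter choices and known
limitations of `ventrecon`'s episode reconstruction, quality grading,
outcome metrics and synthetic-EHR generator.

## Data model and time

All tables are pandas DataFrames with a fixed column contract
(`ventrecon.schema.TABLE_COLUMNS`). Timestamps are timezone-naive
`datetime64[ns]` in a single declared zone and are floored to the minute on
ingestion: EHR charting has minute granularity at best, and sub-minute
precision would be spurious. All interval arithmetic operates on the naive
values directly, which is equivalent to working in UTC; a deployment
ingesting local-time data with DST transitions should convert to UTC before
loading. CSV storage uses RFC 4180 with ISO-8601 minute-precision
timestamps (`YYYY-MM-DDTHH:MM`); the SQLite mirror stores the same strings.

"Invalid data" is operationalized as four reason codes: NULL required
timestamp, negative device interval (removal before placement), dangling
foreign reference, and documentation more than 24 h outside the encounter's
admission–discharge window. Validation partitions rather than aborts, is
idempotent, and preserves row accounting (rejected + retained = input) per
table. The 24-h slack admits legitimate pre-admission documentation
(e.g. field intubation charted against the ED encounter).

## Extraction choices

* **Flowsheet segmentation.** Invasive-mode rows with inter-row gaps
  ≤ `gap_tolerance_hours` (default 8 h) form one invasive interval.
  Charting intervals in ICUs are 1–4 h, so 8 h separates true re-events
  from charting gaps while tolerating several missed rows. Interval
  endpoints are the observed row timestamps, not gap midpoints: this is
  conservative and reproducible, biases duration short by at most one
  charting interval, and the concordance grade absorbs the discrepancy
  against event-timed sources.
* **Ventilator-mode vocabulary.** Shipped as an editable config:
  invasive = {AC, SIMV, PRVC, PS-invasive}, noninvasive = {CPAP, NIPPV,
  nasal-IMV, HFNC}. Unknown tokens are ignored and counted, never treated
  as invasive. Noninvasive rows never open, extend or bridge an invasive
  interval.
* **Tracheostomy events.** Tracheostomy procedure records and tracheostomy
  LDA placements feed a dedicated event stream used for termination
  classification. Tracheostomy-tube candidates are excluded from
  endotracheal event clustering: a trach tube documents the surgical
  airway, and letting its placement/removal cluster with ETT events would
  corrupt episode endpoints.
* **Inference of last resort.** Admission records flagged
  "admitted with airway" yield an intubation candidate at the admission
  time; a death during the encounter yields an extubation candidate at
  min(death, discharge). These carry `inferred=True`, hold the lowest
  canonical-time priority, and are invisible to the quality grade.

## Clustering and pairing

Candidates of one encounter and event type are grouped by single-linkage
clustering in time with link threshold `match_window_hours` (default 12 h).
The threshold is deliberately the outer concordance bound of the grading
scale: two sources more than 12 h apart are, by the scale's own definition,
at the edge of describing "the same event", so candidates farther apart are
treated as different events. One refinement guards against chaining:
because each source documents a physical event at most once, a cluster
containing two candidates from the same source more than the A-band (1 h)
apart must span two events and is split at its largest internal time gap,
recursively. Without this rule a short episode followed by a short
reintubation gap (combined < 12 h) merges two true intubations into one
cluster and silently deletes a reintubation.

The canonical time is the median time of the highest-priority source
present: anesthesia > LDA > flowsheet > procedure > admission. Anesthesia
events are charted to the minute by the anesthesia record; LDA rows are
device-level documentation; flowsheets are interval-sampled; admission
times are inference. A priority rule (rather than averaging) keeps
canonical times equal to an actually documented time and makes the
pipeline's behaviour easy to audit.

Pairing walks each encounter's clusters in time order, alternating
intubation → extubation. Deviations are resolved conservatively:

* consecutive intubations: the first is closed by fallback
  (tracheostomy time, then death time) if one lies between them, else
  dropped and logged;
* a trailing open intubation: closed at the tracheostomy time, death time,
  or — only for transfer-out dispositions — the discharge time (flagged
  inferred); otherwise dropped and logged, never imputed;
* an extubation with no open intubation: dropped and logged;
* an extubation followed by a reintubation within
  `min_episode_gap_minutes` (default 30 min): merged as a documentation
  artifact. The default matters directly for extubation-failure counts and
  is therefore configurable.

Termination is classified per episode: *tracheostomy* when a tracheostomy
event falls inside the episode and within the match window of the
extubation endpoint (ETT removal during the tracheostomy procedure is the
same physical event); else *death* when the patient's death time lies
within the match window of the extubation endpoint; else *extubation*.
Episode indices are assigned per patient across encounters, so
cross-encounter reintubation within 7 days is countable.

## Quality grading

Score: number of distinct non-inferred sources whose time lies within the
A-band (1 h) of the canonical time — ≥3 → 1, exactly 2 → 2, ≤1 → 3.
Concordance: maximum pairwise spread of non-inferred times — ≤1 h → A
(closed bound: exactly 60 min is A), ≤12 h → B (closed: exactly 12 h is B),
>12 h → C. A singleton has zero spread, hence letter A with score 3. An
endpoint resting solely on inference is 3C. The score thresholds and both
band bounds are conventions (`GradingConfig`), since only the ordinal
meaning and the two outer bounds (one hour; more than twelve hours) are
externally fixed; requiring "matching" sources to agree within the A-band
is the only reading under which a multi-source event can grade 3B or 3C.

Note one scale property verified by the acceptance suite: under extreme
timestamp noise the *letter* alone is not a monotone quality measure —
events fragment into singleton clusters, which grade A on concordance by
the singleton rule while their score collapses to 3. The monotone headline
statistic is the fraction of full top grades (1A), which requires both
corroboration and tight concordance.

## Outcome metrics

Duration is extubation − intubation in hours at minute resolution. Age is
the exact year fraction (365.2425-day years) at intubation; pediatric means
age ≤ 18. Reintubation windows: gap ∈ (0, 48 h] → "within 48 h";
(48 h, 168 h] → "2–7 d"; their union → "within 7 d" — consistent by
construction. Extubation failure is 48-h reintubation over a configurable
denominator, default episodes terminated by a true extubation: a patient
who died or received a tracheostomy on the tube cannot fail extubation.
Episode- and patient-denominator policies are both available because the
field uses both. Cohort summaries canonicalize row order internally so
floating-point aggregates are exactly permutation-invariant.

## Synthetic-EHR generator

The generator draws latent ground-truth episodes per patient and renders
them into the five source tables. Defaults emulate the cohort shape of a
large academic center: 11.8% pediatric; 48-h reintubation probability
0.018 and 2–7-day probability 0.014 (7-day total 0.032); in-hospital death
0.032; tracheostomy 0.0012; 1% arriving intubated; a perioperative-dominant
location mix (85%); lognormal durations (σ = 0.9) with means 44.7 h
pediatric and 15.8 h adult, floored at 2 h. Documentation probabilities
default to flowsheet 0.95, LDA 0.95, anesthesia 0.75, procedure 0.40, with
per-source Gaussian timestamp jitter (defaults 30 / 10 / 2 / 60 min)
truncated at ±24 h, rounded to the minute, and clamped inside the encounter
window so noise never masquerades as invalid data. Reintubation is
simulated by chaining a second episode with a gap drawn uniformly inside
the target window (at least 1 h from every window boundary), which makes
the window metrics exactly checkable. Scenario switches: transfers arriving
intubated omit all placement documentation (only the admission flag
remains); deaths omit extubation documentation from a configurable source
subset (default LDA and anesthesia — flowsheets chart until death);
tracheostomies always appear in procedure records and end the flowsheet
run at the tracheostomy time. The `noise_free` preset (all documentation
probabilities 1, zero jitter, no deaths/tracheostomies/transfers/
reintubation) defines the exact-recovery regime: n patients ⇒ exactly n
episodes, every endpoint minute-exact, every grade 1A.

What the generator does **not** emulate: duplicate or contradictory
charting within one source, free-text documentation, device exchanges,
post-tracheostomy ventilation weaning, inter-facility record fragmentation,
or realistic location-conditional case mix. Passing tests therefore
demonstrate algorithmic correctness under the stated documentation model,
not performance on any institution's real data.

## Problem sizes and numerical choices

The test and acceptance suites use cohorts of 60–800 patients for unit and
property checks, 400 for noise-degradation curves, 500 for exact-recovery
and filter accounting, and 5,000 for rate recovery and window consistency —
large enough that binomial intervals around the simulated rates are
informative, small enough to keep a full run in a few minutes on one CPU.
Single-linkage clustering on sorted timestamps is exact (not approximate)
on the line; medians of even-sized timestamp sets are floored to the
minute; all randomness flows from a single integer seed through
`numpy.random.default_rng`, making every output byte-reproducible.

## Known limitations

* The source-priority rule resolves conflicting times by fiat; a weighted
  or learned reconciliation might time events better but would sacrifice
  auditability.
* Two true events closer together than the match window and invisible to
  the duplicate-split rule (documented by disjoint source sets) merge into
  one cluster; at default noise this affects well under 1% of reintubation
  pairs.
* Termination classification near simultaneous death and extubation
  documentation depends on the match-window tolerance; with very large
  jitter a death termination can be misread as a routine extubation.
* Locations are reduced to a closed eight-token taxonomy; unknown tokens
  collapse into "other".
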