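# Methods

## Problem and design

`querysignal` studies what people search for in the days surrounding their
first query about celiac disease or gluten, using per-user search-engine
query logs.  The design is event-anchored and self-controlled: each user's
first celiac-related query (CRQ) defines an index time t0, and each user
serves as their own control by contrasting their queries in the 14 days
before t0 with the 14 days after it.  No external outcome data are needed;
the "diagnosis-like" signal is the index event itself.

### CRQ detection and cohort filters

A CRQ is any query containing a word that starts with "celiac" or "gluten"
(prefix at a word start, so "celiacs" and "glutenfree" count but "eggluten"
does not).  A user enters the cohort iff they

1. have at least one query of any kind on or before the history cutoff
   (default September 1 of the study year) — this makes the washout
   observable,
2. have a first CRQ inside the index period (default October), and
3. have no CRQ during the washout window (default the 9 months before the
   index period).

The index time t0 is the earliest qualifying CRQ; ties at identical
timestamps are broken by file order (the ingest sort is stable), which
makes t0 deterministic.  Members are labelled **passing** when all their
CRQs fall on a single calendar day and **sustained** otherwise; sustained
interest is treated only as a proxy for having the condition or caring for
a patient, never as a diagnosis.  Distinct-day counting uses all CRQs in
the whole log span, not just the index month.

Two further flags are computed per member: *indicator-positive* (the user
issued a query containing a diagnostic work-up phrase such as "marsh
score", "duodenal biopsy" or "tissue transglutaminase"/"ttg") and
*self-identified* ("i have celiac" / "i was diagnosed with celiac" at a
word boundary, vetoed when an interrogative word such as "do", "how" or
"what" precedes the phrase — "do i have celiac" is a question, not an
assertion).  The final phrase word may continue ("i have celiacs" counts),
mirroring a substring search over mentions.

### Concept extraction

Symptoms, conditions and dishes are extracted by dictionary matching:
synonym phrases (normalized: lowercased, punctuation runs collapsed to
single spaces) must occur as contiguous word sequences at word boundaries.
Normalization collapses hyphens, so "gluten-free" and "gluten free" match
identically.  Matching is implemented as an n-gram index lookup, which
enforces the boundary rule by construction; a brute-force scan oracle in
the test suite checks equivalence.  Each concept is reported at most once
per query; one query may match several concepts and several categories.
The package ships small demonstration lexicons (36 symptoms, 40
conditions, 26 dishes); production-scale lists are supplied by the user in
the same TSV format.

### The query ratio

For a concept c, the query ratio is

    QR(c) = N_before(c) / N_after(c)

where N_before pools concept-matching query counts over members' before
windows [t0 − w, t0) and N_after over after windows (t0, t0 + w], w = 14
days.  The index query itself belongs to neither window.  QR > 1 means the
concept was searched more in the run-up to the index event.  Choices worth
stating:

* **Pooled counts, not per-user ratios.**  Per-user ratios are mostly 0/0
  on sparse logs; the pooled ratio is the ratio of two well-populated
  counts and has a simple delta-method standard error
  `QR · sqrt(1/N_before + 1/N_after)` under Poisson counting.
* **After-window denominator.**  The alternative denominator spanning the
  whole ±14-day range bounds the ratio by 1 and cannot produce the
  headline values above 1; it is available as `denominator="union"`.
* **Complete-windows truncation (default).**  Members whose after window
  runs past the log end (index events late in the final month) are
  excluded from pooled counts; otherwise N_after is systematically
  deflated for late adopters and every QR biased upward.
* **Minimum support.**  QR is reported as undefined when N_after < 10
  (configurable); undefined ratios are excluded from rankings rather than
  topping them with 0-denominator artifacts.  Optional +0.5 Laplace
  smoothing is off by default.

Rankings sort defined ratios descending with ties broken by larger
N_before, then concept id; they are produced for the full cohort and the
sustained subcohort separately.

### Temporal profiles

The event-anchored profile bins every member's queries by whole-day offset
floor((t − t0)/1 day) ∈ [−D, D] (so day 0 covers [t0, t0 + 1 day)) and
reports, per day, the concept's share of all queries divided by its share
over the whole profile range.  Under a constant concept rate every defined
ratio is ≈ 1; a pre-index burst shows up as ratios above 1 at negative
offsets.  Days with no queries are left undefined, and a concept never
queried yields an empty profile rather than a division error.

### Dietary shift

Recipe queries (a dish synonym at word boundaries, plus either a
recipe-intent cue — "recipe", "how to make", "bake", "cook" — or a
multi-word dish name) are mapped to dishes and, through the
recipe→ingredient map, to ingredients; ingredient counts are therefore a
linear function of dish counts.  Dishes and ingredients are ranked by the
smoothed log-ratio `log((N_after + 0.5)/(N_before + 0.5))`: antisymmetric
under swapping the windows, finite at zero counts, and monotone in the
underlying shift.  Items with fewer than 10 total counts are dropped.  The
score's exact form is a package choice; any monotone score reproduces the
same ordered lists.

### Classification

Each user is represented by the number of times they queried each symptom
and each condition strictly before their index date; comparison users
(non-members) receive pseudo-index dates drawn with a fixed seed from the
cohort's t0 distribution so both classes see comparable observation
windows (by default 5 comparison users per member).  "Linear regression"
is ordinary least squares on the 0/1 label, ranked as a continuous score —
deliberately not logistic regression, matching the stated modelling choice
— and the forest uses 50 trees.  AUC is computed on held-out folds of a
seeded stratified 10-fold split over users sorted by id, so fold
assignment is independent of input row order.

## The simulator

Real query logs of this kind are proprietary, so the package ships a
generator whose defaults encode the emulated study conditions: a
January–October span whose final calendar month is the index period, a
background Poisson query stream per user (1 query/user-day), per-query
concept probabilities in the 0.4–2% range, an adopter fraction of 5%, a
93%/7% passing/sustained mixture among adopters, 14-day windows, and a
rare post-index self-identification query.  Planted, recoverable structure:

* per-concept rate multipliers in [t0 − 14 d, t0) (extra Poisson queries
  for multipliers above 1, thinning below 1),
* a post-index shift of dish choice toward gluten-free dishes,
* sustained adopters make CRQs on 1 + Geometric(1/2) distinct days (mean 3
  days in total).

Consequences of keeping the planted labels consistent with the emitted
log:

* a *passing* adopter's interest dies with the index day — their
  gluten-free dish choices and any self-identification query are confined
  to day t0, since any "gluten"/"celiac" query on a later day would make
  them sustained by definition;
* non-adopters never emit queries containing "celiac" or "gluten" (their
  dish vocabulary excludes gluten-free dishes); otherwise they would enter
  the cohort without planted ground truth and corrupt recovery tests;
* an adopter whose t0 falls on the last day of the span has no later day
  available for a second CRQ day, so the realized sustained share sits
  ~3% (relative) below the configured 7%.

Timestamps are uniform within the day (no diurnal pattern — irrelevant to
day-level statistics); raw text carries light capitalization/punctuation
noise that normalization removes; identical (config, seed) produce
byte-identical logs.  The generator does **not** model sessions,
reformulations, misspellings, vocabulary drift, regional variation, or
correlated symptom queries (one concept per query, with a small fraction
of explicit two-concept templates to exercise the matcher).  Passing tests
therefore validate the *statistical machinery* — filters, counting,
ratios, calibration — not robustness to real-world text mess.

## Validation problem sizes

The validation suite regenerates its data at run time with the sizes
chosen so every check's stated precondition holds with margin: multiplier
recovery uses 1200 all-adopter users at background rate 1.5 and an
elevated-concept probability of 0.08, giving ≥1000 pooled after-window
counts; null calibration uses 2600 users with twenty 2%-probability
concepts for ≥500 pooled counts per concept; classifier calibration uses
2000 users (≈330 members, 5:1 comparison sampling); the dietary-shift
check uses 900 all-adopter users at 0.5 recipe queries/user-day over 20
seeds.  The planted-signal discrimination check reports the better of the
two model specifications, mirroring how the evaluation harness reports a
maximum attainable AUC.

## Known limitations

* Word-boundary dictionary matching misses misspellings, inflections not
  listed as synonyms, and paraphrases; it also allows one query to count
  toward overlapping concepts ("abdominal pain" matches both "abdominal
  pain" and "pain").
* The QR has no inferential apparatus attached (the delta-method SE is
  descriptive); rankings on few counts are noisy by construction, which is
  what the minimum-support rule mitigates.
* One passing/sustained dichotomy based on calendar days is sensitive to
  the log-local clock; timestamps are intentionally timezone-naive.
* The cohort report counts each excluded user under the *first* failing
  criterion (history → index CRQ → washout), so per-criterion tallies
  depend on that order.
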