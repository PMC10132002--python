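# Methods

## Problem setting

Two records of the same intake event arrive through different channels: a
voice assistant transcribes what the participant *said*, a web form stores
what they *typed*. Both carry an intake timestamp (when the participant
says they ate or drank), a submission timestamp, and one or more free-text
item descriptions. The analysis asks how well the channels agree
(relative validity — agreement between two imperfect instruments, not
against ground truth) and characterizes the voice channel's error modes.

## Counterpart matching

Matching runs within participant, over submitted entries only (partial —
unsubmitted — voice attempts never participate).

* **Step 1.** A voice entry and a web entry are counterparts when
  |intake difference| ≤ `intake_window_minutes` (default 5) and the web
  submission follows the voice submission by 0–`submission_window_minutes`
  (default 30). Both boundaries inclusive; the intake difference is
  absolute. The 5-minute slack absorbs relative spoken phrases ("just
  now", "ten minutes ago"); the 30-minute rule encodes the protocol of
  entering the web record directly after the voice record.
* **Step 2.** Voice entries unmatched by step 1 (typically because the
  assistant misheard the stated intake time) link to the *nearest
  subsequent* web submission within 30 minutes, excluding web entries
  already used.

Design choices the procedure itself leaves open, fixed here: matching is
one-to-one (a web entry never serves two voice entries); voice entries
are processed in ascending submission order; among feasible partners the
tie-break chain is smallest |intake difference|, then earliest web
submission, then lexicographic entry id. This makes the outcome
deterministic and order-insensitive, and an exhaustive enumeration oracle
in the test suite guards the sequential implementation against
pathological greediness on random instances. "Exact timestamp" in
reports means equality at minute resolution, computed after pairing —
stricter than the 5-minute pairing tolerance, so the statistic stays
informative.

## Word-set comparison

Tokens are lowercased runs of alphanumerics. Normalization maps number
words (one–twenty, tens to ninety) and the articles "a"/"an" to digit
strings, and plural nouns to singular by suffix rules (-ies→-y with a
short-stem guard, -es after sibilants and -us stems, then -s) with an
exception list for false plurals ("glass", "cheese", "hummus") and a
small irregular table. The function is idempotent — property-tested —
and deliberately minimal: no stemming, no stop-word removal, because the
automated comparison is defined as *sets of normalized words* and
anything further would blur what it measures. Counts are |W \ A|,
|A \ W|, |W ∩ A| over the two entries' normalized sets (items
concatenated per entry; duplicates collapse). This measure is
intentionally pessimistic: "1 x apple" vs "one apple" differ as written
even when semantically identical.

## Discrepancy classification

A deterministic surrogate for a judgment-based manual review.

* **Screen.** A pair is "different events" when no voice item shares any
  normalized *content* token (excluding pure digits and a small
  glue-word list: of, with, and, x, …) with any web item.
* **Alignment.** Items are aligned one-to-one by exhaustive search over
  injective assignments (entries hold few items), maximizing summed
  similarity = shared normalized tokens + homophone credits, where a pair
  only counts if it clears a floor of at least one shared content token
  or homophone pair. Ties break toward the smallest index tuple.
  Leftovers become extras.
* **Cascade.** First match wins: equal normalized sets → 1; symmetric
  difference fully explained by the homophone table → 5 (voice-side
  wrong form) / 6 (web-side) — when both sides hold wrong forms of the
  same word the item is reported as 5 with a both-sides flag, keeping the
  11-way partition exclusive; voice content ⊊ web content → 3; web ⊊
  voice → 4; unknown voice-side token within edit distance 2 of a web
  token with every web food noun still present → 7; a web food noun
  absent from the voice side → 8; otherwise → 2. Extra voice items are
  10 if they contain a known food noun, else 9; extra web items are 11.

The cascade order embodies two deliberate resolutions: a subset relation
caused purely by a homophone is a misspelling, not missing detail; and a
near-miss token is only a "recognizable" garble (7) if the food's essence
survives, otherwise the essence test (8) takes over. "Essence" is
operationalized as presence of the vocabulary food noun — a heuristic
that will misjudge items far outside the built-in vocabulary.

## Summary statistics

Quartiles use linear interpolation between order statistics (the
convention is recorded in every report, since Tukey hinges differ).
The paired two-tailed *t* test on per-participant entry counts is
computed from its closed form, t = mean(d)/(sd(d)/√n) with n−1 df
(cross-checked against an independent implementation in tests);
participants appearing in only one source count zero in the other.
Percentages are emitted with raw value, one-decimal and integer
roundings, and numerator/denominator, so any display convention can be
cross-footed; zero denominators omit the entry rather than propagate
NaN. Denominators follow reporting convention: the same-item share is
given against both the web-item and voice-item totals, per-category
shares of the "differing" subset use the categories 2–7 total, the
major-issue share uses the voice-item total, and the to/two share uses
the voice-misspelling count. The Bland-Altman-style table has one row
per pair: signed difference (voice intake − web intake, minutes) against
web intake time of day, web time as reference since typed times are
rarely misheard.

## Synthetic cohort generator

Emulates the data structure the analysis assumes — it is the package's
test-bed, not a reconstruction of any real cohort.

* **Events.** Per participant and day, Poisson(`events_per_day`, default
  2.5) events uniform over 07:00–22:00, for `days` (default 7) days.
* **Items.** 1–3 items per event from a closed grammar: quantity +
  optional container + optional adjective + head food noun + optional
  "with X" accompaniment, over ~65 food nouns, 9 containers, 15
  adjectives. Every item carries a container or adjective so each
  corruption branch has a valid target and corrupted items remain
  alignable.
* **Corruption.** Per item, one branch is drawn: homophone (cat 5,
  default 0.10), less detail (3, 0.11), more detail (4, 0.02), different
  detail (2, 0.026), recognizable garble (7, 0.062), major garble (8,
  0.048); remainder is identical (1). Defaults approximate the category
  mix a voice-diary pilot reports. When the homophone branch fires the
  item's quantity is drawn from the homophone-able number words with
  "two" at weight 0.7, mirroring the dominance of the two→to confusion;
  the realized branch is always recorded in the ground truth, so realized
  rates equal configured rates. Minor garbles target container/adjective
  words (the canonical example garbles a container: "ball of yoghurt");
  major garbles replace the head noun with a non-food word. Web-side
  stylistic rewriting ("1 x apple") exists behind `p_web_style` but
  defaults to 0 so category ground truth stays exact.
* **Entry-level noise.** Extra meaningless voice fragments (cat 9,
  p=0.03/entry), extra web-only items (11, 0.11), abandoned partial voice
  attempts replacing the submitted entry (p=0.30, chosen so partial and
  submitted voice counts sit in the ratio a pilot observes), and
  participants with no web entries at all (p=0.19).
* **Timestamps.** Voice intake lands exactly on the event minute with
  probability 0.7, else jitters uniformly within ±`intake_jitter_minutes`
  (5); with p=0.02 it is grossly misheard (±2–48 h). Voice submission
  follows the event by 1–15 min; web submission follows it by offset +
  Exponential(scale) minutes (default (1, 10)), putting ≈5% of delays
  beyond the 30-minute window so some entries are genuinely unmatchable.
  All timestamps are minute-resolution naive local times; all randomness
  flows from one seeded NumPy generator, so cohorts are bitwise
  reproducible.

What the generator does **not** model: acoustic/ASR mechanics (corruption
is text-level), category 6 (web-side typos) and category 10 (real foods
the web user forgot) — the classifier supports both, exercised on
constructed examples; free-text style outside the grammar; participant
drop-out within the week. Passing tests therefore demonstrate that the
pipeline recovers known structure of this synthetic form, not that the
rule cascade matches human judgment on arbitrary real diary text.

## Problem sizes in tests

Property suites use 1,000 random ≤8×8 matching instances against the
exhaustive oracle, ~2,000-item corpora (90 participants × 7 days) for
category-rate recovery within 3 binomial standard errors, and 10–30
participant cohorts for end-to-end checks; the full suite runs in a few
seconds.

## Known limitations

* The classifier is a deterministic surrogate for human review; category
  boundaries (especially 7 vs 8, and 2 for out-of-vocabulary swaps)
  follow the food-noun heuristic and the edit-distance-2 garble rule.
* The singularizer is a rule table, not a dictionary; irregular plurals
  outside its exception lists normalize imperfectly.
* One-to-one matching is an analysis choice; a protocol in which one web
  entry summarizes two voice entries would be scored as one match plus
  one miss.
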