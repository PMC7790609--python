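# Methods

## Problem and scope

`dvminer` analyses corpora of police-recorded domestic-violence (DV) events,
each combining structured fixed fields (per-role person ids, sex, age,
person counts, a boolean "mental illness related" flag, year) with a
free-text narrative. The goal is the prevalence of mental-illness and
psychotropic-medication mentions for the two roles in an event — the person
of interest (POI) and the victim — stratified by sex and age, and contrasted
with the structured flag. Because real corpora of this kind are confidential
administrative data, the package pairs the analysis pipeline with a
synthetic-corpus generator whose gold ledger makes every downstream claim
testable.

## Extraction model

Extraction is dictionary- plus rule-based, deliberately precision-oriented:

- **Dictionary.** Surface forms (conditions, drug classes, brand names,
  generic phrases like "mental health issues") live in a tab-separated file
  with explicit variant spellings and abbreviations. Matching lowercases a
  copy of the text and requires word-boundary, exact (variant-listed) hits;
  there is no stemming and no edit-distance correction, because police
  jargon makes both unsafe and explicit variants keep precision auditable.
  Overlapping hits resolve longest-first ("paranoid schizophrenia" beats
  "schizophrenia").
- **Sentence scope.** Narratives are segmented at `.`/`!`/`?` followed by
  whitespace. The generator's templates are terminator-delimited, so this
  splitter is exact on synthetic text; real narratives with abbreviations
  would need a statistical segmenter, which is out of scope here.
- **Semantic anchors.** A hit produces a mention only if its sentence
  contains a role anchor. The default vocabulary — POI: {poi, defendant,
  accused, offender, perpetrator}; victim: {victim, vic} — is configurable
  in `rules.yaml` and is an assumption: published descriptions of such
  systems list example anchors, not the full set.
- **Attribution.** When a sentence contains anchors of both roles, the
  mention goes to the nearest anchor in character distance, ties to the
  preceding anchor. This is the simplest auditable mechanism consistent
  with sentence-scoped rules.
- **Deduplication.** Within one event, repeated (role, code) pairs collapse
  to the first occurrence, so one event contributes at most one mention per
  role per condition but several *different* conditions may be counted.
  Per-event (rather than per-person-history) deduplication is what makes
  mention totals exceed event counts in the reports.
- **No negation handling.** "POI does not have depression" still fires.
  This is a known limitation, kept deliberately: the evaluation module
  makes its cost measurable rather than hiding it behind heuristics.

## Hierarchy and normalization

The 4-level hierarchy has exactly 26 level-1 categories: 18 ICD-10-derived
chapter blocks (e.g. `F30-39` mood disorders) and 8 custom categories —
four medication groups (antianxiety, antidepressants, neuroleptics,
antipsychotics, for mentions that imply illness only through a drug) and
four non-ICD buckets (drug-prescription abuse, substance abuse unspecified,
traumatic brain injury, unspecified drug-induced disorders). Custom codes
use an `X-`/`MED-` prefix namespace so they cannot collide with ICD codes.
Level 4 is folded into level 3 for reporting (e.g. "intermittent explosive
disorder", level 4, reports under the level-3 impulse-disorder slot). A
mention counts at a level iff its dictionary entry's depth reaches that
level; this is the only reading under which strictly decreasing per-level
totals are coherent, and it yields the invariant n₃ ≤ n₂ ≤ n₁.

The shipped dictionary is a seed: it covers every condition, drug class and
brand name the package's reports and tests exercise (~290 surface forms),
not a full ICD-10 terminology. Extending it is a data edit, not a code
change. Generic phrases map only to the level-1 "unspecified mental
disorder" (F99) bucket; brand names map only under medication groups; both
constraints are validated at load time.

## Cohort and person collapsing

Sentence-scoped attribution cannot distinguish between several POIs or
several victims, so the analysis keeps only events with exactly one of
each. Person identity comes from structured ids only. A person appearing as
POI in one event and victim in another occupies both ledgers independently.
A person's `has_mi` is true iff any of their filtered events carries a
mention for their role; demographics come from their first filtered event
(conflicts are logged). Ages use seven left-closed bands: 0–14, 15–24,
25–34, 35–44, 45–54, 55–64, 65+.

## Prevalence statistics

- Percentages are half-up rounded to 2 decimals (`decimal`-based, not
  banker's rounding — required to reproduce conventionally printed tables).
- 95% CIs default to the binomial normal approximation
  p ± 1.96·√(p(1−p)/n), clipped to [0, 100] and half-up rounded to 1
  decimal; Wilson intervals are available via `method="wilson"` but are not
  the default because the normal form matches how such intervals are
  printed for corpus-scale denominators.
- Events with unknown sex/age are excluded from the corresponding stratum
  but retained in overall counts, which is why stratum denominators need
  not sum to the corpus size.
- Category tables report, per code and role, the mention count, the share
  of that role's mention total at the same level, and "prevalence" — the
  count as a percentage of all filtered events. Rows sort by POI count.
- The fixed-field comparison reports flagged events, mined events, and
  their ratio (2 decimals); a corpus with no flagged events reports the
  ratio as undefined (`None`) rather than raising.

## Synthetic corpus generator

The generator emulates the *statistical structure* the analysis assumes,
not natural language. Narratives are assembled from ≥20 sentence templates
per role (diagnosis, medication and generic-illness phrasings) plus neutral
incident filler; each mention sentence contains exactly one role anchor, so
gold attribution is unambiguous by construction. Defaults are calibrated to
corpus-scale rates reported for police DV data:

| parameter | default | meaning |
|---|---|---|
| `p_single` | 0.846 | event has exactly one POI and one victim |
| `p_mention_poi` | 0.128 | event carries ≥1 POI mention |
| `p_mention_victim` | 0.037 | event carries ≥1 victim mention |
| `p_flag` | 0.0103 | structured flag set (independent of mentions) |
| `p_second/third_mention` | 0.22 / 0.04 | extra distinct-category mentions, giving ≈1.27 mentions per mention-event |
| `typo_rate` | 0.10 | planted surface replaced by one of its listed variants |
| `distractor_rate` | 0.05 | anchor-free sentence containing an illness term (must not be extracted) |
| `category_weights` | corpus-scale level-1 mix per role | which condition gets planted |
| `events_per_poi/victim` | 1.94 / 1.71 | person-id reuse across events |

Sex weights (POI ≈ 79% male, victim ≈ 75% female, small unknown shares) and
age-band weights are similarly corpus-scale-informed; within a band, age is
uniform. All randomness flows through one `random.Random(seed)`, and output
serialization sorts keys, so a given config+seed is byte-identical across
runs.

Two closure properties hold by construction and are asserted in tests:
every planted surface form (typo-perturbed or not) exists in the shipped
dictionary, so recall on typo-free templates is 1; and distractor sentences
never enter the gold ledger. Consequently, passing extraction tests show
the rule engine is *internally* sound — correct anchor scoping, longest
match, deduplication, role attribution — but say nothing about recall on
real police prose, whose phrasing variety, negations, coreference ("he has
depression") and cross-sentence structure the templates do not model. The
synthetic precision/recall figures are upper bounds for real-corpus
performance, not estimates of it.

## Evaluation

Precision (the share of extracted mentions that are correct), recall and F1
are computed overall and per role under greedy one-to-one matching in
document order. The default matching key is (event id, role, level-1
category): credit is judged on attributing the right *kind* of condition to
the right person, with `match_mode="exact"` available for code-level
strictness. TP+FN equals the gold count and TP+FP the prediction count by
construction.

## Numerical and design choices

- Rounding: half-up everywhere percentages are printed; internal arithmetic
  uses exact `Decimal` division for percentages and float math only inside
  the CI square root.
- Spans are 0-based half-open intervals into the raw narrative; no
  normalization that would desynchronize offsets is ever applied in place.
- Degenerate inputs: empty corpora yield empty reports; zero denominators
  raise `ValueError` for percentages/CIs but produce `None` markers where a
  rate is legitimately undefined (empty-ledger summaries, zero flagged
  events, undefined precision with no predictions).
- Problem sizes in the shipped tests and acceptance script (corpora of
  40–5,000 events, 20-seed sweeps) were chosen so statistical checks have
  3-standard-error resolution while the whole suite stays fast; the
  binomial tolerance bands are computed analytically from the configured
  rates, never fitted to observed runs.

## Known limitations

- No negation, no coreference, no cross-sentence attribution; multi-POI or
  multi-victim events are excluded rather than resolved.
- The dictionary is a seed lexicon, not a terminology; real deployments
  would extend it (and the anchor vocabulary) from corpus audits.
- The generator does not model narrative length distributions, reporting
  style drift over years, or correlation between the structured flag and
  narrative content (the flag is independent by default).
- Event-level and person-level prevalence are reported side by side; no
  ordering between them is assumed or asserted, as either can dominate
  depending on repeat-event structure.
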