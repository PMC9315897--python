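# Methods

This note records the modelling choices behind `depehr`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic data does and does not emulate, and where the design was
genuinely open.

## Cohort model and selection criteria

A patient record couples cancer-registry attributes (cancer type, stage,
chemotherapy flag, diagnosis date) with a dated visit timeline; each visit
carries ICD-9-CM codes and one or more free-text notes in Spanish or
Catalan. The diagnosis date is the **index date** that splits the timeline.

Selection mirrors the study design for this kind of before/after analysis:
exactly one qualifying cancer (breast — women only — or colorectal), at
least two visits strictly before and two on or after the index date (so
both periods are observable), stage in {in situ, I, II, III} (stage IV
patients receive palliative care and are excluded), and complete treatment
information (operationalized as a non-missing chemotherapy flag).
Exclusions are tagged with the first failing rule in that order.

**Index-date tie rule.** Events dated exactly on the diagnosis day count as
"after" by default: diagnosis-day notes typically concern the cancer
episode itself. The rule is a flag (`diagnosis_day_is_after`) because the
opposite convention is defensible.

## Term matching

Matching is dictionary-based. Surfaces and note windows are compared after
normalization (casefold, NFKD diacritic stripping, whitespace collapse);
raw surfaces are preserved for reporting. Each k-token window is checked
against k-token surfaces; a hit requires optimal-string-alignment
(Damerau–Levenshtein with adjacent transposition, no double-edit of a
transposed pair) distance 0, or 1 when the lexicon surface is at least 5
characters long. The ≥ 5 threshold exists because single-edit matches on
short terms are mostly noise ("ixel" → "piel"). Overlapping candidates
resolve deterministically: longest span, then smallest distance, then
leftmost, then category/concept identifiers. The implementation uses
first-character buckets plus suffix maps so that candidate generation is
provably complete for distance ≤ 1 without scanning the whole lexicon per
window; tests verify equivalence against an exhaustive window × surface
oracle with an independently implemented distance.

Matching is language-specific: the note's language is identified first
(counts of discriminative function words and word-final n-grams from two
fixed profiles; `unknown` falls back to the full lexicon), and only
surfaces tagged for that language (or `both`) are searched.

## Negation

Negation is a token sequence labelling task over BIO labels for the marker
and its scope. Two detectors are provided:

- **CRF tagger** (`depehr.crf`): a linear-chain conditional random field
  with binary emission features and a dense 5×5 transition matrix, trained
  by penalized maximum likelihood (L-BFGS; L2 weight 0.5, up to 120
  iterations). The objective is convex and the optimizer deterministic, so
  retraining on the same corpus reproduces identical predictions; the seed
  is recorded in the model metadata for provenance. Features are
  orthographic (lowercased surface, word shape, 3-character prefix/suffix,
  punctuation/digit flags) plus membership in per-language trigger lexicons,
  for a −2…+2 token window, with sentence-boundary flags. No part-of-speech
  input is used: trigger-lexicon and shape features carry the same signal
  for this task without a tagger dependency. Decoded label sequences are
  repaired deterministically (an I-X without a preceding B-X/I-X is read as
  B-X). No CRF library ships in the dependency set; the implementation is
  ~200 lines and exactly inferable (forward–backward, Viterbi).
- **Rule baseline**: NegEx-style — each trigger token ("no", "sin",
  "niega", "sense", "nega", …) opens a scope over the next `window` tokens
  (default 5), truncated at punctuation or a conjunction terminator
  ("pero", "aunque", …).

A mention is negated iff its character span overlaps a detected scope by at
least one character (half-open intervals; abutting is not overlap).
Sentences are segmented at '.', ';' and newlines; scopes never cross
sentences. Hedging, family history, and subject attribution are out of
scope.

## Synthetic data: what it emulates, and what it does not

The generator's defaults encode the study-cohort structure rather than
convenient values:

| parameter | default | rationale |
|---|---|---|
| `cancer_mix` | 0.48 breast | breast/colorectal ratio of the analyzed cohort |
| `stage_probs` | (.17, .26, .31, .18, .08) | selected-cohort stage gradient, plus a stage-IV share to exercise the exclusion filter |
| `p_depression_before` / `after` | 0.08 / 0.27 | before/after evidence prevalence implied by the combined-channel paired counts |
| `channel_probs` | icd .65, drug .55, disorder .35 | relative sizes of the three evidence channels among evidence-positive patients |
| `p_chemo` | breast .446, colorectal .256 | chemotherapy rates by cancer type |
| ages | N(62.3, 13.2) / N(70.5, 11.4), clipped 25–95 | per-type age distributions |
| `language_mix` | 0.6 Spanish | the bilingual corpus proportion (572 es / 277 ca) |
| `negation_rate` | 0.15 per visit | plausible decoy-negation density; high enough to test exclusion |
| `misspelling_rate` | 0.1 | typo rate per planted term; study-condition runs use 0.0 and 0.2 |
| `visits_per_patient` | 4–12 | at least the 2+2 the selection filter requires |

Before- and after-period depression are sampled independently per patient;
given a depressed period, each channel emits evidence independently with
its channel probability. Temporal-class ground truth is recorded from what
was actually planted, so downstream recovery checks are exact. No
longitudinal disease model is simulated: the analysis consumes only the
temporal class, so richer dynamics would add nothing testable.

Notes are template-rendered (clinical-style sentence skeletons per
language) so every span and scope is known exactly. Misspellings are a
single OSA edit on a letter position, constrained to stay at distance ≥ 2
from every other lexicon surface, and only applied to surfaces of ≥ 5
characters — i.e. exactly the error class the matcher tolerates. This is a
deliberate pairing: it makes recall properties provable, and it means a
100% recall result certifies the matcher's contract, not robustness to
arbitrary real-world typography (multi-edit errors, abbreviations, OCR
noise are not modelled). Similarly, template fillers contain no lexicon
surfaces or triggers, so the zero-false-positive results bound the
pipeline's behaviour under its stated assumptions, not on free prose. The
negation corpus defaults to 572 Spanish and 277 Catalan sentences, 70%
containing a planted negation; the printed corpus description those
proportions mirror is internally inconsistent about its own total, so the
per-language counts were taken as authoritative.

## Statistics

McNemar's test uses the Edwards continuity correction
`(|b−c|−1)²/(b+c)`: it is the variant that reproduces the published
statistics from the published discordant counts (an uncorrected option is
provided). The chi-square(1) upper tail gives the p-value; tests verify
agreement with an exact binomial sign test over random discordant pairs.
Independence tests are Pearson chi-square without continuity correction
(delegated to `scipy.stats.chi2_contingency`); the chemotherapy ×
depression association is a 2×2 of that form. Percentages render with
half-up rounding to one decimal, printing integer-valued percents bare
("(91)"), matching the report style.

## Numerical and degenerate-input choices

- `b = c = 0` is an undefined McNemar test and raises; all-"both" cohorts
  yield a zero-denominator paired table that still validates.
- Overlap-resolution ties beyond (length, distance, position) break on
  category then concept id, purely for cross-run determinism.
- Lexicon duplicates (same normalized surface and category) collapse with
  a warning; a brand naming an unknown substance is an error.
- Visits are ordered by (date, visit id); date granularity is the calendar
  day.
- Empty cohorts render empty tables and a zero attribution split without
  error.

## Problem sizes

Tests and the acceptance script run the full pipeline at n = 2000 patients
(≈ 16k notes) and train the tagger on the 849-sentence default corpus;
these sizes give stable, repeatable metrics while keeping a full run in the
order of a minute on a single CPU.

## Known limitations

- The bundled lexicons are representative stand-ins (35 substances,
  82 brands, ~16 disorder concepts), not a licensed SNOMED CT or
  nomenclature release; real deployments should load their own TSVs.
- Language identification is profile-based and tuned for clinical
  note-style text; code-switched or very short notes may return `unknown`.
- The matcher does not expand abbreviations or handle distance-2 errors.
- The CRF's near-perfect synthetic F1 reflects template regularity; on
  manually annotated clinical sentences the same architecture would score
  substantially lower and the feature set may need enrichment.
- No confounder adjustment, incidence-rate, or time-to-event modelling:
  the paired before/after design is taken as given.
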