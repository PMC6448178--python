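# Methods

## Problem and model

Free-text radiology reports are the primary record of fracture diagnoses
in most EHRs. `fxtag` casts fracture identification as multi-label,
sentence-scoped pattern matching: a patient is positive for one of twenty
skeletal sites when at least one sentence in one of their reports contains
both a *fracture modifier* (a term asserting fracture status: "fracture",
"fx", "broken", "displaced", ...) and a *site term* for that skeletal
site, in either order, and the sentence is not negated. This mirrors how
radiologists phrase positive findings ("Comminuted fracture of the left
clavicle", "The clavicle appears fractured") while refusing to fire on
anatomy mentioned without a fracture assertion ("The clavicle is
intact").

The pipeline is: JSON-Lines corpus → sentence segmentation → per-sentence
bidirectional rule matching → sentence-scoped exclusion → document label
(any non-excluded mention) → patient label (OR over documents) →
per-site and micro-averaged metrics against per-patient gold labels.

## Lexicon handling

The default lexicon is stored verbatim in `src/fxtag/data/` (one
tab-separated row per site plus one modifier row) and normalized at load
time. Normalization is deliberately minimal and fully specified: split on
top-level `|`, trim each branch, drop empty branches, fold curly
apostrophes to ASCII, rejoin. Empty branches matter: an empty alternation
branch matches the empty string at every position, which would make the
affected site fire on every sentence and destroy specificity — the
doubled-`||` and trailing-`|` forms in the source tables are treated as
typesetting artifacts and repaired, while the verbatim row is retained on
`RawPattern.source_text` for audit. Normalization does not touch the
inside of groups; concatenated forms such as `(inversion)?ankle` are kept
as printed even where a space was plausibly lost in typesetting, because
inventing token boundaries would silently change matching behavior.

Two open choices were resolved as follows:

* **Case.** All matching is case-insensitive. Radiology text freely mixes
  "FRACTURE", "Fracture" and "fracture", and site terms appear in
  headers, impressions and body text with inconsistent casing.
* **Word edges.** The rule template brackets the match with `\b`. We
  bound *each* of the two components on *both* sides, and use the
  lookaround pair `(?<!\w)…(?!\w)` rather than `\b`. Bounding both ends
  of both components is required to reproduce the documented behavior on
  compound words (no bounded `maxilla` inside "maxillofacial"); the
  lookarounds behave identically to `\b` for word-character edges and
  additionally bound branches that end in punctuation (`colles'`,
  `smith's`, `r/o`, `naso-orbital`) when followed by a period or comma,
  where `\b` would spuriously fail.

`lint_lexicon` reports (as warnings, never failures) branches shared
verbatim by several sites — `navicular` (feet/hand) and `supracondylar`
(distal femur/distal humerus shafts) in the default lexicon — plus
branches under three characters (`mc`) and stray unescaped dots. Site
overlap is *not* arbitrated at match time: every matching site fires, and
per-site evaluation treats them independently.

## Sentence segmentation

The matcher's `.*` gap is unbounded within a sentence, so segmentation is
the effective gap control. The splitter breaks after `.`, `?` or `!`
followed by a space/tab and at every newline run (radiology notes are
line-oriented; a newline always terminates a statement, which keeps the
gap from spanning list items). A small configurable abbreviation list
("Dr.", "vs.", ..., in `data/abbreviations.txt`) and a single-capital
initial rule ("J. Smith") suppress false splits. Offsets are 0-based
half-open into the unmodified note text (case folding happens inside the
matcher only), so every sentence re-slices exactly and audit spans point
into the original note.

Run-on text without delimiters is *not* repaired — a missed boundary lets
a modifier reach across two statements, which is a real and documented
failure mode of sentence-scoped rules; the synthetic generator reproduces
it on demand (`runon_rate`).

## Exclusion

The exclusion keyword list is exactly `rule out`, `r/o`, `negative`,
matched case-insensitively and word-bounded, with whole-sentence scope:
one keyword anywhere suppresses every mention in that sentence. This
knowingly over-suppresses sentences like "The bone scan was negative for
X, although an acute fracture in Y was noted" (both halves are
suppressed) and under-suppresses phrasings outside the list ("does not
appear", "no evidence of"). Both behaviors are intrinsic to the published
keyword list; the list and the scope are configurable
(`ExclusionConfig`), and an optional `pre_category` scope restricts
suppression to keywords occurring before the site term.

## Evaluation

Metrics are computed from per-site 2×2 patient counts with the five
formulas given in the README. Decisions:

* The evaluation unit is the **patient** (gold standards for fracture
  cohorts are abstracted per subject); a per-document unit exists for
  debugging (`fxtag tag --unit document`).
* Any 0/0 metric is **undefined**, carried as `None`/`NaN` and rendered
  `NA`. Coercing to 0 or 1 would bias site-level tables for rare sites;
  micro-averages are unaffected because pooled counts are summed before
  dividing.
* `micro_average` is implemented as `compute_metrics` of the summed
  counts, making the defining identity structural; an independent
  cross-check against scikit-learn on random tables is part of the test
  suite (agreement to 1e-12).
* Reports are rendered at 3 decimals with full precision retained in the
  returned DataFrame.

## Synthetic corpus generator

The generator emulates the report phenomena the rules must survive, not
clinical realism (no sections, headers or templated normals). Per
patient it samples true fracture sites, then plants one sentence per true
site into 1–3 notes:

* **Affirmative**: "<Modifier> of the <site term>." where both halves are
  concrete expansions of default-lexicon branches (an AST-based expander
  resolves alternations and optional groups; `.*` gaps become a space).
  Site terms are placed sentence-finally so patterns that require a
  trailing space cannot leak across template words.
* **Negated** (probability `negation_rate`): the same content wrapped
  with an exclusion keyword ("Cannot rule out …", "Negative for …",
  "R/o …"). Negated plantings do not count toward gold.
* **Distractor** (`distractor_rate` per note): a site term with no
  modifier ("Normal alignment of the …").
* **Run-on** (`runon_rate`): adjacent sentences joined without a
  delimiter, defeating sentence scoping.
* **Hard cases** (`hard_case_rate`, default 0): cross-sentence
  co-reference ("Cortical irregularity of the X. Findings likely
  represent a small fracture.", gold-positive but undetectable by
  sentence-scoped rules) and scoped negation ("It does not appear the X
  fracture …", gold-negative but matched). These exist to verify the
  tool reproduces the known failure modes, not to fix them.

Gold is defined by construction: positive iff ≥1 affirmative non-negated
planting (hard co-reference cases also count as true). The default
planting vocabulary contains only terms that fire exactly their own site;
cross-site collision terms (`navicular`, `supracondylar`, ...) are
excluded by default so that a corpus generated with `negation_rate=0` and
`runon_rate=0` round-trips through the tagger with micro sensitivity and
specificity exactly 1.0 — this round trip validates pipeline plumbing and
generator/matcher consistency, not clinical accuracy. A flag re-enables
collision terms to exercise multi-label behavior.

Defaults, chosen once as plausible for a fracture-enriched population and
fixed: `prevalence=0.08` per site (≈1.6 true fractures per patient, the
order of magnitude seen in fracture cohorts), `notes_per_patient=(1,3)`,
`negation_rate=0.1`, `distractor_rate=0.3`, `runon_rate=0.05`. All
randomness flows from a single `seed`; equal specs yield byte-identical
corpora.

What passing the synthetic tests does **not** show: performance on real
reports, which contain vocabulary outside the lexicon ("lamina
papyracea", "debride"), section structure, co-reference, richer negation
("no evidence of"), and institution-specific sublanguage. Published
validations of this rule family on clinical cohorts report high
specificity/PPV with sensitivity limited by exactly these phenomena.

## Numerical and degenerate-input choices

* One mention per (sentence, site): labels are boolean; extra pairs would
  only add audit noise. When both rule orders match, `modifier_first` is
  reported (fixed tie-break); spans are the leftmost match with the lazy
  (shortest) gap.
* Empty note text yields zero sentences and an all-false label vector;
  an empty patient set or empty category set is an error in evaluation.
* Confusion tabulation requires identical patient sets and lists the
  offending ids otherwise.
* Branch expansion caps at 10,000 alternatives per branch and rejects
  constructs outside the lexicon dialect (classes, `+`, `{}`, bare `.`)
  with the offending branch named.

## Problem sizes

The bundled checks use corpora of 40–200 patients and oracle samples of
300–1,000 random sentences; the matcher's brute-force oracle equivalence
and the clean round trip are exact at these sizes, and the quantities in
`scripts/acceptance.py` are recomputed at the same sizes.

## Known limitations

No section awareness (FINDINGS vs IMPRESSION), no co-reference
resolution, no scoped/parsed negation, no use of note-type metadata to
disambiguate hand vs foot films, no de-identification, and no arbitration
of overlapping site vocabularies ("navicular"). The bare Vertebral Body
branches "axis", "burst" and "collapse" are highly ambiguous in general
prose and are kept as published.
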