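# Methods notes

## The detection model

`shxd` is a lexicon-and-rules classifier.  Each of the seven categories
is decided by regular expressions over the raw note text, compiled with
`re.IGNORECASE | re.MULTILINE` (the declared dialect is Python `re`;
case folding applies inside character classes, and `\s` matches
newlines).  There is no sentence splitting, section segmentation,
negation detection or abbreviation expansion: the model's assumption is
that clinicians use a small, stable phrase vocabulary when documenting
sexual history, and that a transparent pattern list a clinician can read
beats a higher-capacity model that cannot be audited.  Known
consequences of that assumption are kept, not patched: "BF" for
boyfriend is invisible, "denies ever having been sexually active" misses
the denial lexicon, and "no clubbing/cyanosis" false-positives the `g/c`
testing shorthand.

Matching operates on raw text so evidence spans (0-based, half-open
character offsets) always index the original note.  Spans are found per
pattern with the standard leftmost, non-overlapping scan; a category is
positive iff at least one span survives exclusion suppression.  Ties
between patterns are irrelevant because positivity needs only one
surviving span.

### Exclusion semantics

An exclusion pattern suppresses any match span that shares at least one
character position with one of its own matches ("condom" inside "condom
catheter"; "chlam" inside "chlamydia pneumonia").  Overlap-by-one was
chosen over containment because every motivating hard negative is a
strict containment anyway, and overlap is the weaker (safer) condition.
Exclusions can only suppress: adding one never turns a label on, and
removing all of them never turns a true label off (a property the test
suite checks over randomized inputs).

### The partner-gender window rule

Partner gender is the one category where a bare lexicon is hopeless —
"male"/"female" appear constantly in demographics.  Positivity therefore
requires a gendered target (`male`, `boy`, `girl`, `men`, `man`;
substring semantics so "female" and "women" count) inside a window from
50 characters before an anchor match's start to 50 characters after its
end, clipped at text boundaries.  Anchors are the sexual-history
patterns (`sex` + follower, `intercourse`).  Start-to-end anchoring is
the most permissive reading consistent with the worked examples; windows
are whole-text, not clipped at sentence boundaries.  Targets must lie
entirely inside the window (the window substring is searched).

### Follower class and end-of-text

The overall sexual-history pattern requires a follower character after
"sex" (letter, comma, period, whitespace, slash) so that "Sex: Male"
stays negative.  A second pattern, `sex\Z`, accepts end-of-text as a
follower so a note that simply ends "…had sex" still counts.  Literal
single spaces in multi-word patterns ("no sex", "birth control") are
kept literal; line-wrapped phrases may be missed, which is faithful to
the rule set's design.

## Evaluation layer

Per category, predictions vs gold form the usual 2x2 table; sensitivity,
specificity, PPV, NPV are `100·TP/(TP+FN)` etc., and F1 is the harmonic
mean of sensitivity and PPV.  All metrics are computed with exact
rationals (`fractions.Fraction`) and rounded once to one decimal, half
away from zero; F1 uses the *unrounded* inputs (rounding first can move
the last digit — e.g. a 26/60 PPV with perfect sensitivity gives 60.5,
not 60.4).  A zero denominator makes a metric undefined; undefined
metrics are reported as `NA` rather than dropped so that categories
absent from a cohort stay visible.  No confidence intervals or
multiple-testing corrections are applied — these are descriptive audit
measures.

## The synthetic corpus generator

Real note corpora for this task are protected health information, so the
generator stands in for them.  It emulates exactly one thing: the
*phrase-level* content that drives this detector — category phrases
embedded among exam/plan boilerplate, demographic headers, device
mentions and lookalike abbreviations.  It does not attempt realistic
clinical narrative, template structure, spelling noise, or correlations
between categories beyond the one it must model (see below), so passing
tests show that the rules behave as specified on the phrase inventory,
not that they would hit any particular performance level on real notes
from a new institution.

Design:

- **Gold is semantic truth.**  Each bank phrase carries an authored set
  of category labels ("what a chart reviewer would record"); its regex
  label set is computed against the rule set when the bank is built, and
  the bank is rejected unless every phrase behaves as declared
  (positives: regex = semantics; planted false negatives: regex ⊂
  semantics; planted false positives: semantics ⊂ regex; fillers:
  all-false).
- **Composition is controlled.**  A note is a shuffled sequence of
  period-terminated sentences joined by spaces.  Sentence terminators
  prevent multi-word patterns and exclusions from bridging sentences,
  and gendered words outside partner-gender-positive phrases are
  confined to the note-start demographic header (followed by at least 62
  characters of neutral filler, putting it beyond any later anchor's
  50-character window) or to the optional beyond-the-window distractor
  appended after a guard gap at the end.  The generator verifies every
  emitted note: classifier labels must equal the union of the inserted
  phrases' regex labels.  Consequently classifier/gold divergence occurs
  exactly on the planted ledger.
- **Prevalence.**  Default semantic prevalences (sexual_history 0.40,
  protection 0.15, sti_testing 0.20, not_sexually_active 0.20,
  partner_gender 0.12, sexual_practice 0.04, contraception 0.12) follow
  the ordering seen in acute-care documentation audits, where roughly
  half of ED notes with STI-compatible complaints and a third of
  inpatient notes carry a sexual history and each component is rarer
  than the whole.  Partner-gender, practice and denial phrases
  necessarily mention sexual activity, so those categories imply overall
  documentation; the standalone documentation probability is solved so
  that the configured sexual-history marginal is recovered (within
  binomial noise — the suite checks 3 percentage points at n = 2000).
  Categories are otherwise sampled independently, so a note can contain
  both a denial and a practice phrase; that is a realism limitation, not
  a labeling inconsistency.
- **Determinism.**  One `random.Random(seed)` stream drives everything;
  identical configs produce byte-identical files.
- A planted phrase may legitimately diverge in more than one category
  (e.g. "BF uses protection" is a semantic positive for partner gender
  *and* overall history that the rules cannot see); the ledger records
  every divergent (note, category) pair, whatever phrase caused it.

## Numerical and interface choices

- Rule configs are YAML (JSON parses too): `name`, `version`,
  `rules.<category>.{match, exclude, window:{anchors, chars, targets}}`.
  The shipped `data/default_rules.yaml` equals `default_ruleset()`; a
  test enforces it.
- Validation returns a list of violations rather than raising, so a
  config author sees all defects at once; loading raises with the full
  list.
- Corpus and label files are JSONL/CSV, UTF-8; classification output
  omits evidence by default (audit-privacy posture) and includes it
  behind a flag.
- CLI exit codes: 0 success, 2 usage/input error; outputs are computed
  fully before writing so failures leave no partial files.
- Problem sizes in the test suite and acceptance script (200-note
  corpora, 2000 for prevalence recovery) were chosen as the smallest
  sizes at which every category is exercised and binomial noise is well
  inside the stated tolerances.

## Known limitations

- The rules are institution-shaped: different templates or abbreviations
  will shift performance, which is why the rule set is an editable,
  re-validated config file rather than code.
- Partner-gender specificity is intrinsically limited by gender words in
  nearby non-partner context (gender identity answers, chaperone
  documentation); the window rule narrows but does not remove this.
- The synthetic generator cannot certify real-world sensitivity or
  specificity; it certifies the mechanics (matching, suppression,
  windowing, scoring) and the documented failure modes.
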