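# shxd — sexual history documentation detector for clinical notes

Adolescents are screened for sexual health far less often than guidelines
recommend, and the only way most quality-improvement teams can measure
whether a sexual history was taken is manual chart review.  `shxd`
automates that audit step: it is a rule-based natural-language-processing
tool that scans free-text ED and inpatient notes and reports, per note,
whether **sexual history documentation (SHxD)** is present and which of
the CDC **5P's** components appear — partners, practices, past history of
STIs, protection from STIs, and prevention of pregnancy.

It is aimed at clinical informaticists and adolescent-health researchers
who need a transparent, auditable process measure they can run over
thousands of notes, not a black-box model.

## The method

Seven note-level categories are each driven by a small set of regular
expressions applied case-insensitively in multi-line mode:

| Category | Mechanism |
|---|---|
| `sexual_history` | `sex` followed by a letter, comma, period, space or slash (so "sexual activity", "no sex/drug use" match but the header "Sex: Male" does not), or `intercourse` |
| `protection_used` | `protect`, `condom`; matches overlapping `condom cath` or `child protect` are suppressed |
| `sti_testing` | `GC[^S]` (avoids the Glasgow Coma Scale), `G/C`, gonorrhea/chlamydia stems, `ST[ID]` + test/screen/lab; `chlam(ydia) pneumo` suppressed |
| `not_sexually_active` | a denial lexicon (`denies any sex…`, `no sex`, `never had sex`, `not sexually active`) |
| `partner_gender` | window rule: `male/boy/girl/men/man` within 50 characters of a `sex`/`intercourse` anchor ("female" and "women" match by substring) |
| `sexual_practice` | `(oral\|vaginal\|anal)` + `sex/penetration/intercourse` |
| `contraception_used` | contraceptive lexicon (`OCP`, `birth control`, `IUD`, `depo`, `planon`, …) |

A category is positive iff at least one match span survives exclusion
suppression (spans sharing a character with an exclusion match are
dropped).  Every label comes with its evidence spans for audit.

Predictions are scored against gold labels with the standard screening
measures — sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`, PPV
`TP/(TP+FP)`, NPV `TN/(TN+FN)` and F1 (harmonic mean of unrounded
sensitivity and PPV) — computed exactly with rationals and rounded once
to one decimal.

Because real chart corpora are protected health information, the package
ships a **synthetic corpus generator**: seeded, labeled ED/inpatient-style
notes whose gold labels are *semantic* truth, with controllable rates of
planted false positives (e.g. "no clubbing/cyanosis" tripping the g/c
pattern, gender-identity mentions near a sex anchor) and false negatives
(the "BF" abbreviation, denial phrasings the lexicon misses).  Every
intentional divergence is recorded in a ledger, so evaluation results on
synthetic data can be reconciled exactly.

## Worked example

```python
from shxd import ClinicalNote, classify_note, default_ruleset

note = ClinicalNote(
    note_id="ed-1", setting="ED",
    text="17 yo female with lower abdominal pain. Sexually active with her "
         "boyfriend, uses condoms some of the time. Will send GC/CT. "
         "On birth control for PCOS.")
result = classify_note(note, default_ruleset())
```

Running `python examples/classify_notes.py` prints:

```
ed-1 (ED):
  sexual_history: 'Sexu'
  protection_used: 'condom'
  sti_testing: 'GC/'
  partner_gender: 'male', 'boy'
  contraception_used: 'birth control'

ed-2 (ED):
  no categories detected

inpt-1 (inpatient):
  sexual_history: 'sexu'
  sti_testing: 'g/c'
  not_sexually_active: 'Denies any sex'
```

`ed-1` documents four of the 5P's plus overall history; the quoted
fragments are the match spans (note `'male'`/`'boy'` found inside
"female"/"boyfriend" within the 50-character window).  `ed-2` — a
demographic header, a Glasgow Coma Scale score and a condom catheter —
stays all-negative by design.  `inpt-1` shows a known failure mode: "no
clubbing/cyanosis" trips the g/c testing shorthand.

The same workflows are available from a shell:

```bash
shxd generate --out notes.jsonl --gold gold.jsonl --n 200 --seed 7
shxd classify --in notes.jsonl --out preds.jsonl --evidence
shxd evaluate --pred preds.jsonl --gold gold.jsonl --out report.csv
shxd rules-export --out rules.yaml   # edit, then: shxd classify --rules rules.yaml ...
```

## Layout

- `src/shxd/rulebook.py` — rule data model, validation, the default rule
  set and its YAML serialization (`src/shxd/data/default_rules.yaml`)
- `src/shxd/matcher.py` — span finding, exclusion suppression, window
  matching, note/corpus classification
- `src/shxd/evaluation.py` — confusion counts, screening metrics,
  documentation rates, CSV/markdown reports
- `src/shxd/synthcorpus.py` — phrase banks and the labeled-note generator
- `src/shxd/cli.py` — the `shxd` command
- `examples/` — one short narrative script per capability
- `docs/methods.md` — modelling and design notes
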