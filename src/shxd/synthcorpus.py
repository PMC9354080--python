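"""Seeded, labeled synthetic clinical notes.

The real corpora this detector targets are protected chart notes, so
testing relies on generated ED/inpatient-style prose.  Each generated
note is a bag of sentences: neutral exam/plan boilerplate plus, per
sampled semantic truth, category phrases drawn from curated banks.
Gold labels record *semantic* truth — what a chart reviewer would
write down — which deliberately diverges from regex output exactly
where adversarial phrases are planted:

* ``regex_negative`` phrases are semantically positive but invisible to
  the rules (e.g. the "BF" abbreviation for boyfriend, or a denial
  phrased in a way the denial lexicon misses), producing false
  negatives;
* ``regex_positive`` phrases trip a rule without the semantics (e.g.
  "no clubbing/cyanosis" matching the g/c gonorrhea/chlamydia
  shorthand, or "male" answering a gender-identity question near a
  sex-anchor), producing false positives.

Every phrase carries an authored semantic label set; its regex label
set is computed against the rule set when the bank is built, and the
bank is rejected if any phrase misbehaves.  Sentence assembly is
constrained (sentences are period-terminated; gendered words outside
partner-gender phrases appear only at a guarded distance from
anchors) so that the note-level classifier output equals the union of
the per-phrase regex label sets; the generator verifies this for every
note it emits.  Divergence between classifier and gold is therefore
exactly the planted ledger.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .evaluation import GoldLabels
from .io import PathLike, write_gold, write_notes
from .matcher import ClinicalNote, Setting, classify_note
from .rulebook import CATEGORIES, Category, RuleSet, default_ruleset

# Substrings that can satisfy the partner-gender target patterns; any
# sentence containing one is placement-restricted unless its own
# partner-gender regex label is already true.
_GENDER_TARGET = re.compile("male|boy|girl|men|man", re.IGNORECASE)

# Categories implied semantically by overall sexual-history documentation:
# a note that documents partner gender, a sexual practice, or a denial of
# activity necessarily mentions sexual activity.
_IMPLIES_SEXUAL_HISTORY = (
    Category.NOT_SEXUALLY_ACTIVE,
    Category.PARTNER_GENDER,
    Category.SEXUAL_PRACTICE,
)


class PhraseBankError(ValueError):
    """A phrase bank failed its build-time verification."""


def _as_sentence(text: str) -> str:
    text = text.strip()
    return text if text and text[-1] in ".!?" else text + "."


@dataclass(frozen=True)
class Phrase:
    """A sentence with its authored semantic label set."""

    text: str
    semantic: frozenset  # frozenset[Category]
    regex: frozenset = frozenset()  # computed at bank build time

    @property
    def sentence(self) -> str:
        return _as_sentence(self.text)


def _regex_labels(sentence: str, ruleset: RuleSet) -> frozenset:
    cls = classify_note(ClinicalNote(note_id="_probe", text=sentence), ruleset)
    return frozenset(c for c in CATEGORIES if cls.labels[c])


@dataclass
class PhraseBank:
    """Curated sentences per category, verified against a rule set.

    ``positive``        — semantically positive and regex-detectable;
    ``regex_negative``  — semantically positive, missed by the rules;
    ``regex_positive``  — semantically negative, tripping the rules;
    ``neutral_fillers`` — boilerplate classifying all-false (fillers
    containing gendered words, e.g. the demographic header "Sex: Male",
    are placed only at the start of a note with a padding guard);
    ``gender_distractors`` — gendered sentences with no anchor, used
    only for the controlled beyond-the-window negative variant.
    """

    positive: dict[Category, list[Phrase]]
    regex_negative: dict[Category, list[Phrase]]
    regex_positive: dict[Category, list[Phrase]]
    neutral_fillers: list[str]
    gender_distractors: list[str] = field(default_factory=list)

    def safe_fillers(self) -> list[str]:
        return [f for f in self.neutral_fillers if not _GENDER_TARGET.search(f)]

    def header_fillers(self) -> list[str]:
        return [f for f in self.neutral_fillers if _GENDER_TARGET.search(f)]


def _verify_phrase(phrase: Phrase, kind: str, cat: Optional[Category]) -> None:
    sem, reg = phrase.semantic, phrase.regex
    text = phrase.text
    if kind == "positive":
        if reg != sem:
            raise PhraseBankError(
                f"positive phrase {text!r}: regex labels {set(map(str, reg))} != "
                f"semantic labels {set(map(str, sem))}"
            )
        if cat not in sem:
            raise PhraseBankError(f"positive phrase {text!r} is not semantically '{cat}'")
    elif kind == "regex_negative":
        if cat not in sem or cat in reg:
            raise PhraseBankError(f"phrase {text!r} is not a regex miss for '{cat}'")
        if not reg <= sem:
            raise PhraseBankError(f"phrase {text!r}: regex adds labels beyond its semantics")
    elif kind == "regex_positive":
        if cat not in reg or cat in sem:
            raise PhraseBankError(f"phrase {text!r} is not a spurious regex hit for '{cat}'")
        if not sem <= reg:
            raise PhraseBankError(f"phrase {text!r}: semantics exceed its regex labels")
    if Category.PARTNER_GENDER not in reg and _GENDER_TARGET.search(phrase.sentence):
        raise PhraseBankError(
            f"phrase {text!r} contains a gendered target word but is not "
            "partner-gender regex-positive; it would leak window hits"
        )


def verify_banks(bank: PhraseBank, ruleset: RuleSet) -> None:
    """Raise :class:`PhraseBankError` unless every phrase behaves as declared."""
    for kind, table in (
        ("positive", bank.positive),
        ("regex_negative", bank.regex_negative),
        ("regex_positive", bank.regex_positive),
    ):
        for cat, phrases in table.items():
            for phrase in phrases:
                _verify_phrase(phrase, kind, cat)
    for filler in bank.neutral_fillers:
        if _regex_labels(_as_sentence(filler), ruleset):
            raise PhraseBankError(f"neutral filler {filler!r} is not all-false under the rules")
    for sent in bank.gender_distractors:
        reg = _regex_labels(_as_sentence(sent), ruleset)
        if reg:
            raise PhraseBankError(f"gender distractor {sent!r} must classify all-false alone")
        if not _GENDER_TARGET.search(sent):
            raise PhraseBankError(f"gender distractor {sent!r} contains no gendered word")


def _bind(raw: dict[Category, list[tuple[str, set]]], ruleset: RuleSet) -> dict[Category, list[Phrase]]:
    out: dict[Category, list[Phrase]] = {}
    for cat, items in raw.items():
        out[cat] = [
            Phrase(
                text=text,
                semantic=frozenset(sem),
                regex=_regex_labels(_as_sentence(text), ruleset),
            )
            for text, sem in items
        ]
    return out


SH = Category.SEXUAL_HISTORY
PROT = Category.PROTECTION_USED
STI = Category.STI_TESTING
NSA = Category.NOT_SEXUALLY_ACTIVE
PG = Category.PARTNER_GENDER
PRAC = Category.SEXUAL_PRACTICE
CON = Category.CONTRACEPTION_USED


def default_phrase_banks(ruleset: Optional[RuleSet] = None) -> PhraseBank:
    """Build and verify the default phrase banks."""
    ruleset = ruleset or default_ruleset()
    positive = _bind(
        {
            SH: [
                ("Patient reports being sexually active", {SH}),
                ("Adolescent endorses prior sexual activity", {SH}),
                ("She has had sex with one partner in the past year", {SH}),
                ("Sexually active per triage note", {SH}),
            ],
            PROT: [
                ("Uses condoms some of the time", {PROT}),
                ("Reports consistent condom use", {PROT}),
                ("Uses protection with each encounter", {PROT}),
            ],
            STI: [
                ("Will send GC/CT today", {STI}),
                ("STD testing performed at last visit", {STI}),
                ("History of chlamydia treated last year", {STI}),
                ("Gonorrhea screening offered and accepted", {STI}),
            ],
            NSA: [
                ("Denies any sexual activity", {SH, NSA}),
                ("Not sexually active at this time", {SH, NSA}),
                ("Never been sexually active", {SH, NSA}),
                ("Denies intercourse", {SH, NSA}),
            ],
            PG: [
                ("Has sex with female partners", {SH, PG}),
                ("Hx of sexual activity with women", {SH, PG}),
                ("Sexually active with her boyfriend", {SH, PG}),
                ("Reports intercourse with male partners only", {SH, PG}),
            ],
            PRAC: [
                ("Has had oral sex", {SH, PRAC}),
                ("Reports vaginal intercourse", {SH, PRAC}),
                ("Endorses receptive anal intercourse", {SH, PRAC}),
            ],
            CON: [
                ("Is on OCP", {CON}),
                ("Started Depo injection 1 month ago", {CON}),
                ("On birth control for PCOS", {CON}),
                ("Nexplanon in place since last year", {CON}),
                ("Has an IUD", {CON}),
            ],
        },
        ruleset,
    )
    regex_negative = _bind(
        {
            SH: [("Reports being intimate with her partner", {SH})],
            PROT: [("Uses a barrier method consistently", {PROT})],
            STI: [("RPR and HIV screen sent", {STI})],
            NSA: [("Denies ever having been sexually active", {SH, NSA})],
            PG: [("BF uses protection", {SH, PROT, PG})],
            PRAC: [("Has had sex—both oral and anal", {SH, PRAC})],
            CON: [("On mini pill", {CON})],
        },
        ruleset,
    )
    regex_positive = _bind(
        {
            SH: [("Staff escorted patient to the unisex bathroom", set())],
            PROT: [("Eye protection worn during the procedure", set())],
            STI: [("Extremities warm with no clubbing/cyanosis", set())],
            NSA: [("No sexual development delay noted on exam", set())],
            PG: [("Sexually active; gender identity: male", {SH})],
            PRAC: [],
            CON: [("MRI shows hemosiderin deposition along the joint", set())],
        },
        ruleset,
    )
    neutral_fillers = [
        "Sex: Male",
        "Sex: Female",
        "Vitals reviewed and stable",
        "Afebrile overnight",
        "Tolerating oral intake well",
        "GCS 15 and oriented on arrival",
        "Condom catheter in place",
        "Abd soft, nontender",
        "Plan reviewed with the family",
        "IV fluids continued",
        "Denies fever or chills",
        "Electrolytes within normal limits",
        "Follow up in clinic next week",
        "Lungs clear to auscultation",
        "No acute distress noted",
        "Heart regular rate and rhythm",
        "Continue home medications",
        "Social work consulted for resources",
        "Encourage fluids and rest",
    ]
    gender_distractors = [
        "Guardian is the male parent at bedside",
        "Accompanied by a young man from the school",
    ]
    bank = PhraseBank(
        positive=positive,
        regex_negative=regex_negative,
        regex_positive=regex_positive,
        neutral_fillers=neutral_fillers,
        gender_distractors=gender_distractors,
    )
    verify_banks(bank, ruleset)
    return bank


_DEFAULT_PREVALENCE: dict[Category, float] = {
    SH: 0.40,
    PROT: 0.15,
    STI: 0.20,
    NSA: 0.20,
    PG: 0.12,
    PRAC: 0.04,
    CON: 0.12,
}


class SyntheticCorpusConfig(BaseModel):
    """Knobs of the generator.

    ``prevalence`` is the target marginal probability that a note is
    *semantically* positive for a category.  ``fp_rate`` is the per-note
    probability of planting one spurious regex hit; ``fn_rate`` is the
    per-positive-category probability of documenting it with a phrase
    the rules miss.  ``window_negative_rate`` controls the variant that
    places a gendered word just beyond the 50-character partner-gender
    window of a sex anchor, creating a hard (non-divergent) negative.
    """

    n_notes: int = 200
    setting_mix: float = 0.5  # proportion of ED notes; remainder inpatient
    prevalence: dict[Category, float] = Field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE)
    )
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    window_negative_rate: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticCorpusConfig":
        if self.n_notes < 0:
            raise ValueError("n_notes must be non-negative")
        probs = [self.setting_mix, self.fp_rate, self.fn_rate, self.window_negative_rate]
        probs += list(self.prevalence.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        missing = [c for c in CATEGORIES if c not in self.prevalence]
        if missing:
            raise ValueError(f"prevalence missing categories: {missing}")
        return self


@dataclass(frozen=True)
class PlantRecord:
    """One intentional classifier/gold divergence."""

    note_id: str
    category: Category
    kind: str  # "fp" or "fn"


@dataclass
class LabeledCorpus:
    notes: list[ClinicalNote]
    gold: list[GoldLabels]
    planted: list[PlantRecord]


def _own_sexual_history_prob(prevalence: dict[Category, float]) -> float:
    """Probability of standalone sexual-history documentation.

    Partner-gender, practice and denial phrases all mention sexual
    activity, so they imply overall documentation; the standalone
    probability is solved so the configured marginal is recovered.
    """
    q = 1.0
    for cat in _IMPLIES_SEXUAL_HISTORY:
        q *= 1.0 - prevalence[cat]
    implied = 1.0 - q
    if implied >= 1.0 or prevalence[SH] <= implied:
        return 0.0
    return (prevalence[SH] - implied) / (1.0 - implied)


def _last_anchor_end(text: str, ruleset: RuleSet) -> Optional[int]:
    from .matcher import find_pattern_spans

    window = ruleset.rules[PG].window_rule
    spans = find_pattern_spans(text, window.anchor_patterns)
    return spans[-1].end if spans else None


def generate_corpus(
    config: SyntheticCorpusConfig,
    banks: Optional[PhraseBank] = None,
    ruleset: Optional[RuleSet] = None,
) -> LabeledCorpus:
    """Generate a labeled corpus; deterministic for a given config+seed.

    Every note is verified on emission: the classifier's labels must
    equal the union of the inserted phrases' regex labels, so the
    divergence between classifier and gold is exactly the ``planted``
    ledger.
    """
    ruleset = ruleset or default_ruleset()
    banks = banks or default_phrase_banks(ruleset)
    rng = random.Random(config.seed)
    safe = banks.safe_fillers()
    headers = banks.header_fillers()
    window_chars = ruleset.rules[PG].window_rule.window_chars
    guard = window_chars + 12  # header targets sit within the first ~12 chars
    p_own = _own_sexual_history_prob(config.prevalence)

    notes: list[ClinicalNote] = []
    gold: list[GoldLabels] = []
    planted: list[PlantRecord] = []
    width = max(4, len(str(max(config.n_notes, 1))))

    for i in range(config.n_notes):
        note_id = f"note-{i:0{width}d}"
        setting = Setting.ED if rng.random() < config.setting_mix else Setting.INPATIENT

        chosen: list[Phrase] = []

        def pick(cat: Category) -> None:
            use_fn = (
                config.fn_rate > 0
                and banks.regex_negative.get(cat)
                and rng.random() < config.fn_rate
            )
            pool = banks.regex_negative[cat] if use_fn else banks.positive[cat]
            chosen.append(rng.choice(pool))

        if rng.random() < p_own:
            pick(SH)
        for cat in (PROT, STI, NSA, PG, PRAC, CON):
            if rng.random() < config.prevalence[cat]:
                pick(cat)

        sem = frozenset().union(*(p.semantic for p in chosen)) if chosen else frozenset()
        if config.fp_rate > 0 and rng.random() < config.fp_rate:
            eligible = [
                c for c in CATEGORIES if banks.regex_positive.get(c) and c not in sem
            ]
            if eligible:
                chosen.append(rng.choice(banks.regex_positive[rng.choice(eligible)]))

        sem = frozenset().union(*(p.semantic for p in chosen)) if chosen else frozenset()
        reg = frozenset().union(*(p.regex for p in chosen)) if chosen else frozenset()

        payload = [p.sentence for p in chosen]
        fillers = [_as_sentence(rng.choice(safe)) for _ in range(rng.randint(3, 6))]
        body = payload + fillers
        rng.shuffle(body)

        prefix: list[str] = []
        if headers and rng.random() < 0.6:
            prefix.append(_as_sentence(rng.choice(headers)))
            while len(" ".join(prefix)) < guard:
                prefix.append(_as_sentence(rng.choice(safe)))

        sentences = prefix + body

        if (
            config.window_negative_rate > 0
            and banks.gender_distractors
            and PG not in reg
            and rng.random() < config.window_negative_rate
        ):
            text_so_far = " ".join(sentences)
            anchor_end = _last_anchor_end(text_so_far, ruleset)
            if anchor_end is not None:
                while len(" ".join(sentences)) - anchor_end <= window_chars + 8:
                    sentences.append(_as_sentence(rng.choice(safe)))
                sentences.append(_as_sentence(rng.choice(banks.gender_distractors)))

        text = " ".join(sentences)
        note = ClinicalNote(note_id=note_id, setting=setting, text=text)

        cls = classify_note(note, ruleset)
        got = frozenset(c for c in CATEGORIES if cls.labels[c])
        if got != reg:
            raise RuntimeError(
                f"assembly guarantee violated for {note_id}: classifier labels "
                f"{sorted(map(str, got))} != phrase-level labels {sorted(map(str, reg))}"
            )

        notes.append(note)
        gold.append(GoldLabels(note_id=note_id, labels={c: c in sem for c in CATEGORIES}))
        for cat in CATEGORIES:
            if (cat in reg) != (cat in sem):
                planted.append(
                    PlantRecord(note_id=note_id, category=cat, kind="fp" if cat in reg else "fn")
                )

    return LabeledCorpus(notes=notes, gold=gold, planted=planted)


def corpus_to_files(
    corpus: LabeledCorpus,
    notes_path: PathLike,
    gold_path: PathLike,
    planted_path: Optional[PathLike] = None,
) -> None:
    """Write the corpus as the JSONL formats the matcher/evaluation read."""
    write_notes(corpus.notes, notes_path)
    write_gold(corpus.gold, gold_path)
    if planted_path is not None:
        import json
        from pathlib import Path

        with Path(planted_path).open("w", encoding="utf-8") as handle:
            for rec in corpus.planted:
                handle.write(
                    json.dumps(
                        {"note_id": rec.note_id, "category": str(rec.category), "kind": rec.kind},
                        sort_keys=True,
                    )
                    + "\n"
                )
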