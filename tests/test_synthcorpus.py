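import json

import pytest

from shxd.evaluation import confusion_counts, evaluate
from shxd.io import read_gold, read_notes
from shxd.matcher import classify_corpus, classify_note
from shxd.rulebook import CATEGORIES, Category
from shxd.synthcorpus import (
    Phrase,
    PhraseBankError,
    SyntheticCorpusConfig,
    corpus_to_files,
    generate_corpus,
    verify_banks,
)


def test_default_banks_verify_and_contain_documented_adversaries(banks):
    assert any(
        "anal" in p.text for p in banks.positive[Category.SEXUAL_PRACTICE]
    )
    sti_fp = [p.text for p in banks.regex_positive[Category.STI_TESTING]]
    assert any("clubbing/cyanosis" in t for t in sti_fp)
    nsa_fn = [p.text for p in banks.regex_negative[Category.NOT_SEXUALLY_ACTIVE]]
    assert "Denies ever having been sexually active" in nsa_fn
    pg_fn = [p.text for p in banks.regex_negative[Category.PARTNER_GENDER]]
    assert any("BF" in t for t in pg_fn)


def test_every_filler_classifies_all_false(banks, ruleset):
    from shxd.matcher import ClinicalNote

    for filler in banks.neutral_fillers:
        result = classify_note(ClinicalNote(note_id="f", text=filler + "."), ruleset)
        assert not any(result.labels.values()), filler


def test_bank_verification_rejects_mislabeled_phrase(banks, ruleset):
    broken_positive = dict(banks.positive)
    broken_positive[Category.SEXUAL_HISTORY] = banks.positive[Category.SEXUAL_HISTORY] + [
        Phrase(text="patient resting comfortably", semantic=frozenset({Category.SEXUAL_HISTORY}))
    ]
    import dataclasses

    broken = dataclasses.replace(banks, positive=broken_positive)
    with pytest.raises(PhraseBankError, match="resting comfortably"):
        verify_banks(broken, ruleset)


def test_generation_is_deterministic(banks, ruleset, tmp_path):
    config = SyntheticCorpusConfig(n_notes=50, seed=9, fp_rate=0.1, fn_rate=0.1)
    a = generate_corpus(config, banks, ruleset)
    b = generate_corpus(config, banks, ruleset)
    for corpus, stem in ((a, "a"), (b, "b")):
        corpus_to_files(
            corpus,
            tmp_path / f"{stem}.notes.jsonl",
            tmp_path / f"{stem}.gold.jsonl",
            tmp_path / f"{stem}.planted.jsonl",
        )
    for suffix in ("notes", "gold", "planted"):
        assert (
            (tmp_path / f"a.{suffix}.jsonl").read_bytes()
            == (tmp_path / f"b.{suffix}.jsonl").read_bytes()
        )


def test_empty_corpus():
    corpus = generate_corpus(SyntheticCorpusConfig(n_notes=0))
    assert corpus.notes == [] and corpus.gold == [] and corpus.planted == []


def test_clean_corpus_scores_perfectly(banks, ruleset):
    corpus = generate_corpus(SyntheticCorpusConfig(n_notes=200, seed=4), banks, ruleset)
    assert corpus.planted == []
    preds = classify_corpus(corpus.notes, ruleset)
    _, metrics = evaluate(preds, corpus.gold)
    for m in metrics:
        assert m.sensitivity == 100.0, m.category
        assert m.specificity == 100.0, m.category


def test_planted_ledger_matches_confusion_counts(banks, ruleset):
    corpus = generate_corpus(
        SyntheticCorpusConfig(
            n_notes=250, seed=21, fp_rate=0.2, fn_rate=0.25, window_negative_rate=0.3
        ),
        banks,
        ruleset,
    )
    assert corpus.planted  # rates are high enough to plant something
    preds = classify_corpus(corpus.notes, ruleset)
    for cat in CATEGORIES:
        counts = confusion_counts(preds, corpus.gold, cat)
        fp_planted = sum(1 for p in corpus.planted if p.category is cat and p.kind == "fp")
        fn_planted = sum(1 for p in corpus.planted if p.category is cat and p.kind == "fn")
        assert counts.fp == fp_planted, cat
        assert counts.fn == fn_planted, cat


def test_divergences_only_on_planted_notes(banks, ruleset):
    corpus = generate_corpus(
        SyntheticCorpusConfig(n_notes=150, seed=6, fp_rate=0.15, fn_rate=0.15),
        banks,
        ruleset,
    )
    planted = {(p.note_id, p.category) for p in corpus.planted}
    gold_by_id = {g.note_id: g for g in corpus.gold}
    for pred in classify_corpus(corpus.notes, ruleset):
        gold = gold_by_id[pred.note_id]
        diverging = {
            (pred.note_id, c) for c in CATEGORIES if pred.labels[c] != gold.labels[c]
        }
        assert diverging == {p for p in planted if p[0] == pred.note_id}


def test_prevalence_recovery_at_scale(banks, ruleset):
    """Empirical semantic prevalence tracks the configuration within 3 points."""
    config = SyntheticCorpusConfig(n_notes=2000, seed=3)
    corpus = generate_corpus(config, banks, ruleset)
    for cat in CATEGORIES:
        observed = sum(1 for g in corpus.gold if g.labels[cat]) / config.n_notes
        assert abs(observed - config.prevalence[cat]) < 0.03, cat


def test_window_negative_variant_creates_hard_negatives(banks, ruleset):
    with_variant = generate_corpus(
        SyntheticCorpusConfig(n_notes=200, seed=5, window_negative_rate=1.0), banks, ruleset
    )
    # the variant plants gendered words beyond the window; they must not
    # flip partner-gender and must not create divergences
    assert with_variant.planted == []
    import re

    gendered = re.compile("male|boy|girl|men|man", re.IGNORECASE)
    gold_by_id = {g.note_id: g for g in with_variant.gold}
    hard = [
        n
        for n in with_variant.notes
        if gendered.search(n.text) and not gold_by_id[n.note_id].labels[Category.PARTNER_GENDER]
    ]
    assert hard  # the distractors actually appear
    for note in hard:
        assert not classify_note(note, ruleset).labels[Category.PARTNER_GENDER]


def test_files_round_trip_and_do_not_leak_labels(banks, ruleset, tmp_path):
    corpus = generate_corpus(SyntheticCorpusConfig(n_notes=30, seed=1), banks, ruleset)
    notes_path = tmp_path / "notes.jsonl"
    gold_path = tmp_path / "gold.jsonl"
    corpus_to_files(corpus, notes_path, gold_path)
    notes = read_notes(notes_path)
    golds = read_gold(gold_path)
    assert [n.note_id for n in notes] == [n.note_id for n in corpus.notes]
    assert [n.text for n in notes] == [n.text for n in corpus.notes]
    assert [g.labels for g in golds] == [g.labels for g in corpus.gold]
    assert len(gold_path.read_text().splitlines()) == 30
    for line in notes_path.read_text().splitlines():
        record = json.loads(line)
        assert set(record) == {"note_id", "setting", "text"}


def test_config_rejects_bad_probabilities():
    with pytest.raises(ValueError):
        SyntheticCorpusConfig(fp_rate=1.5)
    with pytest.raises(ValueError):
        SyntheticCorpusConfig(n_notes=-1)
    with pytest.raises(ValueError):
        SyntheticCorpusConfig(prevalence={Category.SEXUAL_HISTORY: 0.4})
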