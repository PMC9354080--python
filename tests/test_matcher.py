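import pytest
from hypothesis import given, settings, strategies as st

from shxd.matcher import (
    ClinicalNote,
    MatchSpan,
    apply_exclusions,
    classify_corpus,
    classify_note,
    find_pattern_spans,
    find_window_spans,
)
from shxd.rulebook import CATEGORIES, Category
from shxd.synthcorpus import SyntheticCorpusConfig, generate_corpus

from conftest import TABLE_EXAMPLES
from naive_scanner import naive_classify


@pytest.mark.parametrize("category,text,expected", TABLE_EXAMPLES)
def test_documented_example_strings(category, text, expected, ruleset):
    """Each worked example labels exactly as documented for its category."""
    result = classify_note(ClinicalNote(note_id="ex", text=text), ruleset)
    assert result.labels[Category(category)] is expected


def test_find_pattern_spans_basics(ruleset):
    sh = ruleset.rules[Category.SEXUAL_HISTORY].match_patterns
    spans = find_pattern_spans("sexual activity", sh)
    assert spans and spans[0].start == 0
    assert "sexual activity"[spans[0].start : spans[0].end] == "sexu"
    assert find_pattern_spans("Sex: Male", sh) == []
    assert find_pattern_spans("", sh) == []
    sti = ruleset.rules[Category.STI_TESTING].match_patterns
    hits = find_pattern_spans("no clubbing/cyanosis", sti)
    assert ["no clubbing/cyanosis"[s.start : s.end].lower() for s in hits] == ["g/c"]


def test_spans_sorted_and_non_overlapping_per_pattern(ruleset):
    sti = ruleset.rules[Category.STI_TESTING].match_patterns
    spans = find_pattern_spans("chlamydia and chlamydia and gonorrhea", sti)
    assert spans == sorted(spans, key=lambda s: (s.start, s.end, s.pattern_index))
    per_pattern = {}
    for s in spans:
        per_pattern.setdefault(s.pattern_index, []).append(s)
    for group in per_pattern.values():
        for a, b in zip(group, group[1:]):
            assert a.end <= b.start


def test_apply_exclusions_overlap_semantics():
    match = [MatchSpan(start=0, end=6)]
    assert apply_exclusions(match, [MatchSpan(start=0, end=11)]) == []
    assert apply_exclusions(match, []) == match
    assert apply_exclusions(match, [MatchSpan(start=20, end=31)]) == match
    # suppression needs a shared character: touching spans do not overlap
    assert apply_exclusions(match, [MatchSpan(start=6, end=10)]) == match
    chlam = [MatchSpan(start=0, end=5)]
    assert apply_exclusions(chlam, [MatchSpan(start=0, end=16)]) == []


def test_window_rule_in_and_out_of_range(ruleset):
    w = ruleset.rules[Category.PARTNER_GENDER].window_rule
    inside = "has sex with female partners"
    spans = find_window_spans(inside, w)
    assert spans and inside[spans[0].start : spans[0].end].lower() == "male"
    assert find_window_spans("interested in men", w) == []
    # target 60 characters beyond the anchor end: outside the window
    far = "had sex " + "x" * 60 + " men"
    assert find_window_spans(far, w) == []
    near = "had sex " + "x" * 30 + " men"
    assert find_window_spans(near, w) != []


def test_window_containment_brute_force(ruleset, banks):
    """Every window span lies within 50 chars of some anchor match."""
    w = ruleset.rules[Category.PARTNER_GENDER].window_rule
    corpus = generate_corpus(
        SyntheticCorpusConfig(n_notes=60, seed=11, window_negative_rate=0.5), banks, ruleset
    )
    checked = 0
    for note in corpus.notes:
        anchors = find_pattern_spans(note.text, w.anchor_patterns)
        for span in find_window_spans(note.text, w):
            assert any(
                a.start - w.window_chars <= span.start and span.end <= a.end + w.window_chars
                for a in anchors
            )
            checked += 1
    assert checked > 0


def test_classify_note_empty_text(ruleset):
    result = classify_note(ClinicalNote(note_id="empty", text=""), ruleset)
    assert all(result.labels[c] is False for c in CATEGORIES)
    assert all(result.evidence[c] == [] for c in CATEGORIES)


def test_labels_iff_evidence(ruleset, banks):
    corpus = generate_corpus(
        SyntheticCorpusConfig(n_notes=40, seed=2, fp_rate=0.2), banks, ruleset
    )
    for res in classify_corpus(corpus.notes, ruleset):
        for cat in CATEGORIES:
            assert res.labels[cat] == bool(res.evidence[cat])


def test_evidence_spans_rematch_their_pattern(ruleset, banks):
    corpus = generate_corpus(SyntheticCorpusConfig(n_notes=40, seed=8), banks, ruleset)
    for note in corpus.notes:
        res = classify_note(note, ruleset)
        for cat in CATEGORIES:
            rule = ruleset.rules[cat]
            patterns = (
                rule.window_rule.target_patterns if rule.window_rule else rule.match_patterns
            )
            for span in res.evidence[cat]:
                rx = patterns[span.pattern_index].compile()
                assert rx.fullmatch(note.text[span.start : span.end])


def test_case_invariance(ruleset):
    for _, text, _ in TABLE_EXAMPLES:
        lower = classify_note(ClinicalNote(note_id="a", text=text), ruleset).labels
        upper = classify_note(ClinicalNote(note_id="a", text=text.upper()), ruleset).labels
        assert lower == upper


def test_classify_corpus_matches_per_note_loop(ruleset, banks):
    corpus = generate_corpus(
        SyntheticCorpusConfig(n_notes=200, seed=13, fp_rate=0.1, fn_rate=0.1), banks, ruleset
    )
    batch = classify_corpus(corpus.notes, ruleset)
    single = [classify_note(n, ruleset) for n in corpus.notes]
    assert [r.labels for r in batch] == [r.labels for r in single]
    assert [r.note_id for r in batch] == [n.note_id for n in corpus.notes]


def test_classify_corpus_rejects_duplicate_ids(ruleset):
    notes = [ClinicalNote(note_id="n1"), ClinicalNote(note_id="n1")]
    with pytest.raises(ValueError, match="duplicate note_id"):
        classify_corpus(notes, ruleset)
    assert classify_corpus([], ruleset) == []


def test_matcher_agrees_with_naive_scanner(ruleset, banks):
    """Independent-oracle equivalence on a 200-note seeded corpus."""
    corpus = generate_corpus(
        SyntheticCorpusConfig(
            n_notes=200, seed=17, fp_rate=0.15, fn_rate=0.15, window_negative_rate=0.3
        ),
        banks,
        ruleset,
    )
    for note in corpus.notes:
        ours = classify_note(note, ruleset).labels
        theirs = naive_classify(note.text, ruleset)
        assert ours == theirs, note.note_id


_WORDS = [
    "sex", "sexual", "intercourse", "condom", "condom cath", "protect", "child",
    "chlam", "pneumo", "GCS", "g/c", "male", "men", "girl", "no", "denies",
    "oral", "anal", "birth control", "depo", "IUD", "patient", "exam", "stable",
    "Sex: Male", "never", "had", "testing", "STD", ".", "\n",
]
_texts = st.lists(st.sampled_from(_WORDS), min_size=0, max_size=25).map(" ".join)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(text=_texts)
def test_property_naive_oracle_and_case_invariance(text, ruleset):
    note = ClinicalNote(note_id="p", text=text)
    ours = classify_note(note, ruleset).labels
    assert ours == naive_classify(text, ruleset)
    upper = classify_note(ClinicalNote(note_id="p", text=text.upper()), ruleset).labels
    assert ours == upper
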