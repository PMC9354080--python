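"""Applying a rule set to note text.

The matcher works on raw note text: no lowercasing, no Unicode
normalisation, no sentence splitting.  Case-insensitivity is a compile
flag so that every reported span indexes the original note.  Offsets
are 0-based, half-open character positions.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .rulebook import CATEGORIES, Category, CategoryRule, PatternSpec, RuleSet, WindowRule

logger = logging.getLogger(__name__)


class Setting(str, enum.Enum):
    """Care setting a note was written in."""

    ED = "ED"
    INPATIENT = "inpatient"
    OTHER = "other"

    def __str__(self) -> str:
        return self.value


@dataclass
class ClinicalNote:
    """One free-text note: id, care setting, raw body."""

    note_id: str
    setting: Setting = Setting.OTHER
    text: str = ""

    def __post_init__(self) -> None:
        if not self.note_id:
            raise ValueError("note_id must be non-empty")
        self.setting = Setting(self.setting)


@dataclass(frozen=True, order=True)
class MatchSpan:
    """Evidence for one pattern hit: [start, end) in the note text."""

    start: int
    end: int
    pattern_index: int = 0
    category: Optional[Category] = field(default=None, compare=False)

    def overlaps(self, other: "MatchSpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class NoteClassification:
    """Per-note labels with their supporting evidence spans.

    Invariant: ``labels[c]`` is true iff ``evidence[c]`` is non-empty.
    """

    note_id: str
    labels: dict[Category, bool]
    evidence: dict[Category, list[MatchSpan]]


def find_pattern_spans(
    text: str,
    patterns: Sequence[PatternSpec],
    category: Optional[Category] = None,
) -> list[MatchSpan]:
    """Every non-overlapping left-to-right occurrence of each pattern.

    Matching is case-insensitive (folding applies inside character
    classes) and multi-line, with whitespace classes matching newlines.
    Spans are sorted by (start, end).
    """
    spans: list[MatchSpan] = []
    for idx, spec in enumerate(patterns):
        rx = spec.compile()
        for m in rx.finditer(text):
            if m.end() == m.start():  # ignore zero-width hits
                continue
            spans.append(MatchSpan(start=m.start(), end=m.end(), pattern_index=idx, category=category))
    spans.sort(key=lambda s: (s.start, s.end, s.pattern_index))
    return spans


def apply_exclusions(
    match_spans: Sequence[MatchSpan],
    exclusion_spans: Sequence[MatchSpan],
) -> list[MatchSpan]:
    """Drop match spans that share at least one character with any exclusion span."""
    if not exclusion_spans:
        return list(match_spans)
    return [m for m in match_spans if not any(m.overlaps(e) for e in exclusion_spans)]


def find_window_spans(
    text: str,
    rule: WindowRule,
    category: Optional[Category] = None,
) -> list[MatchSpan]:
    """Target-pattern spans that fall inside a window around some anchor match.

    For each anchor match A the substring from ``A.start - window_chars``
    to ``A.end + window_chars`` (clipped at the text boundaries) is
    searched for the target patterns; returned spans are in whole-text
    coordinates, deduplicated and sorted.
    """
    anchors = find_pattern_spans(text, rule.anchor_patterns)
    out: dict[tuple[int, int, int], MatchSpan] = {}
    for a in anchors:
        lo = max(0, a.start - rule.window_chars)
        hi = min(len(text), a.end + rule.window_chars)
        for t in find_pattern_spans(text[lo:hi], rule.target_patterns, category):
            span = MatchSpan(
                start=t.start + lo, end=t.end + lo, pattern_index=t.pattern_index, category=category
            )
            out.setdefault((span.start, span.end, span.pattern_index), span)
    return sorted(out.values(), key=lambda s: (s.start, s.end, s.pattern_index))


def _category_evidence(text: str, rule: CategoryRule) -> list[MatchSpan]:
    if rule.window_rule is not None:
        hits = find_window_spans(text, rule.window_rule, rule.category)
    else:
        hits = find_pattern_spans(text, rule.match_patterns, rule.category)
    if rule.exclusion_patterns:
        exclusions = find_pattern_spans(text, rule.exclusion_patterns, rule.category)
        hits = apply_exclusions(hits, exclusions)
    return hits


def classify_note(note: ClinicalNote, ruleset: RuleSet) -> NoteClassification:
    """Label one note for all seven categories, with evidence spans.

    Categories are computed independently: the overall sexual-history
    label is NOT forced true by subcategory hits.
    """
    labels: dict[Category, bool] = {}
    evidence: dict[Category, list[MatchSpan]] = {}
    for cat in CATEGORIES:
        ev = _category_evidence(note.text, ruleset.rules[cat])
        evidence[cat] = ev
        labels[cat] = bool(ev)
    return NoteClassification(note_id=note.note_id, labels=labels, evidence=evidence)


def classify_corpus(
    notes: Iterable[ClinicalNote],
    ruleset: RuleSet,
) -> list[NoteClassification]:
    """Order-preserving :func:`classify_note` over a corpus.

    Raises ``ValueError`` before any classification if note ids repeat.
    """
    notes = list(notes)
    seen: set[str] = set()
    dups: list[str] = []
    for n in notes:
        if n.note_id in seen:
            dups.append(n.note_id)
        seen.add(n.note_id)
    if dups:
        raise ValueError(f"duplicate note_id(s): {sorted(set(dups))}")
    results = [classify_note(n, ruleset) for n in notes]
    positives = {
        str(cat): sum(1 for r in results if r.labels[cat]) for cat in CATEGORIES
    }
    logger.info("classified %d notes; positives per category: %s", len(results), positives)
    return results
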