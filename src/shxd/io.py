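"""Reading and writing the corpus, gold-label and classification files.

Formats are deliberately plain: JSONL (one object per line) or CSV with
the same columns, UTF-8 throughout.  Notes carry ``note_id``,
``setting`` and ``text``; gold files carry ``note_id`` plus one boolean
column per category; classification files carry nested ``labels`` and,
optionally, ``evidence`` spans for audit.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence, Union

from .evaluation import GoldLabels
from .matcher import ClinicalNote, MatchSpan, NoteClassification, Setting
from .rulebook import CATEGORIES, Category

PathLike = Union[str, Path]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _parse_bool(value, where: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"{where}: cannot interpret {value!r} as a boolean")


def _jsonl_records(path: Path) -> list[dict]:
    records = []
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
    return records


def read_notes(path: PathLike) -> list[ClinicalNote]:
    """Read a corpus file (JSONL or CSV, chosen by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with path.open(encoding="utf-8", newline="") as handle:
            records = list(csv.DictReader(handle))
    else:
        records = _jsonl_records(path)
    notes = []
    for i, rec in enumerate(records):
        if "note_id" not in rec or "text" not in rec:
            raise ValueError(f"{path}: record {i} lacks note_id/text fields")
        notes.append(
            ClinicalNote(
                note_id=str(rec["note_id"]),
                setting=Setting(rec.get("setting") or "other"),
                text=rec["text"] if rec["text"] is not None else "",
            )
        )
    return notes


def write_notes(notes: Sequence[ClinicalNote], path: PathLike) -> Path:
    """Write a corpus as JSONL (no label fields — notes never leak gold)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for note in notes:
            handle.write(
                json.dumps(
                    {"note_id": note.note_id, "setting": str(note.setting), "text": note.text},
                    sort_keys=True,
                    ensure_ascii=False,
                )
                + "\n"
            )
    return path


def read_gold(path: PathLike) -> list[GoldLabels]:
    """Read gold labels from JSONL (flat or nested ``labels``) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with path.open(encoding="utf-8", newline="") as handle:
            records = list(csv.DictReader(handle))
    else:
        records = _jsonl_records(path)
    golds = []
    for i, rec in enumerate(records):
        if "note_id" not in rec:
            raise ValueError(f"{path}: record {i} lacks note_id")
        source = rec.get("labels", rec)
        labels = {}
        for cat in CATEGORIES:
            if str(cat) not in source:
                raise ValueError(f"{path}: record {rec['note_id']} lacks label '{cat}'")
            labels[cat] = _parse_bool(source[str(cat)], f"{path}:{rec['note_id']}:{cat}")
        golds.append(GoldLabels(note_id=str(rec["note_id"]), labels=labels))
    return golds


def write_gold(golds: Sequence[GoldLabels], path: PathLike) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for g in golds:
            rec = {"note_id": g.note_id}
            rec.update({str(cat): bool(g.labels[cat]) for cat in CATEGORIES})
            handle.write(json.dumps(rec, sort_keys=True) + "\n")
    return path


def write_classifications(
    results: Sequence[NoteClassification],
    path: PathLike,
    notes: Sequence[ClinicalNote] = (),
    evidence: bool = False,
) -> Path:
    """Write classifier output as JSONL.

    With ``evidence=True`` each record carries the match spans
    (category, start, end, matched_text) that justify its labels;
    ``notes`` must then be supplied so span text can be echoed.
    """
    path = Path(path)
    text_by_id = {n.note_id: n.text for n in notes}
    with path.open("w", encoding="utf-8") as handle:
        for res in results:
            rec: dict = {
                "note_id": res.note_id,
                "labels": {str(cat): bool(res.labels[cat]) for cat in CATEGORIES},
            }
            if evidence:
                text = text_by_id.get(res.note_id, "")
                rec["evidence"] = {
                    str(cat): [
                        {
                            "start": s.start,
                            "end": s.end,
                            "matched_text": text[s.start : s.end],
                        }
                        for s in res.evidence[cat]
                    ]
                    for cat in CATEGORIES
                    if res.evidence[cat]
                }
            handle.write(json.dumps(rec, sort_keys=True, ensure_ascii=False) + "\n")
    return path


def read_classifications(path: PathLike) -> list[NoteClassification]:
    path = Path(path)
    results = []
    for i, rec in enumerate(_jsonl_records(path)):
        if "note_id" not in rec or "labels" not in rec:
            raise ValueError(f"{path}: record {i} lacks note_id/labels")
        labels = {}
        for cat in CATEGORIES:
            if str(cat) not in rec["labels"]:
                raise ValueError(f"{path}: record {rec['note_id']} lacks label '{cat}'")
            labels[cat] = _parse_bool(rec["labels"][str(cat)], f"{path}:{rec['note_id']}:{cat}")
        evidence = {cat: [] for cat in CATEGORIES}
        for cat_name, spans in (rec.get("evidence") or {}).items():
            cat = Category(cat_name)
            evidence[cat] = [
                MatchSpan(start=s["start"], end=s["end"], category=cat) for s in spans
            ]
        results.append(
            NoteClassification(note_id=str(rec["note_id"]), labels=labels, evidence=evidence)
        )
    return results
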