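"""Screening-metric evaluation against gold-standard labels.

Predictions are compared to chart-review-style gold labels per category
with the usual 2x2 tabulation, from which sensitivity, specificity,
positive and negative predictive value and the F1 score are derived as
percentages.  All metrics are computed exactly with rationals and
rounded once, to one decimal, half away from zero; the F1 score is the
harmonic mean of the *unrounded* sensitivity and PPV.  A metric whose
denominator is zero is undefined and reported as ``None`` (rendered
"NA"), never silently dropped.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

from .matcher import NoteClassification
from .rulebook import CATEGORIES, Category

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "f1")


@dataclass
class GoldLabels:
    """Gold-standard labels for one note (all seven categories)."""

    note_id: str
    labels: dict[Category, bool]

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.labels]
        if missing:
            raise ValueError(f"gold labels for {self.note_id} missing categories: {missing}")


@dataclass
class ConfusionCounts:
    category: Category
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Percentages in [0, 100], or ``None`` where undefined."""

    category: Category
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    f1: Optional[float]


def _round1(x: Fraction) -> float:
    """Round a non-negative rational to one decimal, half away from zero."""
    scaled = x * 10
    q, r = divmod(scaled.numerator, scaled.denominator)
    if 2 * r >= scaled.denominator:
        q += 1
    return q / 10


def _ratio(num: int, den: int) -> Optional[Fraction]:
    if den == 0:
        return None
    return Fraction(100 * num, den)


def confusion_counts(
    preds: Sequence[NoteClassification],
    golds: Sequence[GoldLabels],
    category: Category,
) -> ConfusionCounts:
    """2x2 tabulation of predicted vs gold labels for one category."""
    pred_map = {p.note_id: p for p in preds}
    gold_map = {g.note_id: g for g in golds}
    if len(pred_map) != len(preds):
        raise ValueError("duplicate note_id in predictions")
    if len(gold_map) != len(golds):
        raise ValueError("duplicate note_id in gold labels")
    if set(pred_map) != set(gold_map):
        only_pred = sorted(set(pred_map) - set(gold_map))
        only_gold = sorted(set(gold_map) - set(pred_map))
        raise ValueError(
            f"prediction/gold note_id mismatch: only in predictions {only_pred[:10]}, "
            f"only in gold {only_gold[:10]}"
        )
    counts = ConfusionCounts(category=category)
    for note_id, pred in pred_map.items():
        p = bool(pred.labels[category])
        g = bool(gold_map[note_id].labels[category])
        if p and g:
            counts.tp += 1
        elif p and not g:
            counts.fp += 1
        elif not p and g:
            counts.fn += 1
        else:
            counts.tn += 1
    return counts


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, PPV, NPV and F1 (percent, one decimal)."""
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    npv = _ratio(counts.tn, counts.tn + counts.fn)
    f1: Optional[Fraction] = None
    if sens is not None and ppv is not None and sens + ppv > 0:
        f1 = 2 * sens * ppv / (sens + ppv)
    return MetricsReport(
        category=counts.category,
        sensitivity=None if sens is None else _round1(sens),
        specificity=None if spec is None else _round1(spec),
        ppv=None if ppv is None else _round1(ppv),
        npv=None if npv is None else _round1(npv),
        f1=None if f1 is None else _round1(f1),
    )


def evaluate(
    preds: Sequence[NoteClassification],
    golds: Sequence[GoldLabels],
) -> tuple[list[ConfusionCounts], list[MetricsReport]]:
    """Counts and metrics for every category, in canonical order."""
    counts = [confusion_counts(preds, golds, cat) for cat in CATEGORIES]
    return counts, [compute_metrics(c) for c in counts]


LabelCarrier = Union[GoldLabels, NoteClassification]


def documentation_rates(
    labels: Sequence[LabelCarrier],
) -> dict[Category, tuple[int, int, float]]:
    """Per category: (positive count, total, percentage to one decimal).

    Accepts either gold labels or classifier output; this is the
    cohort-frequency view (how often each element is documented).
    """
    if not labels:
        raise ValueError("documentation_rates requires a non-empty label set")
    total = len(labels)
    out: dict[Category, tuple[int, int, float]] = {}
    for cat in CATEGORIES:
        pos = sum(1 for item in labels if item.labels[cat])
        out[cat] = (pos, total, _round1(Fraction(100 * pos, total)))
    return out


def _fmt_metric(value: Optional[float]) -> str:
    return "NA" if value is None else f"{value:.1f}"


def _fraction_cell(num: int, den: int, value: Optional[float]) -> str:
    if value is None:
        return f"{num}/{den} (NA)"
    return f"{num}/{den} ({value:.1f}%)"


_COLUMNS = ("category", "tp", "fp", "tn", "fn") + METRIC_NAMES


def render_report(
    metrics: Sequence[MetricsReport],
    counts: Sequence[ConfusionCounts],
    format: str = "markdown",
) -> str:
    """Render one row per category as CSV or a markdown table.

    The markdown flavour mirrors the screening-study convention of
    fraction cells, e.g. sensitivity "97/97 (100.0%)" meaning TP over
    TP+FN; the CSV flavour is plain numeric columns (counts plus
    metrics, "NA" where undefined) and round-trips losslessly.
    """
    by_cat = {c.category: c for c in counts}
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(_COLUMNS)
        for m in metrics:
            c = by_cat.get(m.category, ConfusionCounts(category=m.category))
            writer.writerow(
                [str(m.category), c.tp, c.fp, c.tn, c.fn]
                + [_fmt_metric(getattr(m, name)) for name in METRIC_NAMES]
            )
        return buf.getvalue()
    if format == "markdown":
        header = "| Category | Sensitivity | Specificity | PPV | NPV | F1 score |"
        sep = "|---|---|---|---|---|---|"
        lines = [header, sep]
        for m in metrics:
            c = by_cat.get(m.category, ConfusionCounts(category=m.category))
            lines.append(
                "| {} | {} | {} | {} | {} | {} |".format(
                    str(m.category),
                    _fraction_cell(c.tp, c.tp + c.fn, m.sensitivity),
                    _fraction_cell(c.tn, c.tn + c.fp, m.specificity),
                    _fraction_cell(c.tp, c.tp + c.fp, m.ppv),
                    _fraction_cell(c.tn, c.tn + c.fn, m.npv),
                    _fmt_metric(m.f1),
                )
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format: {format!r}")


def parse_report_csv(text: str) -> list[dict]:
    """Parse :func:`render_report`'s CSV back into dict rows."""
    rows = []
    for row in csv.DictReader(io.StringIO(text)):
        parsed: dict = {"category": Category(row["category"])}
        for key in ("tp", "fp", "tn", "fn"):
            parsed[key] = int(row[key])
        for key in METRIC_NAMES:
            parsed[key] = None if row[key] == "NA" else float(row[key])
        rows.append(parsed)
    return rows
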