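"""Rule data model and the default seven-category rule set.

The detector is organised around seven note-level categories: overall
sexual history documentation (SHxD) plus the CDC "5P's" components
(partners, practices, past history of STIs, protection from STIs, and
prevention of pregnancy), with denial of sexual activity tracked
separately.  Each category is driven either by a list of match patterns
(optionally suppressed by exclusion patterns) or, for partner gender, by
a windowed-context rule: a gendered target term must occur within a
fixed number of characters of a sexual-activity anchor term.

All patterns use the Python ``re`` dialect and are applied
case-insensitively in multi-line mode.
"""

from __future__ import annotations

import enum
import re
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field

# Dialect flags used everywhere a rule pattern is compiled.
PATTERN_FLAGS = re.IGNORECASE | re.MULTILINE


class Category(str, enum.Enum):
    """The seven note-level categories the detector reports."""

    SEXUAL_HISTORY = "sexual_history"
    PROTECTION_USED = "protection_used"
    STI_TESTING = "sti_testing"
    NOT_SEXUALLY_ACTIVE = "not_sexually_active"
    PARTNER_GENDER = "partner_gender"
    SEXUAL_PRACTICE = "sexual_practice"
    CONTRACEPTION_USED = "contraception_used"

    def __str__(self) -> str:  # stable names in all I/O
        return self.value


CATEGORIES: tuple[Category, ...] = tuple(Category)


class PatternSpec(BaseModel):
    """A single regular expression plus a short rationale."""

    pattern: str
    note: str = ""

    def compile(self) -> re.Pattern:
        return re.compile(self.pattern, PATTERN_FLAGS)


class WindowRule(BaseModel):
    """Positivity requires a target term near an anchor term.

    For every anchor match the substring from ``window_chars`` characters
    before the anchor start to ``window_chars`` characters after the
    anchor end (clipped at the text boundaries) is searched for the
    target patterns.
    """

    anchor_patterns: list[PatternSpec]
    window_chars: int = 50
    target_patterns: list[PatternSpec]


class CategoryRule(BaseModel):
    """Rule for one category.

    Exactly one of ``match_patterns`` (non-empty) or ``window_rule``
    drives positivity; ``exclusion_patterns`` only ever suppress
    overlapping matches, never add them.
    """

    category: Category
    match_patterns: list[PatternSpec] = Field(default_factory=list)
    exclusion_patterns: list[PatternSpec] = Field(default_factory=list)
    window_rule: Optional[WindowRule] = None


class RuleSet(BaseModel):
    name: str
    version: str
    rules: dict[Category, CategoryRule]


class RuleConfigError(ValueError):
    """Raised when a rule configuration file is malformed or invalid."""


def _p(pattern: str, note: str = "") -> PatternSpec:
    return PatternSpec(pattern=pattern, note=note)


# Anchor terms shared by the overall sexual-history rule and the
# partner-gender window rule.  The first pattern requires "sex" to be
# followed by a letter, comma, period, whitespace or slash, so that
# "sexual activity", "had sex today" and "no sex/drug use" match while
# the demographic header "Sex: Male" does not.  The bare-string pattern
# "sex\Z" additionally accepts end-of-text as a follower so that a note
# ending in "had sex" still counts.
_SEX_ANCHORS = [
    _p(r"sex[a-z,\.,\s,\/]|intercourse", "sex followed by letter/space/period/slash, or intercourse"),
    _p(r"sex\Z", "bare 'sex' at end of text"),
]


def default_ruleset() -> RuleSet:
    """Return the default seven-category rule set.

    Deterministic: identical (structurally equal) across calls.
    """
    rules: dict[Category, CategoryRule] = {
        Category.SEXUAL_HISTORY: CategoryRule(
            category=Category.SEXUAL_HISTORY,
            match_patterns=list(_SEX_ANCHORS),
        ),
        Category.PROTECTION_USED: CategoryRule(
            category=Category.PROTECTION_USED,
            match_patterns=[_p("protect"), _p("condom")],
            exclusion_patterns=[
                _p("condom cath", "condom catheter is a urinary device"),
                _p("child protect", "child protective services"),
            ],
        ),
        Category.STI_TESTING: CategoryRule(
            category=Category.STI_TESTING,
            match_patterns=[
                _p(r"GC[^S]", "gonorrhea/chlamydia shorthand; [^S] avoids the Glasgow Coma Scale 'GCS'"),
                _p(r"G\/C"),
                _p("gonorr"),
                _p("gonnor", "common misspelling"),
                _p("gonor"),
                _p("gonoc", "gonococcal"),
                _p("chlam"),
                _p(r"ST[ID]\s(test|screen|lab)"),
                _p(r"test(ing|ed)?\s+for\sST[ID]"),
            ],
            exclusion_patterns=[
                _p("chlam pneumo", "Chlamydophila pneumoniae is respiratory, not an STI"),
                _p("chlamydia pneumo"),
            ],
        ),
        Category.NOT_SEXUALLY_ACTIVE: CategoryRule(
            category=Category.NOT_SEXUALLY_ACTIVE,
            match_patterns=[
                _p(
                    r"denies (any sex|history of sex|hx of sex|intercourse"
                    r"|hx of intercourse|being sexual|ever being sexual)"
                    r"|no sex|never (had sex|been sexual)|not sexually active"
                ),
            ],
        ),
        Category.PARTNER_GENDER: CategoryRule(
            category=Category.PARTNER_GENDER,
            window_rule=WindowRule(
                anchor_patterns=list(_SEX_ANCHORS),
                window_chars=50,
                target_patterns=[
                    _p("male", "substring also covers 'female'"),
                    _p("boy"),
                    _p("girl"),
                    _p("men", "substring also covers 'women'"),
                    _p("man"),
                ],
            ),
        ),
        Category.SEXUAL_PRACTICE: CategoryRule(
            category=Category.SEXUAL_PRACTICE,
            match_patterns=[_p(r"(oral|vaginal|anal)\s(sex|penetration|intercourse)")],
        ),
        Category.CONTRACEPTION_USED: CategoryRule(
            category=Category.CONTRACEPTION_USED,
            match_patterns=[
                _p("OCP", "oral contraceptive pill"),
                _p("contraceptive"),
                _p("contraception"),
                _p("birth control"),
                _p("planon", "substring covers Nexplanon/Implanon"),
                _p("IUD"),
                _p("nuvaring"),
                _p("depo", "depot medroxyprogesterone"),
            ],
        ),
    }
    return RuleSet(name="shxd-default", version="1.0", rules=rules)


def validate_ruleset(ruleset: RuleSet) -> list[str]:
    """Return a list of invariant violations (empty iff the set is valid)."""
    violations: list[str] = []
    seen: set[Category] = set()
    for key, rule in ruleset.rules.items():
        if rule.category != key:
            violations.append(
                f"rule stored under key '{key}' declares category '{rule.category}'"
                " (duplicate or misfiled category)"
            )
        if rule.category in seen:
            violations.append(f"duplicate category '{rule.category}'")
        seen.add(rule.category)

        has_match = bool(rule.match_patterns)
        has_window = rule.window_rule is not None
        if has_match == has_window:
            violations.append(
                f"{key}: exactly one of match_patterns or window_rule must drive positivity"
            )
        all_specs: list[tuple[str, PatternSpec]] = []
        all_specs += [(f"{key}.match[{i}]", s) for i, s in enumerate(rule.match_patterns)]
        all_specs += [(f"{key}.exclude[{i}]", s) for i, s in enumerate(rule.exclusion_patterns)]
        if rule.window_rule is not None:
            w = rule.window_rule
            if w.window_chars < 0:
                violations.append(f"{key}: window_chars must be non-negative")
            if not w.anchor_patterns:
                violations.append(f"{key}: window rule has no anchor patterns")
            if not w.target_patterns:
                violations.append(f"{key}: window rule has no target patterns")
            all_specs += [(f"{key}.window.anchor[{i}]", s) for i, s in enumerate(w.anchor_patterns)]
            all_specs += [(f"{key}.window.target[{i}]", s) for i, s in enumerate(w.target_patterns)]
        for label, spec in all_specs:
            if not spec.pattern:
                violations.append(f"{label}: empty pattern")
                continue
            try:
                spec.compile()
            except re.error as exc:
                violations.append(f"{label}: pattern {spec.pattern!r} does not compile ({exc})")
    for cat in CATEGORIES:
        if cat not in seen:
            violations.append(f"missing category '{cat}'")
    return violations


def _window_to_config(w: WindowRule) -> dict:
    return {
        "anchors": [{"pattern": s.pattern, "note": s.note} for s in w.anchor_patterns],
        "chars": w.window_chars,
        "targets": [{"pattern": s.pattern, "note": s.note} for s in w.target_patterns],
    }


def ruleset_to_config(ruleset: RuleSet) -> dict:
    """Plain-dict form of a rule set (the on-disk config schema)."""
    rules: dict[str, dict] = {}
    for key, rule in ruleset.rules.items():
        entry: dict = {
            "match": [{"pattern": s.pattern, "note": s.note} for s in rule.match_patterns],
            "exclude": [{"pattern": s.pattern, "note": s.note} for s in rule.exclusion_patterns],
        }
        if rule.window_rule is not None:
            entry["window"] = _window_to_config(rule.window_rule)
        rules[str(key)] = entry
    return {"name": ruleset.name, "version": ruleset.version, "rules": rules}


def _specs_from_config(raw, where: str) -> list[PatternSpec]:
    specs = []
    for i, item in enumerate(raw or []):
        if isinstance(item, str):
            specs.append(PatternSpec(pattern=item))
        elif isinstance(item, dict) and "pattern" in item:
            specs.append(PatternSpec(pattern=item["pattern"], note=item.get("note") or ""))
        else:
            raise RuleConfigError(f"{where}[{i}]: expected a pattern string or mapping with 'pattern'")
    return specs


def ruleset_from_config(config: dict) -> RuleSet:
    if not isinstance(config, dict):
        raise RuleConfigError("rule config must be a mapping")
    for required in ("name", "version", "rules"):
        if required not in config:
            raise RuleConfigError(f"rule config missing key '{required}'")
    rules: dict[Category, CategoryRule] = {}
    for key, entry in config["rules"].items():
        try:
            cat = Category(key)
        except ValueError:
            raise RuleConfigError(f"rules.{key}: unknown category") from None
        entry = entry or {}
        window = None
        if "window" in entry and entry["window"] is not None:
            w = entry["window"]
            window = WindowRule(
                anchor_patterns=_specs_from_config(w.get("anchors"), f"rules.{key}.window.anchors"),
                window_chars=int(w.get("chars", 50)),
                target_patterns=_specs_from_config(w.get("targets"), f"rules.{key}.window.targets"),
            )
        rules[cat] = CategoryRule(
            category=cat,
            match_patterns=_specs_from_config(entry.get("match"), f"rules.{key}.match"),
            exclusion_patterns=_specs_from_config(entry.get("exclude"), f"rules.{key}.exclude"),
            window_rule=window,
        )
    ruleset = RuleSet(name=str(config["name"]), version=str(config["version"]), rules=rules)
    violations = validate_ruleset(ruleset)
    if violations:
        raise RuleConfigError("invalid rule set: " + "; ".join(violations))
    return ruleset


def load_ruleset(path: Union[str, Path]) -> RuleSet:
    """Load and validate a YAML or JSON rule configuration file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise RuleConfigError(f"cannot parse rule config {path}: {exc}") from exc
    return ruleset_from_config(raw)


def save_ruleset(ruleset: RuleSet, path: Union[str, Path]) -> Path:
    """Write a rule set to YAML; round-trips with :func:`load_ruleset`."""
    path = Path(path)
    path.write_text(
        yaml.safe_dump(ruleset_to_config(ruleset), sort_keys=False, allow_unicode=True),
        encoding="utf-8",
    )
    return path
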