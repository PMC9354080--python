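"""An independent, deliberately naive re-implementation of the matcher.

Used only as an oracle in tests.  It shares the rule *definitions* but
none of the matcher's code paths: matching walks the text with repeated
``search`` calls, exclusion overlap is checked with explicit position
sets, and the window rule is evaluated by scanning every target
occurrence against every anchor interval.
"""

import re

FLAGS = re.IGNORECASE | re.MULTILINE


def _all_intervals(text, pattern):
    """Every leftmost non-overlapping [start, end) for one pattern."""
    rx = re.compile(pattern, FLAGS)
    out = []
    pos = 0
    while pos <= len(text):
        m = rx.search(text, pos)
        if m is None:
            break
        if m.end() == m.start():
            pos = m.start() + 1
            continue
        out.append((m.start(), m.end()))
        pos = m.end()
    return out


def naive_label(text, rule):
    """Boolean label for one category rule, computed the slow way."""
    excluded = set()
    for spec in rule.exclusion_patterns:
        for start, end in _all_intervals(text, spec.pattern):
            excluded.update(range(start, end))

    if rule.window_rule is not None:
        w = rule.window_rule
        anchors = []
        for spec in w.anchor_patterns:
            anchors.extend(_all_intervals(text, spec.pattern))
        targets = []
        for spec in w.target_patterns:
            targets.extend(_all_intervals(text, spec.pattern))
        for t_start, t_end in targets:
            if set(range(t_start, t_end)) & excluded:
                continue
            for a_start, a_end in anchors:
                lo = max(0, a_start - w.window_chars)
                hi = min(len(text), a_end + w.window_chars)
                if lo <= t_start and t_end <= hi:
                    return True
        return False

    for spec in rule.match_patterns:
        for start, end in _all_intervals(text, spec.pattern):
            if not set(range(start, end)) & excluded:
                return True
    return False


def naive_classify(text, ruleset):
    """Mapping category -> bool, independent of the package matcher."""
    return {cat: naive_label(text, rule) for cat, rule in ruleset.rules.items()}
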