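"""Classify a handful of notes and show the evidence behind each label.

Builds three tiny notes in memory, runs the default rule set over them
and prints, per note, which of the seven categories fired and the exact
text spans responsible.  A span is the audit trail a chart reviewer
would check when deciding whether to trust an automated label.
"""

from shxd import CATEGORIES, ClinicalNote, classify_note, default_ruleset

notes = [
    ClinicalNote(
        note_id="ed-1",
        setting="ED",
        text=(
            "17 yo female with lower abdominal pain. Sexually active with her "
            "boyfriend, uses condoms some of the time. Will send GC/CT. "
            "On birth control for PCOS."
        ),
    ),
    ClinicalNote(
        note_id="ed-2",
        setting="ED",
        text="Sex: Male. GCS 15 and oriented on arrival. Condom catheter in place.",
    ),
    ClinicalNote(
        note_id="inpt-1",
        setting="inpatient",
        text="Denies any sexual activity. No clubbing/cyanosis on exam.",
    ),
]

ruleset = default_ruleset()
for note in notes:
    result = classify_note(note, ruleset)
    positives = [c for c in CATEGORIES if result.labels[c]]
    print(f"\n{note.note_id} ({note.setting}):")
    if not positives:
        print("  no categories detected")
    for cat in positives:
        spans = ", ".join(repr(note.text[s.start : s.end]) for s in result.evidence[cat])
        print(f"  {cat}: {spans}")

# ed-2 stays all-negative: the demographic header, the Glasgow Coma Scale
# and the urinary device are exactly the hard negatives the exclusions and
# the follower-character class exist for.  inpt-1 shows a known failure
# mode: "no clubbing/cyanosis" trips the g/c (gonorrhea/chlamydia) pattern,
# a documented false positive of this rule family.
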