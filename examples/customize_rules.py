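"""Export the default rule set, extend it, and classify with the variant.

Institutions differ in abbreviations and note templates, so the rule set
is an editable YAML config rather than hard-coded behaviour.  Here the
sexual-history lexicon gains a pattern for the "s.a." abbreviation and
the modified file is loaded back and applied.
"""

import tempfile
from pathlib import Path

import yaml

from shxd import Category, ClinicalNote, classify_note, default_ruleset, load_ruleset, save_ruleset

workdir = Path(tempfile.mkdtemp())
rules_path = workdir / "rules.yaml"
save_ruleset(default_ruleset(), rules_path)

config = yaml.safe_load(rules_path.read_text())
config["name"] = "shxd-local"
config["rules"]["sexual_history"]["match"].append(
    {"pattern": r"s\.a\.\s", "note": "local abbreviation for sexually active"}
)
rules_path.write_text(yaml.safe_dump(config, sort_keys=False))

local = load_ruleset(rules_path)
note = ClinicalNote(note_id="n1", text="Pt is s.a. with one partner.")
for name, rs in (("default", default_ruleset()), ("local", local)):
    label = classify_note(note, rs).labels[Category.SEXUAL_HISTORY]
    print(f"{name} rule set: sexual_history = {label}")

# default -> False (the abbreviation is invisible to the stock lexicon),
# local -> True.  Every loaded rule set is re-validated: seven categories,
# compiling patterns, and a window rule for partner gender.
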