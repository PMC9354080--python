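import pytest

from shxd.rulebook import default_ruleset
from shxd.synthcorpus import default_phrase_banks


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture(scope="session")
def banks(ruleset):
    return default_phrase_banks(ruleset)


# The documented worked examples for the default rule set: each entry is
# (category, text, expected label for that category).  These include the
# deliberate rule misses (a denial phrasing the lexicon does not cover,
# the em-dash "sex—both oral and anal") and the known g/c false positive.
TABLE_EXAMPLES = [
    ("sexual_history", "sexual activity", True),
    ("sexual_history", "does not have sex", True),
    ("sexual_history", "no sex/drug use", True),
    ("sexual_history", "had sex", True),
    ("sexual_history", "Sex: Male", False),
    ("protection_used", "uses protection", True),
    ("protection_used", "uses condoms some of the time", True),
    ("protection_used", "condom catheter", False),
    ("protection_used", "child protection services", False),
    ("sti_testing", "will send GC/CT", True),
    ("sti_testing", "STD testing", True),
    ("sti_testing", "test for STI", True),
    ("sti_testing", "chlamydia", True),
    ("sti_testing", "chlamydia pneumonia", False),
    ("sti_testing", "no clubbing/cyanosis", True),
    ("not_sexually_active", "denies ever being sexually active", True),
    ("not_sexually_active", "never been sexually active", True),
    ("not_sexually_active", "denies ever having been sexually active", False),
    ("partner_gender", "has sex with female partners", True),
    ("partner_gender", "hx of sexual activity with women", True),
    ("partner_gender", "interested in men", False),
    ("sexual_practice", "has had oral sex", True),
    ("sexual_practice", "anal penetration", True),
    ("sexual_practice", "has had sex—both oral and anal", False),
    ("contraception_used", "is on OCP", True),
    ("contraception_used", "Depo-provera 1 month ago", True),
    ("contraception_used", "on birth control for PCOS", True),
    ("contraception_used", "on mini pill", False),
]
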