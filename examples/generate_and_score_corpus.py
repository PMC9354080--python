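"""Generate a labeled synthetic corpus, classify it, and score end to end.

The generator writes notes whose gold labels are *semantic* truth (what
a chart reviewer would record).  With fp_rate/fn_rate at zero the rules
recover that truth perfectly; with adversarial phrases planted, every
classifier/gold divergence is listed in the corpus's planted ledger, so
the evaluation's FP/FN counts can be reconciled exactly.
"""

from collections import Counter

from shxd import (
    CATEGORIES,
    SyntheticCorpusConfig,
    classify_corpus,
    default_ruleset,
    evaluate,
    generate_corpus,
    render_report,
)

ruleset = default_ruleset()

clean = generate_corpus(SyntheticCorpusConfig(n_notes=200, seed=11))
counts, metrics = evaluate(classify_corpus(clean.notes, ruleset), clean.gold)
print("clean corpus (no planted errors):")
print(render_report(metrics, counts, format="markdown"))

planted = generate_corpus(SyntheticCorpusConfig(n_notes=200, seed=11, fp_rate=0.2, fn_rate=0.25))
counts, metrics = evaluate(classify_corpus(planted.notes, ruleset), planted.gold)
print("corpus with planted adversarial phrases:")
print(render_report(metrics, counts, format="markdown"))

ledger = Counter((str(p.category), p.kind) for p in planted.planted)
print("planted ledger vs evaluation:")
for c in counts:
    print(
        f"  {c.category}: FP {c.fp} (planted {ledger.get((str(c.category), 'fp'), 0)}), "
        f"FN {c.fn} (planted {ledger.get((str(c.category), 'fn'), 0)})"
    )

# On the clean corpus every defined sensitivity/specificity is 100.0%.
# On the planted corpus the FP/FN columns equal the ledger exactly —
# the generator knows precisely which notes it sabotaged.
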