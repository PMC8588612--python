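"""Evaluate a molecule set: coefficients, diversity, substructures, SA/QED.

The Solow–Polasky diversity I(A) = eᵀF⁻¹e / |A| rewards sets whose members
are mutually distant in fingerprint space; θ is reported with every value
because I(A) is not comparable across kernel widths.
"""

import json

from paretogen import evaluate, make_corpus, multi_target_objectives

molecules = make_corpus(200, seed=11)
report = evaluate(molecules, multi_target_objectives(), theta=1.0, seed=0)
print(json.dumps(report.to_dict(), indent=2))
# validity/uniqueness are 100% by construction here; desirability shows how
# many corpus molecules already satisfy all three objectives; diversity near
# 1 means the set is spread out, near 0 means heavy redundancy.
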