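"""Score molecules on multiple objectives and compare WS vs PF rewards.

Three toy objectives (maximize aromatic rings and heteroatoms, minimize
rotatable bonds) mimic the multi-target design: two on-targets and one
off-target.
"""

import numpy as np

from paretogen import (batch_reward, multi_target_objectives, pareto_reward,
                       score_batch, ws_weights)

molecules = [
    "CCO",                       # nothing aromatic: low on both on-targets
    "c1ccccc1",                  # one ring, no heteroatoms
    "c1ccncc1c1cncnc1",          # two rings but only three N: close, not desired
    "Nc1ncnc2[nH]cnc12",         # adenine: two rings, six heteroatoms, rigid
    "C(",                        # invalid: scored 0 everywhere
]
objectives = multi_target_objectives()
matrix = score_batch(molecules, objectives)
names = [o.name for o in objectives]
print("scores (rows = molecules, cols =", names, ")")
print(np.round(matrix.scores, 3))
print("valid:  ", matrix.valid.tolist())
print("desired:", matrix.desired.tolist())

w = ws_weights(matrix.scores, matrix.thresholds)
print("\nWS dynamic weights:", np.round(w, 3),
      "(harder objectives get more weight)")
print("WS rewards:", np.round(batch_reward(matrix, "ws"), 3))

ranking = pareto_reward(matrix)
print("PF fronts (0 = worst):", ranking.front_index.tolist())
print("PF global rank k:     ", ranking.rank.tolist())
print("PF rewards:           ", np.round(ranking.rewards, 3))
# Undesired molecules fill (0, 0.5], desired fill (0.5, 1]; the invalid
# string is pinned to the lowest rank.
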