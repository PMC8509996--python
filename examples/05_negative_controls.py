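"""The two negative-control experiments for the prediction models.

Swapped nets: every miRNA is retrained on another miRNA's causal-net genes
(seeded derangement) — accuracy should collapse. PPI superset: every miRNA
is retrained on the full pre-selection candidate network (all PPI partners)
— accuracy should not beat the pruned causal net. Both arms use the exact
training protocol of the causal models.
"""

import numpy as np
from scipy import stats

from mirnet.pipeline import control_experiment

causal, swapped, superset = [], [], []
for seed in (1, 2, 3):
    res = control_experiment(seed)
    causal += res["causal"]
    swapped += res["swapped"]
    superset += res["superset"]

t, p_two = stats.ttest_rel(causal, swapped)
p_one = p_two / 2 if t > 0 else 1 - p_two / 2
print(f"causal-net models : mean test accuracy {np.mean(causal):.2f}%")
print(f"swapped-net models: mean test accuracy {np.mean(swapped):.2f}%")
print(f"PPI-superset models: mean test accuracy {np.mean(superset):.2f}%")
print(f"\ncausal vs swapped gap: {np.mean(causal) - np.mean(swapped):.1f} "
      f"accuracy points (paired one-sided p = {p_one:.2e})")
print("A large gap shows the models exploit the miRNA-specific causal "
      "relationships, not generic expression structure; the superset result "
      "shows the pruned causal net carries the information of the full "
      "static PPI neighbourhood.")
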