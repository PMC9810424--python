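"""Map behavioural regions over the environment plane.

Sweeps the task-X reward b1 against the task-Y threshold w with the fast
analytic (adaptive-dynamics) classifier and prints the resulting region
labels: where the colony dies out, shares work uniformly, or branches
into active and lazy castes.
"""

import numpy as np

from colonygames import EnvironmentParams, LearningParams, region_sweep

env = EnvironmentParams(b1=20, b2=-6, w=0.3, beta=3)
params = LearningParams(N=100, T=30_000)

axes = {"b1": np.linspace(14, 30, 5), "w": np.linspace(0.1, 0.5, 5)}
rmap = region_sweep(axes, env, params, method="adaptive")

df = rmap.to_frame()
print(df.pivot(index="b1", columns="w", values="label").to_string())
# 'fully_inactive' cells are environments too poor to sustain any work;
# labels change along b1 (how rewarding regulation is) and w (how much
# collective effort the thresholding task demands).
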