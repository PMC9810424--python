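"""Price of anarchy: how far below the social optimum does the colony land?

Finds the payoff-maximizing joint allocation by differential evolution,
runs the learning dynamics, and compares the two.  A ratio of 1 means the
self-organized colony regulates optimally; lower values are the price of
decentralized task allocation.
"""

import numpy as np

from colonygames import (
    EnvironmentParams,
    LearningParams,
    optimal_allocation,
    relative_efficiency,
    run,
    uniform_simplex,
)

env = EnvironmentParams(b1=28, b2=-6, w=0.3, beta=3)

opt = optimal_allocation(env, restarts=3, rng=np.random.default_rng(0))
print("social optimum (per-member allocations):")
for x, y in opt.traits:
    print(f"  x={x:.2f} y={y:.2f} z={1-x-y:.2f}")
print(f"optimal mean payoff: {opt.mean_payoff:.3f} "
      f"(best symmetric: {opt.symmetric_mean_payoff:.3f})")

traj = run(env, LearningParams(N=100, T=8000, seed=3), uniform_simplex())
rep = relative_efficiency(traj, opt)
print(f"achieved mean payoff at steady state: {rep.achieved:.3f}")
print(f"relative colony efficiency: {rep.ratio:.2f}   SED: {rep.sed:.3f}")
# SED (social efficiency deficit) is the raw payoff an average worker
# forgoes because allocation is decentralized rather than planned.
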