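"""Virtual culling experiment: remove active workers, watch the colony heal.

Runs to a steady state, removes 20% of the currently active workers, and
tracks the active/inactive ratio.  In regimes with a stable attractor the
colony re-establishes its previous activity balance, with previously lazy
workers stepping in — the homeostatic recovery seen in empirical culling
experiments.
"""

from colonygames import (
    EnvironmentParams,
    LearningParams,
    activity_ratio,
    cull_experiment,
    uniform_simplex,
)

env = EnvironmentParams(b1=28, b2=-6, w=0.3, beta=3)
params = LearningParams(N=100, T=4000, seed=5)

traj = cull_experiment(env, params, uniform_simplex(), t_cull=2000,
                       fraction=0.2)
ratios = activity_ratio(traj, threshold=0.5)

before = ratios[ratios.step < 2000]["active"].iloc[-3:].mean()
just_after = ratios[ratios.step >= 2000]["active"].iloc[0]
recovered = ratios["active"].iloc[-3:].mean()
print(f"active fraction before cull:   {before:.2f}")
print(f"active fraction right after:   {just_after:.2f}")
print(f"active fraction at the end:    {recovered:.2f}")
print(f"population size after cull:    {traj.snapshots[-1].shape[0]}")
# the cull removes whole game-groups' worth of workers (a multiple of n),
# so the remaining colony still partitions exactly into games.
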