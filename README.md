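# colonygames

Why do social insect colonies — famously efficient superorganisms — carry
large sub-populations of workers that do essentially nothing?
`colonygames` implements a behavioural-ecology model in which such "lazy"
workers emerge as a by-product of decentralized task allocation, with no
adaptive function of their own.  It is aimed at researchers in collective
behaviour and evolutionary game theory who want a seeded, testable
simulator plus the matching analytic toolkit.

## The model

A colony of *N* workers repeatedly plays *K = N/n* separate *n*-player
games.  Worker *i* is a point on the trait simplex

```
(x_i, y_i, z_i),   x_i + y_i + z_i = 1
```

where *x* is the propensity to work on a **homeostatic** task *X* (e.g.
thermoregulation: over-investment hurts), *y* on a **thresholding** task
*Y* (e.g. brood care or defence: little benefit below a minimum collective
effort), and *z* is inactivity.  In a group with collective efforts
*S_X = Σx*, *S_Y = Σy*, every member receives the benefit share

```
B = (1/n) · B_X(S_X) · B_Y(S_Y),
B_X(S) = max(0, b1·S + b2·S²),
B_Y(S) = sigmoidal in S/n, inflection at w, steepness growing with β,
```

while costs are individual and additive, `C(x, y) = C_X(x) + C_Y(y)`, with
concave ("marginally decreasing") per-task costs.  Payoff is benefit share
minus own cost.  Each step the population is randomly re-partitioned into
games; workers then copy the traits of colony members sampled with
probability `exp(α·Π_l) / Σ_m exp(α·Π_m)` (softmax recruitment — a
Wright–Fisher realisation of replicator-style social learning), and each
worker mutates with probability μ by Gaussian exploration of size σ,
projected back onto the simplex.

Depending on the environment parameters `(b1, b2, w, β)` the colony ends
up in one of four regimes: **fully inactive**, **uniform partly active**
(an ESS), **branching** (stable coexistence of active and lazy workers),
or **bistable** fully-active/fully-inactive.  An adaptive-dynamics layer
(invasion fitness, selection gradients, singular-strategy classification)
predicts these regions analytically, and an efficiency layer quantifies
the *price of anarchy*: the ratio of the achieved steady-state payoff to
the differential-evolution social optimum.

## A worked example

```python
import numpy as np
from colonygames import (EnvironmentParams, LearningParams, run,
                         uniform_simplex, detect_clusters)

env = EnvironmentParams(b1=23, b2=-6, w=0.25, beta=3)   # branching regime
params = LearningParams(N=100, T=30_000, seed=1)        # benchmark defaults
traj = run(env, params, uniform_simplex())
clusters = detect_clusters(np.vstack(traj.window_snapshots(0.1)))
for w_, (x, y, z) in zip(clusters.weights, clusters.means):
    print(f"{w_:4.0%} of the colony at (x={x:.2f}, y={y:.2f}, z={z:.2f})")
```

This run prints two clusters:

```
 24% of the colony at (x=0.01, y=0.96, z=0.03)
 76% of the colony at (x=0.44, y=0.01, z=0.55)
```

— one branch works nearly full-time while the other idles more than half
of its time: an emergent lazy caste.  Branch compositions are stochastic:
other seeds land in different but persistently bimodal splits, and some
fall into the environment's coexisting full-inactivity basin instead.
The `examples/` directory walks through each capability: a single run,
region maps, adaptive dynamics, efficiency, and the virtual culling
experiment in which a colony removes 20% of its active workers and
re-establishes its activity balance.

There is also a thin CLI:

```bash
colony-games simulate --seed 3 --out out/run --override learning.T=5000
colony-games ad --override environment.b1=20
colony-games sweep --method adaptive --out out/regions
```

Every run writes its fully resolved configuration as JSON next to the
outputs; re-running from the same seed and config reproduces them bit for
bit.

## Layout

```
src/colonygames/payoffs.py     benefits, costs, group payoffs (pluggable shapes)
src/colonygames/engine.py      social-learning loop, culling experiment
src/colonygames/analysis.py    clustering, region classification, sweeps
src/colonygames/adaptive.py    invasion fitness, singular strategies, flows
src/colonygames/efficiency.py  social optimum, price of anarchy, SED
src/colonygames/config.py      YAML/JSON configs
src/colonygames/cli.py         colony-games CLI
docs/methods.md                model details, calibration and limitations
```
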