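"""Social optimum, relative colony efficiency and the social efficiency
deficit.

The *social optimum* is the joint allocation of the n group members'
efforts that maximizes the mean individual payoff — found by differential
evolution over the 2n-dimensional joint strategy space (branching steady
states are asymmetric, so the optimum is allowed to be asymmetric too; the
best symmetric allocation is reported alongside).

*Relative colony efficiency* is the ratio of the payoff the self-organized
dynamics actually achieves at steady state to this optimum — the price of
anarchy of decentralized task allocation.  A ratio of 1 means the colony
regulates optimally.  The *social efficiency deficit* (SED) is the raw
difference ``optimal - achieved``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from . import engine
from .engine import LearningParams, Trajectory, uniform_simplex
from .payoffs import EnvironmentParams, group_payoffs

__all__ = [
    "OptimalAllocation",
    "EfficiencyReport",
    "optimal_allocation",
    "relative_efficiency",
    "efficiency_sweep",
]

_TOL = 1e-6


@dataclass
class OptimalAllocation:
    """Best joint allocation found for one group of n workers."""

    traits: np.ndarray  # (n, 2) member strategies
    mean_payoff: float
    symmetric_traits: np.ndarray  # (2,) best all-members-equal strategy
    symmetric_mean_payoff: float
    optimizer_trace: np.ndarray  # best value per restart


def _decode(u: np.ndarray, n: int) -> np.ndarray:
    """Map unconstrained [0,1]^(2n) optimizer variables onto n feasible
    simplex points: x = u, y = v * (1 - u)."""
    u = np.asarray(u).reshape(n, 2)
    xy = np.empty_like(u)
    xy[:, 0] = u[:, 0]
    xy[:, 1] = u[:, 1] * (1.0 - u[:, 0])
    return xy


def _mean_group_payoff(xy: np.ndarray, env: EnvironmentParams, n: int,
                       mode: str) -> float:
    return float(np.mean(group_payoffs(xy, env, n, mode)))


def optimal_allocation(
    env: EnvironmentParams,
    n: int = 5,
    mode: str = "full",
    restarts: int = 5,
    rng: Optional[np.random.Generator] = None,
    maxiter: int = 300,
) -> OptimalAllocation:
    """Globally optimize the group's mean payoff by differential evolution.

    Runs ``restarts`` independent DE searches (best/1/bin, F = 0.5,
    CR = 0.7, population 15 per dimension-set) and keeps the best; also
    solves the symmetric 2-D problem for comparison."""
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)

    def negobj(u):
        return -_mean_group_payoff(_decode(u, n), env, n, mode)

    trace = []
    best = None
    for _ in range(restarts):
        seed = int(rng.integers(2**31 - 1))
        res = differential_evolution(
            negobj,
            bounds=[(0.0, 1.0)] * (2 * n),
            strategy="best1bin",
            mutation=0.5,
            recombination=0.7,
            popsize=15,
            tol=1e-8,
            maxiter=maxiter,
            seed=seed,
            polish=True,
        )
        trace.append(-res.fun)
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res.x)

    def negobj_sym(v):
        x, yfrac = v
        xy = np.tile([x, yfrac * (1 - x)], (n, 1))
        return -_mean_group_payoff(xy, env, n, mode)

    best_sym = None
    for _ in range(max(1, restarts // 2)):
        seed = int(rng.integers(2**31 - 1))
        res = differential_evolution(
            negobj_sym, bounds=[(0.0, 1.0)] * 2, strategy="best1bin",
            mutation=0.5, recombination=0.7, popsize=15, tol=1e-8,
            maxiter=maxiter, seed=seed, polish=True,
        )
        if best_sym is None or -res.fun > best_sym[0]:
            best_sym = (-res.fun, res.x)

    sym_xy = np.array([best_sym[1][0], best_sym[1][1] * (1 - best_sym[1][0])])
    return OptimalAllocation(
        traits=_decode(best[1], n),
        mean_payoff=float(best[0]),
        symmetric_traits=sym_xy,
        symmetric_mean_payoff=float(best_sym[0]),
        optimizer_trace=np.array(trace),
    )


@dataclass
class EfficiencyReport:
    """Achieved vs optimal payoff for one environment."""

    achieved: float
    optimal: float
    ratio: Optional[float]  # None when the optimum is not positive
    sed: float  # optimal - achieved, always reported

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def achieved_payoff(traj: Trajectory, window: float = 0.1) -> float:
    """Steady-state mean individual payoff, time-averaged over the final
    analysis window."""
    mask = traj.window_mask(window)
    return float(np.mean(traj.mean_payoff[mask]))


def relative_efficiency(
    achieved: Union[Trajectory, float],
    optimal: OptimalAllocation,
    window: float = 0.1,
) -> EfficiencyReport:
    """Relative colony efficiency (price of anarchy) and SED.

    ``achieved`` may be a trajectory (time-averaged over its final window)
    or a plain mean-payoff number.  Negative achieved payoffs report a
    ratio of 0 (the printed efficiency scale is 0 to 1); the SED keeps the
    raw difference."""
    if isinstance(achieved, Trajectory):
        ach = achieved_payoff(achieved, window)
    else:
        ach = float(achieved)
    opt = optimal.mean_payoff
    sed = opt - ach
    if opt <= _TOL:
        return EfficiencyReport(achieved=ach, optimal=opt, ratio=None, sed=sed)
    ratio = max(0.0, ach) / opt
    return EfficiencyReport(achieved=ach, optimal=opt, ratio=ratio, sed=sed)


def efficiency_sweep(
    axes: Dict[str, Sequence[float]],
    env: EnvironmentParams,
    params: LearningParams,
    mode: str = "full",
    restarts: int = 3,
    window: float = 0.1,
    init_spec=None,
) -> pd.DataFrame:
    """Efficiency report for every cell of a 2-D environment grid.

    Each cell runs one simulation (same uniform-simplex initial condition
    as the region sweeps) and one global optimization; undefined ratios
    (non-positive optimum) are flagged, not dropped."""
    if len(axes) != 2:
        raise ValueError("efficiency_sweep needs exactly two swept parameters")
    init_spec = init_spec if init_spec is not None else uniform_simplex()
    (name1, vals1), (name2, vals2) = axes.items()
    rows = []
    cell = 0
    for v1 in vals1:
        for v2 in vals2:
            cell_env = env.with_(**{name1: float(v1), name2: float(v2)})
            p = LearningParams(
                n=params.n, N=params.N, alpha=params.alpha, mu=params.mu,
                sigma=params.sigma, T=params.T, seed=params.seed + 7919 * cell,
            )
            traj = engine.run(cell_env, p, init_spec, mode=mode)
            opt = optimal_allocation(
                cell_env, params.n, mode, restarts=restarts,
                rng=np.random.default_rng(params.seed + 7919 * cell + 1),
            )
            rep = relative_efficiency(traj, opt, window)
            rows.append(
                {
                    name1: float(v1),
                    name2: float(v2),
                    "achieved": rep.achieved,
                    "optimal": rep.optimal,
                    "ratio": rep.ratio if rep.defined else np.nan,
                    "sed": rep.sed,
                    "defined": rep.defined,
                }
            )
            cell += 1
    return pd.DataFrame(rows)
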