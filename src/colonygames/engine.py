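"""Discrete-time social-learning dynamics of the task-allocation game.

Each step the population of ``N`` workers is randomly partitioned into
``K = N/n`` games, every worker receives a payoff from its group, and a new
population is formed by sampling parents with replacement with probability
proportional to ``exp(alpha * payoff)`` (softmax over the whole population —
a Wright–Fisher realisation of replicator-style recruitment dynamics).
Each worker then mutates with probability ``mu``: its free traits are
perturbed by Gaussian noise of scale ``sigma`` and projected back onto the
feasible simplex.

All randomness flows from a single top-level seed through named substreams
(``partition``, ``recruitment``, ``mutation``), so a fixed (seed, config)
pair reproduces a trajectory bit for bit and individual substreams can be
replayed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .payoffs import (
    ConfigurationError,
    DomainError,
    EnvironmentParams,
    PartitionError,
    TraitTriple,
    benefit_x,
    benefit_y,
    individual_cost,
)

__all__ = [
    "LearningParams",
    "Population",
    "GamePartition",
    "Trajectory",
    "RngStreams",
    "monomorphic",
    "uniform_simplex",
    "explicit",
    "init_population",
    "partition_games",
    "compute_payoffs",
    "recruitment_step",
    "mutation_step",
    "project_to_simplex",
    "run",
    "cull_experiment",
]

STREAM_NAMES = ("partition", "recruitment", "mutation", "optimizer", "init")


@dataclass(frozen=True)
class LearningParams:
    """Parameters of the social-learning process.

    Defaults follow the benchmark parameterisation: groups of ``n = 5``,
    selection intensity ``alpha = 2``, mutation rate ``mu = 0.01`` with
    size ``sigma = 0.005``, run for ``T = 30000`` steps.  ``N`` must be a
    multiple of ``n`` so the population partitions exactly into games.
    """

    n: int = 5
    N: int = 100
    alpha: float = 2.0
    mu: float = 0.01
    sigma: float = 0.005
    T: int = 30_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N % self.n != 0:
            raise PartitionError(f"N={self.N} must be divisible by n={self.n}")
        if self.alpha < 0:
            raise ConfigurationError("alpha must be >= 0")
        if not 0 <= self.mu <= 1:
            raise ConfigurationError("mu must lie in [0, 1]")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if self.T < 1:
            raise ConfigurationError("T must be >= 1")

    @property
    def K(self) -> int:
        return self.N // self.n


class RngStreams:
    """Named, independently replayable random substreams from one seed."""

    def __init__(self, seed: int):
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(STREAM_NAMES))
        self._streams = {
            name: np.random.default_rng(child)
            for name, child in zip(STREAM_NAMES, children)
        }

    def __getattr__(self, name: str) -> np.random.Generator:
        try:
            return self.__dict__["_streams"][name]
        except KeyError:
            raise AttributeError(name) from None


@dataclass
class Population:
    """State of the learning dynamics: an ``(N, 2)`` array of (x, y) traits.

    ``z = 1 - x - y`` is implicit, so the simplex constraint is exact.
    """

    traits: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        self.traits = np.asarray(self.traits, dtype=float)
        if self.traits.ndim != 2 or self.traits.shape[1] != 2:
            raise ConfigurationError("traits must be an (N, 2) array of (x, y)")
        if not feasible(self.traits):
            raise DomainError("population traits leave the simplex")

    @property
    def N(self) -> int:
        return self.traits.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.traits[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.traits[:, 1]

    @property
    def z(self) -> np.ndarray:
        return 1.0 - self.traits.sum(axis=1)

    def copy(self) -> "Population":
        return Population(self.traits.copy(), self.step)


@dataclass(frozen=True)
class GamePartition:
    """Disjoint assignment of the N agents into K groups of n."""

    groups: np.ndarray  # (K, n) agent indices

    def __post_init__(self) -> None:
        flat = np.sort(self.groups.ravel())
        if not np.array_equal(flat, np.arange(flat.size)):
            raise PartitionError("partition must cover every agent exactly once")


# ---------------------------------------------------------------------------
# initial populations


@dataclass(frozen=True)
class InitSpec:
    kind: str
    x: float = 0.0
    y: float = 0.0
    traits: Optional[Tuple[Tuple[float, float], ...]] = None
    alpha: Tuple[float, float, float] = (1.0, 1.0, 1.0)


def monomorphic(x: float, y: float) -> InitSpec:
    """Everyone starts with the same strategy (x, y, 1-x-y)."""
    TraitTriple(x, y)  # validates
    return InitSpec("monomorphic", x=x, y=y)


def uniform_simplex() -> InitSpec:
    """Traits drawn uniformly from the feasible simplex (Dirichlet(1,1,1))."""
    return InitSpec("uniform_simplex")


def dirichlet(a_x: float, a_y: float, a_z: float) -> InitSpec:
    """Traits drawn from a Dirichlet distribution on the simplex.

    Concentrating mass near a face (e.g. ``dirichlet(1, 1, 0.05)`` for a
    near-fully-active colony) yields a biased population that still carries
    the standing trait variation selection needs to act on."""
    return InitSpec("dirichlet", alpha=(a_x, a_y, a_z))


def explicit(traits: Iterable) -> InitSpec:
    """Exactly the given list of (x, y) pairs or :class:`TraitTriple`."""
    rows = tuple(
        (t.x, t.y) if isinstance(t, TraitTriple) else (float(t[0]), float(t[1]))
        for t in traits
    )
    return InitSpec("explicit", traits=rows)


def _free_axes(mode: str) -> np.ndarray:
    # which of (x, y) a strategy may use in each (sub-)system
    if mode == "full":
        return np.array([True, True])
    if mode == "M1":  # task Y + inactivity only
        return np.array([False, True])
    if mode == "M2":  # task X + inactivity only
        return np.array([True, False])
    raise ConfigurationError(f"unknown mode {mode!r}")


def init_population(
    params: LearningParams,
    init_spec: InitSpec,
    rng: np.random.Generator,
    mode: str = "full",
) -> Population:
    """Build the t=0 population from a specification."""
    N = params.N
    if init_spec.kind == "monomorphic":
        traits = np.tile([init_spec.x, init_spec.y], (N, 1))
    elif init_spec.kind == "uniform_simplex":
        free = _free_axes(mode)
        if free.all():
            traits = rng.dirichlet((1.0, 1.0, 1.0), size=N)[:, :2]
        else:
            traits = np.zeros((N, 2))
            traits[:, np.where(free)[0][0]] = rng.random(N)
    elif init_spec.kind == "dirichlet":
        free = _free_axes(mode)
        if free.all():
            traits = rng.dirichlet(init_spec.alpha, size=N)[:, :2]
        else:
            j = np.where(free)[0][0]
            a = (init_spec.alpha[j], init_spec.alpha[2])
            traits = np.zeros((N, 2))
            traits[:, j] = rng.dirichlet(a, size=N)[:, 0]
    elif init_spec.kind == "explicit":
        traits = np.asarray(init_spec.traits, dtype=float)
        if traits.shape != (N, 2):
            raise ConfigurationError(
                f"explicit init has {traits.shape[0]} traits, expected N={N}"
            )
    else:
        raise ConfigurationError(f"unknown init spec kind {init_spec.kind!r}")
    return Population(traits.copy())


# ---------------------------------------------------------------------------
# one step of the dynamics


def feasible(xy: np.ndarray, tol: float = 1e-9) -> bool:
    return bool(
        np.all(xy >= -tol) and np.all(xy.sum(axis=-1) <= 1 + tol) and np.all(np.isfinite(xy))
    )


def partition_games(
    pop: Population, params: LearningParams, rng: np.random.Generator
) -> GamePartition:
    """Uniformly random partition of the population into K games of n."""
    N = pop.N
    if N % params.n != 0:
        raise PartitionError(f"N={N} not divisible by n={params.n}")
    perm = rng.permutation(N)
    return GamePartition(perm.reshape(N // params.n, params.n))


def compute_payoffs(
    pop: Population,
    partition: GamePartition,
    env: EnvironmentParams,
    mode: str = "full",
    n: Optional[int] = None,
) -> np.ndarray:
    """Per-agent payoffs for one partition, aligned with population order."""
    groups = partition.groups
    n = groups.shape[1] if n is None else n
    xy = pop.traits[groups]  # (K, n, 2)
    Sx = xy[:, :, 0].sum(axis=1)
    Sy = xy[:, :, 1].sum(axis=1)
    if mode == "full":
        share = benefit_x(Sx, env, n) * benefit_y(Sy, env, n) / n
        cost = individual_cost(xy, env, "full")
    elif mode == "M1":
        share = benefit_y(Sy, env, n) / n
        cost = individual_cost(xy, env, "M1")
    elif mode == "M2":
        share = benefit_x(Sx, env, n) / n
        cost = individual_cost(xy, env, "M2")
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    group_pay = share[:, None] - cost  # (K, n)
    payoffs = np.empty(pop.N)
    payoffs[groups] = group_pay
    return payoffs


def recruitment_step(
    pop: Population,
    payoffs: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
) -> Population:
    """Softmax (Wright–Fisher) resampling of the whole population.

    Parent l is copied with probability ``exp(alpha*Π_l) / Σ_m exp(alpha*Π_m)``;
    the exponent is max-shifted for overflow safety.
    """
    payoffs = np.asarray(payoffs, dtype=float)
    if payoffs.shape != (pop.N,):
        raise ConfigurationError("payoff vector length must equal N")
    if not np.all(np.isfinite(payoffs)):
        raise FloatingPointError(
            f"non-finite payoffs in recruitment at step {pop.step}"
        )
    logw = alpha * payoffs
    w = np.exp(logw - logw.max())
    p = w / w.sum()
    parents = rng.choice(pop.N, size=pop.N, replace=True, p=p)
    return Population(pop.traits[parents].copy(), pop.step)


def project_to_simplex(xy: np.ndarray) -> np.ndarray:
    """Euclidean projection of (x, y) points onto {x>=0, y>=0, x+y<=1}.

    Exact: infeasible points are projected onto the nearest of the three
    boundary segments of the trait triangle.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    out = xy.copy()
    inside = (xy[:, 0] >= 0) & (xy[:, 1] >= 0) & (xy.sum(axis=1) <= 1)
    bad = ~inside
    if np.any(bad):
        p = xy[bad]
        cands = np.empty((p.shape[0], 3, 2))
        # edge y = 0
        cands[:, 0, 0] = np.clip(p[:, 0], 0.0, 1.0)
        cands[:, 0, 1] = 0.0
        # edge x = 0
        cands[:, 1, 0] = 0.0
        cands[:, 1, 1] = np.clip(p[:, 1], 0.0, 1.0)
        # edge x + y = 1
        t = np.clip((p[:, 0] - p[:, 1] + 1.0) / 2.0, 0.0, 1.0)
        cands[:, 2, 0] = t
        cands[:, 2, 1] = 1.0 - t
        d2 = ((cands - p[:, None, :]) ** 2).sum(axis=2)
        out[bad] = cands[np.arange(p.shape[0]), d2.argmin(axis=1)]
    return out.reshape(np.asarray(xy).shape)


def mutation_step(
    pop: Population,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
    mode: str = "full",
) -> Population:
    """Behavioural exploration: rare Gaussian perturbation of the traits.

    Each agent is mutated independently with probability ``mu``; its free
    traits receive N(0, sigma) noise and the result is projected back onto
    the feasible set.
    """
    traits = pop.traits.copy()
    mask = rng.random(pop.N) < mu
    m = int(mask.sum())
    if m and sigma > 0:
        free = _free_axes(mode)
        noise = rng.normal(0.0, sigma, size=(m, 2))
        noise[:, ~free] = 0.0
        mutated = traits[mask] + noise
        if mode == "full":
            traits[mask] = project_to_simplex(mutated)
        else:
            j = np.where(free)[0][0]
            traits[mask, j] = np.clip(mutated[:, j], 0.0, 1.0)
    return Population(traits, pop.step)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Time-indexed record of one run: per-step summaries + trait snapshots."""

    env: EnvironmentParams
    params: LearningParams
    mode: str
    steps: np.ndarray
    mean_x: np.ndarray
    mean_y: np.ndarray
    mean_z: np.ndarray
    var_z: np.ndarray
    mean_payoff: np.ndarray
    active_frac: np.ndarray
    snapshot_steps: List[int]
    snapshots: List[np.ndarray]
    cull_step: Optional[int] = None

    def summaries(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.steps,
                "mean_x": self.mean_x,
                "mean_y": self.mean_y,
                "mean_z": self.mean_z,
                "var_z": self.var_z,
                "mean_payoff": self.mean_payoff,
                "active_frac": self.active_frac,
            }
        )

    def snapshot_frame(self) -> pd.DataFrame:
        rows = []
        for step, snap in zip(self.snapshot_steps, self.snapshots):
            df = pd.DataFrame(snap, columns=["x", "y"])
            df.insert(0, "agent", np.arange(snap.shape[0]))
            df.insert(0, "step", step)
            df["z"] = 1.0 - df["x"] - df["y"]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def window_snapshots(self, window: float = 0.1) -> List[np.ndarray]:
        """Snapshots within the final ``window`` fraction of the run."""
        cutoff = self.params.T * (1.0 - window)
        snaps = [s for t, s in zip(self.snapshot_steps, self.snapshots) if t >= cutoff]
        return snaps if snaps else [self.snapshots[-1]]

    def window_mask(self, window: float = 0.1) -> np.ndarray:
        return self.steps >= self.params.T * (1.0 - window)


def _summarise(pop: Population, payoffs: np.ndarray, z_cut: float) -> Tuple[float, ...]:
    z = pop.z
    return (
        float(pop.x.mean()),
        float(pop.y.mean()),
        float(z.mean()),
        float(z.var()),
        float(payoffs.mean()),
        float((z < z_cut).mean()),
    )


def run(
    env: EnvironmentParams,
    params: LearningParams,
    init_spec: InitSpec,
    mode: str = "full",
    record_every: int = 100,
    summary_every: int = 1,
    activity_threshold: float = 0.5,
    _cull: Optional[Tuple[int, float, float]] = None,
) -> Trajectory:
    """Run the full learning loop for T steps and record a trajectory.

    Snapshots of the complete trait matrix are kept every ``record_every``
    steps (plus the first and last); scalar summaries every
    ``summary_every`` steps.  Identical (seed, config) gives identical
    output.
    """
    streams = RngStreams(params.seed)
    pop = init_population(params, init_spec, streams.init, mode)

    steps: List[int] = []
    summaries: List[Tuple[float, ...]] = []
    snapshot_steps: List[int] = []
    snapshots: List[np.ndarray] = []
    cull_step = None

    for t in range(params.T + 1):
        pop.step = t
        if _cull is not None and t == _cull[0]:
            pop = _apply_cull(pop, params.n, _cull[1], _cull[2], streams.partition)
            cull_step = t
        partition = partition_games(pop, params, streams.partition)
        payoffs = compute_payoffs(pop, partition, env, mode, params.n)
        if t % summary_every == 0 or t == params.T:
            steps.append(t)
            summaries.append(_summarise(pop, payoffs, activity_threshold))
        if t % record_every == 0 or t == params.T:
            snapshot_steps.append(t)
            snapshots.append(pop.traits.copy())
        if t == params.T:
            break
        pop = recruitment_step(pop, payoffs, params.alpha, streams.recruitment)
        pop = mutation_step(pop, params.mu, params.sigma, streams.mutation, mode)

    arr = np.array(summaries)
    return Trajectory(
        env=env,
        params=params,
        mode=mode,
        steps=np.array(steps),
        mean_x=arr[:, 0],
        mean_y=arr[:, 1],
        mean_z=arr[:, 2],
        var_z=arr[:, 3],
        mean_payoff=arr[:, 4],
        active_frac=arr[:, 5],
        snapshot_steps=snapshot_steps,
        snapshots=snapshots,
        cull_step=cull_step,
    )


class RemovalError(RuntimeError):
    """Culling asked for more active workers than the colony has."""


def _apply_cull(
    pop: Population,
    n: int,
    fraction: float,
    activity_threshold: float,
    rng: np.random.Generator,
) -> Population:
    active_idx = np.where(pop.z < activity_threshold)[0]
    n_remove = int(fraction * active_idx.size) // n * n
    if n_remove > active_idx.size:
        raise RemovalError(
            f"cannot remove {n_remove} active workers, only {active_idx.size} present"
        )
    if n_remove == 0:
        return pop
    victims = rng.choice(active_idx, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(pop.N), victims)
    return Population(pop.traits[keep].copy(), pop.step)


def cull_experiment(
    env: EnvironmentParams,
    params: LearningParams,
    init_spec: InitSpec,
    t_cull: int,
    fraction: float = 0.2,
    activity_threshold: float = 0.5,
    mode: str = "full",
    record_every: int = 100,
    summary_every: int = 1,
) -> Trajectory:
    """Worker-loss experiment: run to ``t_cull``, then remove a fraction of
    the currently active workers (rounded down to a multiple of n so the
    games still partition) and continue.  The returned trajectory carries
    the active/inactive fraction at every summary step."""
    if not 0 <= fraction < 1:
        raise ConfigurationError("fraction must lie in [0, 1)")
    if t_cull >= params.T:
        raise ConfigurationError("t_cull must precede the end of the run")
    return run(
        env,
        params,
        init_spec,
        mode=mode,
        record_every=record_every,
        summary_every=summary_every,
        activity_threshold=activity_threshold,
        _cull=(t_cull, fraction, activity_threshold),
    )
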