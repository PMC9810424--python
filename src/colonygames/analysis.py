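"""Steady-state detection, branching diagnosis and behavioural-region maps.

A run of the learning dynamics ends in one of four qualitative outcomes,
mirroring how the environment shapes colony behaviour:

* ``fully_inactive`` — the whole population converges on inactivity
  (z = 1) from every initial condition;
* ``uniform_partly_active`` — everyone shares one interior strategy
  (an ESS with 0 < z < 1);
* ``branching`` — the population splits into coexisting sub-populations
  with distinct activity levels (free-riding "lazy" workers);
* ``uniform_full_active_or_inactive`` — bistable: full activity or full
  inactivity depending on the initial population.

Classification works on the final stretch of a trajectory: a trend test
guards against calling a still-moving population "steady", clusters on the
inactivity trait z diagnose branching, and an environment-level classifier
aggregates runs from several canonical initial conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import engine
from .engine import (
    InitSpec,
    LearningParams,
    Trajectory,
    dirichlet,
    uniform_simplex,
)
from .payoffs import EnvironmentParams

__all__ = [
    "REGION_LABELS",
    "ClusterSummary",
    "RegionMap",
    "detect_clusters",
    "classify_run",
    "classify_environment",
    "region_sweep",
    "activity_ratio",
    "CANONICAL_INITS",
]

REGION_LABELS = (
    "uniform_full_active_or_inactive",
    "uniform_partly_active",
    "branching",
    "fully_inactive",
)

# branching thresholds: clusters count as separate branches only when their
# z-means differ by far more than the sigma = 0.005 mutation noise floor
SEPARATION_THRESHOLD = 0.2
MIN_CLUSTER_WEIGHT = 0.10
FULL_TOL = 0.05  # |z - vertex| tolerance for "full" activity/inactivity
TREND_TOL = 0.1  # max drift of mean z across the window before "unresolved"

# canonical initial conditions used to probe bistability; the biased inits
# are Dirichlet-concentrated near a simplex face rather than monomorphic so
# selection has standing variation to act on from step one
CANONICAL_INITS: Dict[str, InitSpec] = {
    "active": dirichlet(1.0, 1.0, 0.05),
    "inactive": dirichlet(0.05, 0.05, 1.0),
    "uniform": uniform_simplex(),
}


@dataclass
class ClusterSummary:
    """Trait clusters of one population snapshot (or pooled window)."""

    k: int
    means: np.ndarray  # (k, 3) mean (x, y, z) per cluster, sorted by z
    weights: np.ndarray  # (k,) population fractions, sum to 1
    separation: float  # z-distance between extreme cluster means

    def __post_init__(self) -> None:
        assert abs(self.weights.sum() - 1.0) < 1e-9


def detect_clusters(snapshot: np.ndarray, max_k: int = 3) -> ClusterSummary:
    """Cluster a population on the inactivity trait z.

    Fits 1-D k-means for k = 1..max_k and keeps the largest k whose
    clusters are all non-trivial (weight >= 10%) and pairwise separated in
    z by more than the branching threshold — a deliberately conservative
    rule so mutation noise around one strategy never reads as branching.
    """
    xy = np.asarray(snapshot, dtype=float)
    z = 1.0 - xy.sum(axis=1)
    N = z.size
    chosen_labels = np.zeros(N, dtype=int)
    chosen_k = 1
    n_distinct = np.unique(np.round(z, 12)).size
    for k in range(2, min(max_k, N, n_distinct) + 1):
        km = KMeans(n_clusters=k, n_init=4, random_state=0).fit(z.reshape(-1, 1))
        centers = km.cluster_centers_.ravel()
        order = np.argsort(centers)
        weights = np.array([(km.labels_ == c).mean() for c in order])
        gaps = np.diff(centers[order])
        if weights.min() >= MIN_CLUSTER_WEIGHT and np.all(gaps > SEPARATION_THRESHOLD):
            chosen_k, chosen_labels = k, km.labels_
        else:
            break
    means = []
    weights = []
    for c in range(chosen_k):
        m = chosen_labels == c
        means.append([xy[m, 0].mean(), xy[m, 1].mean(), z[m].mean()])
        weights.append(m.mean())
    means = np.array(means)
    order = np.argsort(means[:, 2])
    means = means[order]
    weights = np.array(weights)[order]
    separation = float(means[-1, 2] - means[0, 2]) if chosen_k > 1 else 0.0
    return ClusterSummary(k=chosen_k, means=means, weights=weights,
                          separation=separation)


def _window_snaps(traj: Trajectory, window: float) -> List[np.ndarray]:
    snaps = traj.window_snapshots(window)
    if not snaps:
        raise ValueError("trajectory too short for the analysis window")
    return snaps


def classify_run(traj: Trajectory, window: float = 0.1) -> Tuple[str, dict]:
    """Label one trajectory with its behavioural outcome.

    Returns ``(label, diagnostics)``; the label is one of the four region
    labels or ``"unresolved"`` when the mean inactivity still trends across
    the window (no steady state to classify).
    """
    mask = traj.window_mask(window)
    steps = traj.steps[mask]
    mz = traj.mean_z[mask]
    drift = 0.0
    if steps.size >= 2 and steps[-1] > steps[0]:
        slope = np.polyfit(steps, mz, 1)[0]
        drift = float(slope * (steps[-1] - steps[0]))
    snaps = _window_snaps(traj, window)
    per_snap = [detect_clusters(s) for s in snaps]
    branch_frac = float(np.mean([c.k >= 2 for c in per_snap]))
    pooled = detect_clusters(np.vstack(snaps))
    mean_z = float(np.mean(mz)) if mz.size else float(1 - np.vstack(snaps).sum(1).mean())
    diag = {
        "drift": drift,
        "branch_fraction": branch_frac,
        "clusters": pooled,
        "mean_z": mean_z,
    }
    if abs(drift) > TREND_TOL:
        return "unresolved", diag
    if branch_frac >= 0.5 and pooled.k >= 2:
        return "branching", diag
    if mean_z > 1 - FULL_TOL:
        return "fully_inactive", diag
    if mean_z < FULL_TOL:
        # a single fully active strategy: the bistable region's active face
        return "uniform_full_active_or_inactive", diag
    return "uniform_partly_active", diag


def classify_environment(
    env: EnvironmentParams,
    params: LearningParams,
    n_replicates: int = 2,
    inits: Optional[Dict[str, InitSpec]] = None,
    mode: str = "full",
    window: float = 0.1,
    agreement_floor: float = 0.5,
) -> Tuple[str, dict]:
    """Classify an environment by simulating from several initial conditions.

    Full inactivity is only attributed when *every* run ends inactive; a
    split where active-leaning starts stay active and inactive-leaning
    starts die out is the bistable region.  Otherwise the majority label
    wins, with the replicate agreement reported.
    """
    inits = inits if inits is not None else CANONICAL_INITS
    labels: Dict[str, List[str]] = {}
    runs = 0
    for name, spec in inits.items():
        labels[name] = []
        for rep in range(n_replicates):
            p = LearningParams(
                n=params.n, N=params.N, alpha=params.alpha, mu=params.mu,
                sigma=params.sigma, T=params.T,
                seed=params.seed + 104729 * runs,
            )
            runs += 1
            traj = engine.run(env, p, spec, mode=mode)
            lab, _ = classify_run(traj, window)
            labels[name].append(lab)
    flat = [l for ls in labels.values() for l in ls]
    diag = {"labels_by_init": labels}
    resolved = [l for l in flat if l != "unresolved"]
    if not resolved:
        return "unresolved", diag
    if all(l == "fully_inactive" for l in resolved):
        return "fully_inactive", diag

    def mostly(name, lab):
        ls = [l for l in labels.get(name, []) if l != "unresolved"]
        return bool(ls) and sum(l == lab for l in ls) > len(ls) / 2

    # bistability: full activity from the active-leaning start, extinction
    # from the inactive-leaning one (an interior ESS from the active start
    # is *not* bistability even if the inactive start dies out — the
    # inactive vertex has a residual basin in most environments)
    bistable = (
        mostly("active", "uniform_full_active_or_inactive")
        and mostly("inactive", "fully_inactive")
    )
    if bistable:
        diag["agreement"] = 1.0
        return "uniform_full_active_or_inactive", diag
    counts = pd.Series(resolved).value_counts()
    label = counts.index[0]
    agreement = float(counts.iloc[0] / len(resolved))
    diag["agreement"] = agreement
    if agreement < agreement_floor:
        return "unresolved", diag
    return label, diag


@dataclass
class RegionMap:
    """Region labels over a 2-D grid of environment parameters."""

    axis_names: Tuple[str, str]
    axis_values: Tuple[np.ndarray, np.ndarray]
    labels: np.ndarray  # (len(ax1), len(ax2)) object array of labels
    agreement: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        a1, a2 = self.axis_values
        for i, v1 in enumerate(a1):
            for j, v2 in enumerate(a2):
                rows.append(
                    {
                        self.axis_names[0]: v1,
                        self.axis_names[1]: v2,
                        "label": self.labels[i, j],
                        "agreement": self.agreement[i, j],
                    }
                )
        return pd.DataFrame(rows)


def region_sweep(
    axes: Dict[str, Sequence[float]],
    env: EnvironmentParams,
    params: LearningParams,
    mode: str = "full",
    method: str = "adaptive",
    n_replicates: int = 2,
) -> RegionMap:
    """Label every cell of a 2-D environment-parameter grid.

    ``method='adaptive'`` uses the analytic adaptive-dynamics fast path
    (seconds per cell); ``method='simulation'`` runs the full classifier.
    """
    if len(axes) != 2:
        raise ValueError("region_sweep needs exactly two swept parameters")
    (name1, vals1), (name2, vals2) = axes.items()
    vals1 = np.asarray(list(vals1), dtype=float)
    vals2 = np.asarray(list(vals2), dtype=float)
    labels = np.empty((vals1.size, vals2.size), dtype=object)
    agreement = np.ones((vals1.size, vals2.size))
    from . import adaptive  # deferred to avoid import cycle

    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            cell_env = env.with_(**{name1: float(v1), name2: float(v2)})
            if method == "adaptive":
                labels[i, j] = adaptive.predicted_region(cell_env, params.n, mode)
            elif method == "simulation":
                lab, diag = classify_environment(
                    cell_env, params, n_replicates=n_replicates, mode=mode
                )
                labels[i, j] = lab
                agreement[i, j] = diag.get("agreement", 1.0)
            else:
                raise ValueError(f"unknown sweep method {method!r}")
    return RegionMap(
        axis_names=(name1, name2),
        axis_values=(vals1, vals2),
        labels=labels,
        agreement=agreement,
    )


def activity_ratio(traj: Trajectory, threshold: float = 0.5) -> pd.DataFrame:
    """Fractions of active (z < threshold) and inactive workers over time.

    Uses the recorded trait snapshots; the two fractions sum to 1 at every
    recorded step."""
    rows = []
    for step, snap in zip(traj.snapshot_steps, traj.snapshots):
        z = 1.0 - snap.sum(axis=1)
        act = float((z < threshold).mean())
        rows.append({"step": step, "active": act, "inactive": 1.0 - act})
    return pd.DataFrame(rows)
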