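"""Adaptive-dynamics analysis of the task-allocation game.

Treats the population as monomorphic with resident strategy ``r = (x, y)``
and asks how rare mutants fare.  The invasion fitness of mutant ``m``
against resident ``r`` is the expected payoff of a single mutant in a group
with ``n - 1`` residents minus the resident's payoff in an all-resident
group.  Its gradient in the mutant direction drives the slow trait
dynamics; strategies where the gradient vanishes (singular strategies) are
classified by second-order conditions into

* ``ess`` — convergence stable and locally uninvadable: the population
  settles on one shared strategy;
* ``branching_point`` — convergence stable but invadable: the population
  is first attracted to the strategy and then splits into coexisting
  sub-populations (the route by which inactive workers emerge);
* ``repeller`` — not convergence stable.

Everything here is numerical (finite differences + root finding), so it
works for any registered benefit/cost shapes, not just the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .payoffs import (
    DomainError,
    EnvironmentParams,
    benefit_x,
    benefit_y,
    individual_cost,
)

__all__ = [
    "ResidentStrategy",
    "SingularStrategy",
    "invasion_payoff",
    "selection_gradient",
    "mutant_hessian",
    "convergence_jacobian",
    "find_singular",
    "streamline_field",
    "integrate_flow",
    "predicted_region",
]

_FD_STEP = 1e-5
_ROOT_TOL = 1e-8
_DEDUPE_RADIUS = 1e-4
_EIG_TOL = 1e-7


@dataclass(frozen=True)
class ResidentStrategy:
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < -1e-12 or self.y < -1e-12 or self.x + self.y > 1 + 1e-12:
            raise DomainError(f"resident ({self.x}, {self.y}) infeasible")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class SingularStrategy:
    """A zero of the selection gradient with its second-order classification."""

    location: Tuple[float, float]
    gradient_norm: float
    second_order: np.ndarray  # mutant Hessian restricted to free directions
    convergence_eigs: np.ndarray
    classification: str  # ess | branching_point | repeller | degenerate

    @property
    def invadable(self) -> bool:
        return bool(np.max(np.real(np.linalg.eigvalsh(self.second_order))) > _EIG_TOL)

    @property
    def convergence_stable(self) -> bool:
        return bool(np.max(np.real(self.convergence_eigs)) < -_EIG_TOL)


def _as_xy(point) -> np.ndarray:
    if isinstance(point, ResidentStrategy):
        return point.as_array()
    return np.asarray(point, dtype=float)


def invasion_payoff(mutant, resident, env: EnvironmentParams, n: int = 5,
                    mode: str = "full") -> float:
    """Fitness of a rare mutant: its payoff among n-1 residents minus the
    resident's payoff in an all-resident group.  Zero at mutant = resident."""
    m = _as_xy(mutant)
    r = _as_xy(resident)
    for p, who in ((m, "mutant"), (r, "resident")):
        if p[0] < -1e-12 or p[1] < -1e-12 or p.sum() > 1 + 1e-12:
            raise DomainError(f"{who} strategy {tuple(p)} infeasible")

    def group_payoff_of_focal(focal, others):
        Sx = focal[0] + (n - 1) * others[0]
        Sy = focal[1] + (n - 1) * others[1]
        if mode == "full":
            share = benefit_x(Sx, env, n) * benefit_y(Sy, env, n) / n
        elif mode == "M1":
            share = benefit_y(Sy, env, n) / n
        elif mode == "M2":
            share = benefit_x(Sx, env, n) / n
        else:
            raise DomainError(f"unknown mode {mode!r}")
        return share - individual_cost(focal, env, mode)

    return group_payoff_of_focal(m, r) - group_payoff_of_focal(r, r)


def _free_directions(r: np.ndarray, mode: str, tol: float = 1e-9) -> List[int]:
    if mode == "M1":
        return [1]
    if mode == "M2":
        return [0]
    return [0, 1]


def selection_gradient(resident, env: EnvironmentParams, n: int = 5,
                       mode: str = "full", h: float = _FD_STEP) -> np.ndarray:
    """Derivative of invasion fitness in the mutant directions at m = r.

    Central finite differences in the interior; one-sided differencing on
    the simplex boundary (where the default concave costs make the inward
    derivative the only defined one).
    """
    r = _as_xy(resident)
    g = np.zeros(2)
    for j in _free_directions(r, mode):
        e = np.zeros(2)
        e[j] = 1.0
        lo_ok = r[j] - h >= 0
        hi_ok = r.sum() + h <= 1
        if lo_ok and hi_ok:
            g[j] = (
                invasion_payoff(r + h * e, r, env, n, mode)
                - invasion_payoff(r - h * e, r, env, n, mode)
            ) / (2 * h)
        elif hi_ok:
            g[j] = (
                invasion_payoff(r + h * e, r, env, n, mode)
                - invasion_payoff(r, r, env, n, mode)
            ) / h
        elif lo_ok:
            g[j] = (
                invasion_payoff(r, r, env, n, mode)
                - invasion_payoff(r - h * e, r, env, n, mode)
            ) / h
    if not np.all(np.isfinite(g)):
        raise FloatingPointError(f"non-finite selection gradient at {tuple(r)}")
    return g


def mutant_hessian(resident, env: EnvironmentParams, n: int = 5,
                   mode: str = "full", h: float = 1e-4,
                   directions: Optional[Sequence[int]] = None) -> np.ndarray:
    """Second derivatives of invasion fitness in the mutant directions at
    m = r, restricted to ``directions`` (defaults to the interior-free ones).

    A positive eigenvalue means nearby mutants on that axis can invade
    (disruptive selection)."""
    r = _as_xy(resident)
    dirs = [j for j in (directions if directions is not None
                        else _free_directions(r, mode))
            if j in _free_directions(r, mode)]
    k = len(dirs)
    H = np.zeros((k, k))

    def f(dm):
        m = r.copy()
        for idx, j in enumerate(dirs):
            m[j] += dm[idx]
        # clip tiny boundary violations introduced by the stencil
        m = np.clip(m, 0.0, None)
        if m.sum() > 1:
            m = m / m.sum()
        return invasion_payoff(m, r, env, n, mode)

    # shift the stencil inward when the resident sits on a boundary so all
    # stencil points stay feasible
    base = np.zeros(k)
    for idx, j in enumerate(dirs):
        if r[j] < h:
            base[idx] = h - r[j]
    f0 = f(base)
    for a in range(k):
        ea = np.zeros(k)
        ea[a] = h
        H[a, a] = (f(base + ea) - 2 * f0 + f(base - ea)) / h**2
        for b in range(a + 1, k):
            eb = np.zeros(k)
            eb[b] = h
            H[a, b] = H[b, a] = (
                f(base + ea + eb) - f(base + ea - eb)
                - f(base - ea + eb) + f(base - ea - eb)
            ) / (4 * h**2)
    return H


def convergence_jacobian(resident, env: EnvironmentParams, n: int = 5,
                         mode: str = "full", h: float = 1e-4) -> np.ndarray:
    """Jacobian of the selection-gradient map with respect to the resident;
    eigenvalues with negative real parts mean the singular strategy attracts
    the monomorphic dynamics (convergence stability)."""
    r = _as_xy(resident)
    dirs = _free_directions(r, mode)
    J = np.zeros((len(dirs), len(dirs)))
    for col, j in enumerate(dirs):
        e = np.zeros(2)
        e[j] = 1.0
        rp = np.clip(r + h * e, 0, None)
        rm = np.clip(r - h * e, 0, None)
        if rp.sum() > 1:
            rp /= rp.sum()
        gp = selection_gradient(rp, env, n, mode)
        gm = selection_gradient(rm, env, n, mode)
        J[:, col] = (gp[dirs] - gm[dirs]) / (rp[j] - rm[j])
    return J


def _classify(loc: np.ndarray, env, n, mode, gnorm: float) -> SingularStrategy:
    # restrict second-order analysis to directions not pinned at a boundary
    free = [j for j in _free_directions(loc, mode) if loc[j] > 1e-6]
    if loc.sum() > 1 - 1e-6:
        pass  # the active edge still admits tangential variation; keep both
    if not free:
        free = _free_directions(loc, mode)
    H = mutant_hessian(loc, env, n, mode, directions=free)
    J = convergence_jacobian(loc, env, n, mode)
    eigJ = np.linalg.eigvals(J)
    eigH = np.linalg.eigvalsh(H)
    cs = np.max(np.real(eigJ)) < -_EIG_TOL
    inv = np.max(eigH) > _EIG_TOL
    if np.max(np.abs(eigH)) <= _EIG_TOL or abs(np.max(np.real(eigJ))) <= _EIG_TOL:
        label = "degenerate"
    elif not cs:
        label = "repeller"
    elif inv:
        label = "branching_point"
    else:
        label = "ess"
    return SingularStrategy(
        location=(float(loc[0]), float(loc[1])),
        gradient_norm=gnorm,
        second_order=H,
        convergence_eigs=eigJ,
        classification=label,
    )


def default_starts() -> List[Tuple[float, float]]:
    """3x3 interior lattice plus near-vertex points."""
    pts = [(a, b) for a in (0.15, 0.4, 0.65) for b in (0.15, 0.4, 0.65) if a + b < 1]
    pts += [(0.9, 0.05), (0.05, 0.9), (0.02, 0.02)]
    return pts


def find_singular(env: EnvironmentParams, n: int = 5, mode: str = "full",
                  starts: Optional[Sequence[Tuple[float, float]]] = None
                  ) -> List[SingularStrategy]:
    """Root-find the selection gradient from multiple starts and classify
    the distinct feasible roots."""
    starts = list(starts) if starts is not None else default_starts()
    dirs = _free_directions(np.zeros(2), mode)

    def fun(v):
        r = np.zeros(2)
        r[dirs] = v
        r = np.clip(r, 1e-9, None)
        if r.sum() > 1 - 1e-9:
            r *= (1 - 1e-9) / r.sum()
        return selection_gradient(r, env, n, mode)[dirs]

    found: List[np.ndarray] = []
    for s in starts:
        v0 = np.asarray(s, dtype=float)[dirs]
        try:
            sol = optimize.root(fun, v0, method="hybr", tol=_ROOT_TOL)
        except FloatingPointError:
            continue
        if not sol.success:
            continue
        r = np.zeros(2)
        r[dirs] = sol.x
        if np.any(r < -1e-7) or r.sum() > 1 + 1e-7:
            continue
        r = np.clip(r, 0, None)
        if any(np.linalg.norm(r - f) < _DEDUPE_RADIUS for f in found):
            continue
        found.append(r)
    out = []
    for r in found:
        gnorm = float(np.linalg.norm(selection_gradient(r, env, n, mode)))
        out.append(_classify(r, env, n, mode, gnorm))
    return out


# ---------------------------------------------------------------------------
# trait flow


def _projected_gradient(r: np.ndarray, env, n, mode) -> np.ndarray:
    """Selection gradient projected onto the feasible cone at r, so the flow
    can slide along the simplex boundary instead of leaving it."""
    g = selection_gradient(r, env, n, mode)
    for j in _free_directions(r, mode):
        if r[j] <= 1e-9 and g[j] < 0:
            g[j] = 0.0
    if r.sum() >= 1 - 1e-9 and g.sum() > 0:
        g = g - g.sum() / 2.0 * np.ones(2)  # remove outward normal (1,1)/sqrt2
        for j in range(2):
            if r[j] <= 1e-9 and g[j] < 0:
                g[j] = 0.0
    mask = np.zeros(2)
    mask[_free_directions(r, mode)] = 1.0
    return g * mask


def integrate_flow(start, env: EnvironmentParams, n: int = 5, mode: str = "full",
                   max_steps: int = 4000, step_size: float = 0.01,
                   tol: float = 1e-7) -> np.ndarray:
    """Follow the monomorphic trait dynamics dr/dt = gradient from ``start``
    until the projected gradient vanishes; returns the endpoint."""
    r = np.clip(_as_xy(start), 0.0, None).astype(float)
    if r.sum() > 1:
        r /= r.sum()
    for _ in range(max_steps):
        g = _projected_gradient(r, env, n, mode)
        gn = np.linalg.norm(g)
        if gn < tol:
            break
        r = r + g * min(step_size / gn, 0.05)  # bounded trait displacement
        r = np.clip(r, 0.0, None)
        if r.sum() > 1:
            r /= r.sum()
    return r


def streamline_field(env: EnvironmentParams, n: int = 5, mode: str = "full",
                     grid: int = 21):
    """Selection gradient on a lattice over the trait simplex.

    Returns an (M, 4) array of rows (x, y, dx, dy) at feasible nodes —
    the raw material of a streamline plot of the monomorphic dynamics."""
    vals = np.linspace(0.0, 1.0, grid)
    rows = []
    for x in vals:
        for y in vals:
            if x + y > 1 + 1e-12:
                continue
            g = selection_gradient(np.array([x, y]), env, n, mode)
            rows.append((x, y, g[0], g[1]))
    return np.array(rows)


CANONICAL_FLOW_STARTS = [(0.475, 0.475), (0.02, 0.02), (1 / 3, 1 / 3),
                         (0.1, 0.4), (0.4, 0.1)]


def predicted_region(env: EnvironmentParams, n: int = 5, mode: str = "full",
                     starts: Optional[Sequence[Tuple[float, float]]] = None,
                     z_full: float = 0.05) -> str:
    """Fast analytic classification of an environment into the four
    behavioural regions, by integrating the monomorphic trait flow from
    canonical initial strategies and classifying the attractors reached.

    Returns one of ``fully_inactive``, ``branching``,
    ``uniform_partly_active``, ``uniform_full_active_or_inactive`` (or
    ``unresolved`` on degenerate second-order terms)."""
    starts = list(starts) if starts is not None else list(CANONICAL_FLOW_STARTS)
    outcomes = []
    for s in starts:
        end = integrate_flow(s, env, n, mode)
        zs = 1 - end.sum()
        if end.sum() < z_full:
            outcomes.append("inactive")
            continue
        sing = _classify(end, env, n, mode,
                         float(np.linalg.norm(selection_gradient(end, env, n, mode))))
        if sing.classification == "branching_point":
            outcomes.append("branching")
        elif sing.classification in ("ess", "degenerate", "repeller"):
            # flow endpoints are attractors by construction; classify by z
            if sing.classification == "degenerate":
                outcomes.append("degenerate")
            elif zs < z_full:
                outcomes.append("active")
            else:
                outcomes.append("partly_active")
        else:
            outcomes.append("degenerate")
    if "branching" in outcomes:
        return "branching"
    kinds = set(outcomes)
    if kinds == {"inactive"}:
        return "fully_inactive"
    if "degenerate" in kinds:
        return "unresolved"
    if "partly_active" in kinds and "inactive" not in kinds:
        return "uniform_partly_active"
    # any mix of full-activity and full-inactivity endpoints
    return "uniform_full_active_or_inactive"
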