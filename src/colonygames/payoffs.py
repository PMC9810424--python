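"""Benefits, costs and payoffs of the two-task allocation game.

A colony worker allocates its effort among a homeostatic task X (e.g.
thermoregulation), a thresholding task Y (e.g. brood care or defence) and
inactivity, described by a point ``(x, y, z)`` on the 2-simplex.  Workers
interact in groups of ``n``; the group's benefit couples the two tasks
multiplicatively and is shared equally, while costs are individual and
additive across tasks:

    B(Sx, Sy) = (1/n) * B_X(Sx) * B_Y(Sy)
    C(x, y)   = C_X(x) + C_Y(y)
    payoff_j  = B(Sx, Sy) - C(x_j, y_j)

where ``Sx, Sy`` are the collective efforts (sums of the members' x and y).

Functional forms are pluggable by name; the defaults are

* ``quadratic`` benefit for X: ``max(0, b1*S + b2*S**2)`` — unimodal
  (homeostatic) for ``b2 < 0``, monotone (maximizing) for ``b2 >= 0``;
* ``tanh_sigmoid`` benefit for Y: a tanh ramp normalised to [0, 1] with
  inflection at per-capita effort ``w``; steepness grows as ``beta**2``
  (near-linear at beta = 1, near-hard threshold at beta >= 3);
* ``shifted_power`` costs ``c * ((e + e0)**q - e0**q)`` with exponent
  ``q <= 1`` — concave increasing (marginally decreasing: extra effort at
  a task gets cheaper with practice) with a finite marginal cost at zero.
  A plain ``power`` law ``c * e**q`` is registered as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict

import numpy as np

__all__ = [
    "EnvironmentParams",
    "TraitTriple",
    "GroupEfforts",
    "benefit_x",
    "benefit_y",
    "combined_benefit",
    "individual_cost",
    "group_payoffs",
    "register_benefit_x",
    "register_benefit_y",
    "register_cost",
    "MODES",
]

MODES = ("full", "M1", "M2")

# Cost scale calibrated so that, together with the default benefit forms,
# the printed environment points of the benchmark parameter table fall in
# their qualitative behavioural regions (see docs/methods.md).
DEFAULT_COST_COEFF = 1.5
DEFAULT_COST_EXPONENT = 0.5
DEFAULT_COST_OFFSET = 0.2


class DomainError(ValueError):
    """Argument outside the feasible domain of a game function."""


class ConfigurationError(ValueError):
    """Unknown mode, shape name or inconsistent configuration."""


class PartitionError(ValueError):
    """Group or partition structure violates K = N/n bookkeeping."""


@dataclass(frozen=True)
class TraitTriple:
    """One worker's strategy: probabilities of task X, task Y, inactivity.

    ``z`` is implicit (``1 - x - y``) so the simplex constraint holds
    exactly by construction.
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < -1e-12 or self.y < -1e-12 or self.x + self.y > 1 + 1e-12:
            raise DomainError(
                f"trait ({self.x}, {self.y}) outside the simplex x,y>=0, x+y<=1"
            )

    @property
    def z(self) -> float:
        return 1.0 - self.x - self.y

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class GroupEfforts:
    """Collective engagement levels of one n-player group."""

    Sx: float
    Sy: float


@dataclass(frozen=True)
class EnvironmentParams:
    """Environment of the game: benefit shapes and cost scales.

    Parameters
    ----------
    b1, b2
        Linear and quadratic benefit coefficients of task X.  ``b1`` sets
        how rewarding regulation is; ``b2 < 0`` makes the task homeostatic
        (over-investment hurts), ``b2 >= 0`` makes it maximizing.
    w
        Inflection point of the task-Y benefit, as a per-capita effort
        fraction in (0, 1); roughly the minimum collective engagement the
        task needs before it starts paying off.
    beta
        Slope of the task-Y sigmoid; ``beta = 1`` is essentially linear,
        larger values approach a hard threshold.
    cost_coeff_x, cost_coeff_y, cost_exponent, cost_offset
        Scale, concavity and offset of the per-task effort costs; the
        default shifted power law ``C_T(e) = c_T*((e+e0)**q - e0**q)`` is
        concave increasing (``q <= 1`` keeps marginal costs decreasing)
        with a finite marginal cost at zero effort.
    """

    b1: float
    b2: float
    w: float
    beta: float
    cost_coeff_x: float = DEFAULT_COST_COEFF
    cost_coeff_y: float = DEFAULT_COST_COEFF
    cost_exponent: float = DEFAULT_COST_EXPONENT
    cost_offset: float = DEFAULT_COST_OFFSET
    benefit_x_shape: str = "quadratic"
    benefit_y_shape: str = "tanh_sigmoid"
    cost_shape: str = "shifted_power"

    def __post_init__(self) -> None:
        if not 0.0 < self.w < 1.0:
            raise ConfigurationError(f"w must lie in (0, 1), got {self.w}")
        if self.beta <= 0.0:
            raise ConfigurationError(f"beta must be positive, got {self.beta}")
        if self.cost_coeff_x < 0 or self.cost_coeff_y < 0:
            raise ConfigurationError("cost coefficients must be non-negative")
        if not 0.0 < self.cost_exponent <= 1.0:
            raise ConfigurationError(
                f"cost_exponent must lie in (0, 1], got {self.cost_exponent}"
            )
        for name, registry in (
            (self.benefit_x_shape, _BENEFIT_X_SHAPES),
            (self.benefit_y_shape, _BENEFIT_Y_SHAPES),
            (self.cost_shape, _COST_SHAPES),
        ):
            if name not in registry:
                raise ConfigurationError(f"unknown function shape {name!r}")

    def with_(self, **kwargs) -> "EnvironmentParams":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# pluggable functional forms


def _quadratic_benefit_x(S, env: EnvironmentParams):
    return np.maximum(0.0, env.b1 * S + env.b2 * np.square(S))


def _tanh_sigmoid_benefit_y(S, env: EnvironmentParams, n: int):
    # steepness grows as beta^2: beta = 1 is close to a linear ramp while
    # beta >= 3 is a near-hard threshold at per-capita effort w
    g = env.beta**2
    w = env.w
    lo = np.tanh(g * w)
    hi = np.tanh(g * (1.0 - w))
    return (np.tanh(g * (np.asarray(S) / n - w)) + lo) / (hi + lo)


def _tanh_soft_benefit_y(S, env: EnvironmentParams, n: int):
    # same normalised ramp with steepness linear in beta (gentler threshold)
    b = env.beta
    w = env.w
    lo = np.tanh(b * w)
    hi = np.tanh(b * (1.0 - w))
    return (np.tanh(b * (np.asarray(S) / n - w)) + lo) / (hi + lo)


def _power_cost(e, coeff: float, q: float, e0: float = 0.0):
    return coeff * np.power(np.maximum(np.asarray(e, dtype=float), 0.0), q)


def _shifted_power_cost(e, coeff: float, q: float, e0: float):
    # concave increasing with finite marginal cost at zero effort
    e = np.maximum(np.asarray(e, dtype=float), 0.0)
    return coeff * (np.power(e + e0, q) - e0**q)


_BENEFIT_X_SHAPES: Dict[str, Callable] = {"quadratic": _quadratic_benefit_x}
_BENEFIT_Y_SHAPES: Dict[str, Callable] = {
    "tanh_sigmoid": _tanh_sigmoid_benefit_y,
    "tanh_soft": _tanh_soft_benefit_y,
}
_COST_SHAPES: Dict[str, Callable] = {
    "power": _power_cost,
    "shifted_power": _shifted_power_cost,
}


def register_benefit_x(name: str, fn: Callable) -> None:
    """Register a user-supplied task-X benefit ``fn(S, env) -> value``."""
    _BENEFIT_X_SHAPES[name] = fn


def register_benefit_y(name: str, fn: Callable) -> None:
    """Register a user-supplied task-Y benefit ``fn(S, env, n) -> value``."""
    _BENEFIT_Y_SHAPES[name] = fn


def register_cost(name: str, fn: Callable) -> None:
    """Register a user-supplied cost component ``fn(e, coeff, q, e0) -> value``."""
    _COST_SHAPES[name] = fn


# ---------------------------------------------------------------------------
# game functions


def _check_effort(S, n: int, label: str) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if np.any(S < -1e-9) or np.any(S > n + 1e-9):
        raise DomainError(f"{label} must lie in [0, {n}]")
    return S


def benefit_x(Sx, env: EnvironmentParams, n: int = 5):
    """Collective benefit of task X at collective effort ``Sx`` in [0, n]."""
    Sx = _check_effort(Sx, n, "Sx")
    out = _BENEFIT_X_SHAPES[env.benefit_x_shape](Sx, env)
    return out if out.ndim else float(out)


def benefit_y(Sy, env: EnvironmentParams, n: int = 5):
    """Collective benefit of task Y at collective effort ``Sy`` in [0, n].

    The default form rises sigmoidally from 0 (no effort) to 1 (everyone
    fully engaged), steepest where per-capita effort crosses ``w``.
    """
    Sy = _check_effort(Sy, n, "Sy")
    out = _BENEFIT_Y_SHAPES[env.benefit_y_shape](Sy, env, n)
    return out if out.ndim else float(out)


def combined_benefit(g: GroupEfforts, env: EnvironmentParams, n: int, mode: str = "full"):
    """Per-member benefit share of a group with collective efforts ``g``.

    ``mode='full'`` couples the two tasks multiplicatively; the sub-systems
    ``M1`` (task Y + inactivity) and ``M2`` (task X + inactivity) keep only
    their own task's benefit factor.
    """
    if mode == "full":
        return benefit_x(g.Sx, env, n) * benefit_y(g.Sy, env, n) / n
    if mode == "M1":
        return benefit_y(g.Sy, env, n) / n
    if mode == "M2":
        return benefit_x(g.Sx, env, n) / n
    raise ConfigurationError(f"unknown mode {mode!r}; expected one of {MODES}")


def individual_cost(t, env: EnvironmentParams, mode: str = "full"):
    """Additive individual cost ``C_X(x) + C_Y(y)`` of one worker's efforts.

    ``t`` may be a :class:`TraitTriple` or an ``(..., 2)`` array of (x, y).
    Sub-systems only pay the cost of their own task.
    """
    if isinstance(t, TraitTriple):
        xy = t.as_array()
    else:
        xy = np.asarray(t, dtype=float)
    cost_fn = _COST_SHAPES[env.cost_shape]
    cx = cost_fn(xy[..., 0], env.cost_coeff_x, env.cost_exponent, env.cost_offset)
    cy = cost_fn(xy[..., 1], env.cost_coeff_y, env.cost_exponent, env.cost_offset)
    if mode == "full":
        total = cx + cy
    elif mode == "M1":
        total = cy
    elif mode == "M2":
        total = cx
    else:
        raise ConfigurationError(f"unknown mode {mode!r}; expected one of {MODES}")
    return total if np.ndim(total) else float(total)


def group_payoffs(group, env: EnvironmentParams, n: int = 5, mode: str = "full"):
    """Payoffs of the ``n`` members of one game group.

    Each member receives the equal benefit share minus its own cost.
    ``group`` is a sequence of :class:`TraitTriple` or an ``(n, 2)`` array.
    """
    if isinstance(group, np.ndarray):
        xy = np.asarray(group, dtype=float)
    else:
        xy = np.array(
            [t.as_array() if isinstance(t, TraitTriple) else t for t in group],
            dtype=float,
        )
    if xy.shape != (n, 2):
        raise PartitionError(f"group must have exactly {n} members, got shape {xy.shape}")
    g = GroupEfforts(Sx=float(xy[:, 0].sum()), Sy=float(xy[:, 1].sum()))
    share = combined_benefit(g, env, n, mode)
    return share - individual_cost(xy, env, mode)
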