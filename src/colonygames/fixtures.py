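"""Deterministic toy populations with known structure, for tests and demos."""

from __future__ import annotations

import numpy as np

from .engine import Population
from .payoffs import ConfigurationError

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("monomorphic", "bimodal", "uniform_simplex", "noisy_blob")


def make_fixture(
    name: str,
    N: int = 100,
    seed: int = 0,
    x: float = 0.3,
    y: float = 0.7,
    inactive_fraction: float = 0.5,
    sd: float = 0.01,
) -> Population:
    """Build a named toy population.

    * ``monomorphic`` — N copies of (x, y);
    * ``bimodal`` — an ``inactive_fraction`` of agents fully inactive
      (0, 0, 1), the rest at (x, y) — a constructed branching state;
    * ``uniform_simplex`` — traits uniform on the feasible simplex;
    * ``noisy_blob`` — Gaussian cloud of width ``sd`` around (x, y),
      clipped to the simplex (mutation-noise stand-in).

    The same (name, seed, parameters) always yields the same population.
    """
    rng = np.random.default_rng(seed)
    if name == "monomorphic":
        traits = np.tile([x, y], (N, 1))
    elif name == "bimodal":
        n_in = int(round(N * inactive_fraction))
        traits = np.vstack(
            [np.tile([x, y], (N - n_in, 1)), np.zeros((n_in, 2))]
        )
    elif name == "uniform_simplex":
        traits = rng.dirichlet((1.0, 1.0, 1.0), size=N)[:, :2]
    elif name == "noisy_blob":
        traits = rng.normal([x, y], sd, size=(N, 2))
        traits = np.clip(traits, 0.0, None)
        s = traits.sum(axis=1)
        over = s > 1
        traits[over] /= s[over, None]
    else:
        raise ConfigurationError(
            f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}"
        )
    return Population(traits)
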