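"""Visibility-scaled threshold cascade of panic buying.

Each consumer carries a personal panic threshold drawn from a normal
distribution with mean ``threshold_mean`` and s.d. ``threshold_sd`` and then
divided by the product's visibility ``v > 0``: conspicuous products (big
trolleys of toilet paper) shrink everyone's threshold, inconspicuous ones
(pharmaceuticals) enlarge it. Thresholds are in panic-fraction units — a
consumer starts panic buying once the fraction of the population already
panic buying reaches their own threshold — so anyone with a threshold at or
below zero panics immediately (a lockdown scare). The synchronous
best-response dynamic is monotone and reaches an equilibrium in at most n
rounds.

The default calibration sets sigma = mu / Phi^-1(0.9), which puts exactly
10% of the base normal's mass at or below zero: about 10% of consumers are
triggered at the initial state regardless of visibility (scaling by 1/v
preserves signs).

In the large-population limit the equilibrium panic fraction is the smallest
fixed point f* >= Phi(-mu/sigma) of

    f = Phi((v * f - mu) / sigma),

computed by :func:`analytic_fixed_point` via monotone iteration; the
simulation and the fixed point agree to Monte-Carlo accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DEFAULT_THRESHOLD_MEAN",
    "DEFAULT_THRESHOLD_SD",
    "PanicConfig",
    "PanicPopulation",
    "CascadeResult",
    "draw_thresholds",
    "cascade_step",
    "run_cascade",
    "analytic_fixed_point",
    "sweep_visibility",
]

DEFAULT_THRESHOLD_MEAN: float = 0.35
#: sigma chosen so that Phi(-mu/sigma) = 0.10 exactly (10% initial triggers).
DEFAULT_THRESHOLD_SD: float = DEFAULT_THRESHOLD_MEAN / float(norm.ppf(0.9))


@dataclass(frozen=True)
class PanicConfig:
    """Parameters of one cascade run."""

    n_consumers: int = 1000
    visibility: float = 1.0
    threshold_mean: float = DEFAULT_THRESHOLD_MEAN
    threshold_sd: float = DEFAULT_THRESHOLD_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_consumers <= 0:
            raise ValueError("n_consumers must be positive")
        if self.visibility <= 0:
            raise ValueError("visibility must be positive")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")


@dataclass
class PanicPopulation:
    """Thresholds (panic-fraction units, already scaled by 1/v) and states."""

    thresholds: np.ndarray
    panicking: np.ndarray

    @property
    def n_consumers(self) -> int:
        return self.thresholds.size

    @property
    def panic_fraction(self) -> float:
        return float(self.panicking.mean())


@dataclass(frozen=True)
class CascadeResult:
    """Round-by-round panic fractions and the equilibrium they reach."""

    fraction_trajectory: np.ndarray
    equilibrium_fraction: float
    rounds_to_equilibrium: int
    initial_fraction: float


def draw_thresholds(
    config: PanicConfig, rng: np.random.Generator | None = None
) -> PanicPopulation:
    """Draw normal thresholds and scale by 1/visibility.

    Scaling by a positive constant preserves signs, so the set of initially
    panicking consumers (threshold <= 0) does not depend on visibility.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base = rng.normal(config.threshold_mean, config.threshold_sd, config.n_consumers)
    thresholds = base / config.visibility
    return PanicPopulation(thresholds=thresholds, panicking=thresholds <= 0.0)


def cascade_step(population: PanicPopulation) -> PanicPopulation:
    """One synchronous best-response round; panic is absorbing."""
    f = population.panic_fraction
    new_panicking = population.panicking | (population.thresholds <= f)
    return PanicPopulation(thresholds=population.thresholds, panicking=new_panicking)


def run_cascade(
    config: PanicConfig, population: PanicPopulation | None = None
) -> CascadeResult:
    """Iterate synchronous rounds to the (finite, deterministic) equilibrium.

    Each round at least one consumer joins or the process has stopped, so at
    most ``n_consumers`` rounds occur. The trajectory starts with the initial
    fraction and is nondecreasing.
    """
    if population is None:
        population = draw_thresholds(config)
    trajectory = [population.panic_fraction]
    rounds = 0
    while True:
        nxt = cascade_step(population)
        if nxt.panicking.sum() == population.panicking.sum():
            break
        population = nxt
        trajectory.append(population.panic_fraction)
        rounds += 1
    return CascadeResult(
        fraction_trajectory=np.array(trajectory),
        equilibrium_fraction=trajectory[-1],
        rounds_to_equilibrium=rounds,
        initial_fraction=trajectory[0],
    )


def analytic_fixed_point(
    visibility: float,
    threshold_mean: float = DEFAULT_THRESHOLD_MEAN,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> float:
    """Large-population equilibrium panic fraction.

    Iterates f <- Phi((v f - mu) / sigma) from f0 = Phi(-mu/sigma). The map
    is nondecreasing in f and f1 >= f0, so the iteration increases
    monotonically to the smallest fixed point at or above the initial
    trigger fraction. Converges to ``tol`` (default 1e-10).
    """
    if visibility <= 0:
        raise ValueError("visibility must be positive")
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    f = float(norm.cdf(-threshold_mean / threshold_sd))
    for _ in range(max_iter):
        nxt = float(norm.cdf((visibility * f - threshold_mean) / threshold_sd))
        if abs(nxt - f) < tol:
            return nxt
        f = nxt
    return f


def sweep_visibility(
    v_grid,
    replicates: int,
    config: PanicConfig | None = None,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Independent cascade runs over a visibility grid.

    Returns a tidy table with one row per (v, replicate): columns
    ``v, replicate, seed, initial_fraction, equilibrium_fraction, rounds``.
    Thresholds are freshly drawn per cell from a child seed derived
    deterministically from the master seed and the cell position.
    """
    v_grid = np.asarray(list(v_grid), dtype=float)
    if v_grid.size == 0:
        raise ValueError("v_grid must be nonempty")
    if np.any(v_grid <= 0):
        raise ValueError("all visibility values must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if config is None:
        config = PanicConfig()
    if master_seed is None:
        master_seed = config.seed
    rows = []
    for vi, v in enumerate(v_grid):
        for rep in range(replicates):
            child = np.random.SeedSequence([int(master_seed), vi, rep])
            seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
            cfg = replace(config, visibility=float(v), seed=seed)
            res = run_cascade(cfg)
            rows.append(
                {
                    "v": float(v),
                    "replicate": rep,
                    "seed": seed,
                    "initial_fraction": res.initial_fraction,
                    "equilibrium_fraction": res.equilibrium_fraction,
                    "rounds": res.rounds_to_equilibrium,
                }
            )
    return pd.DataFrame(rows)
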