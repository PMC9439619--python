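"""Modified SIR contagion of conspiracy belief with assortative matching.

A population of N individuals holds four compartments: most are
*unsusceptible* (will never believe the theory), a minority are
*susceptible*, a seed group is *infected* (believes), and believers who
abandon the belief become *recovered* — recovery is social, not biological,
and is one-directional: S -> I -> R, with the unsusceptible never moving.

Each period one individual i is drawn uniformly. If i is infected, with
probability ``assortative_prob`` (the echo-chamber parameter m) its partner
j is drawn uniformly from the *other infected*; otherwise — and always when
i is uninfected — j is uniform over everyone else. The pair then interacts:

* susceptible x infected: the susceptible becomes infected, starting with
  the initial recovery probability;
* unsusceptible-or-recovered x infected: the infected recovers with its
  current recovery probability; under *cumulative influence* a failed
  attempt multiplies that probability by ``influence_factor`` (capped at 1);
* infected x infected: both recovery probabilities are multiplied by
  ``reinforcement_factor`` (belief reinforcement; disabled under
  *constant recovery*);
* any other pairing changes nothing.

Time is reported as mean interactions per individual: two people interact
per period, so the unit is ``n_population / 2`` periods. Baseline defaults
(N=1000, 100 susceptible, 10 infected, m=0.5, initial recovery 0.05,
reinforcement 0.9) sustain a permanent believer core; removing
reinforcement, or letting non-believers exert cumulative influence
(factor 1.1), burns the belief out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "UNSUSCEPTIBLE",
    "SUSCEPTIBLE",
    "INFECTED",
    "RECOVERED",
    "ContagionConfig",
    "ContagionState",
    "TrajectoryRecord",
    "init_population",
    "match_pair",
    "interact",
    "run_contagion",
    "sweep_assortativity",
]

UNSUSCEPTIBLE, SUSCEPTIBLE, INFECTED, RECOVERED = 0, 1, 2, 3


@dataclass(frozen=True)
class ContagionConfig:
    """Parameters of one contagion run (defaults = baseline scenario)."""

    n_population: int = 1000
    n_susceptible: int = 100
    n_infected_initial: int = 10
    assortative_prob: float = 0.5
    recovery_prob_initial: float = 0.05
    reinforcement_factor: float = 0.9
    influence_factor: float = 1.1
    cumulative_influence: bool = False
    constant_recovery: bool = False
    n_periods: int | None = None
    periods_per_capita: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_infected_initial <= self.n_susceptible <= self.n_population:
            raise ValueError(
                "need 0 < n_infected_initial <= n_susceptible <= n_population"
            )
        for name in ("assortative_prob", "recovery_prob_initial"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.reinforcement_factor <= 1.0:
            raise ValueError("reinforcement_factor must lie in (0, 1]")
        if self.influence_factor < 1.0:
            raise ValueError("influence_factor must be >= 1")

    def resolved_n_periods(self) -> int:
        """Default horizon: 250 periods per capita = 500 mean interactions,
        long enough for the burn-out scenarios to actually reach extinction."""
        if self.n_periods is not None:
            return self.n_periods
        return self.periods_per_capita * self.n_population


@dataclass
class ContagionState:
    """Per-individual compartment labels and recovery probabilities."""

    compartment: np.ndarray
    recovery_prob: np.ndarray

    @property
    def n_population(self) -> int:
        return self.compartment.size

    def counts(self) -> dict[str, int]:
        c = self.compartment
        return {
            "unsusceptible": int(np.sum(c == UNSUSCEPTIBLE)),
            "susceptible": int(np.sum(c == SUSCEPTIBLE)),
            "infected": int(np.sum(c == INFECTED)),
            "recovered": int(np.sum(c == RECOVERED)),
        }


@dataclass(frozen=True)
class TrajectoryRecord:
    """Compartment counts over time plus the final snapshot.

    ``time`` is in mean interactions per individual (2 x periods / N).
    ``extinction_time`` is the time at which the infected count first hit
    zero, or None if believers persisted to the horizon. After extinction
    the counts are constant; the arrays are padded to the full horizon.
    """

    time: np.ndarray
    susceptible: np.ndarray
    infected: np.ndarray
    recovered: np.ndarray
    final_state: ContagionState
    extinction_time: float | None

    @property
    def all_susceptible_ever_infected(self) -> bool:
        """Susceptibility is only lost by infection, so final S==0 means
        every initially susceptible individual believed at some point."""
        return int(self.susceptible[-1]) == 0

    @property
    def peak_infected(self) -> int:
        return int(self.infected.max())

    @property
    def final_infected(self) -> int:
        return int(self.infected[-1])


def init_population(
    config: ContagionConfig, rng: np.random.Generator | None = None
) -> ContagionState:
    """Assign compartments uniformly at random.

    ``n_infected_initial`` believers (each with the initial recovery
    probability), ``n_susceptible - n_infected_initial`` susceptibles, and
    the rest unsusceptible.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_population
    comp = np.full(n, UNSUSCEPTIBLE, dtype=np.int8)
    chosen = rng.choice(n, size=config.n_susceptible, replace=False)
    comp[chosen[: config.n_infected_initial]] = INFECTED
    comp[chosen[config.n_infected_initial :]] = SUSCEPTIBLE
    prob = np.zeros(n, dtype=float)
    prob[comp == INFECTED] = config.recovery_prob_initial
    return ContagionState(compartment=comp, recovery_prob=prob)


def match_pair(
    state: ContagionState,
    assortative_prob: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw the interacting pair (i, j), i uniform, j by assortative rule.

    An infected i is matched to another infected with probability
    ``assortative_prob`` (falling back to a uniform partner when i is the
    sole believer); otherwise, and for uninfected i, j is uniform over
    everyone else. Never returns i == j.
    """
    n = state.n_population
    if n < 2:
        raise ValueError("need at least two individuals to match")
    i = int(rng.integers(n))
    if state.compartment[i] == INFECTED and rng.random() < assortative_prob:
        infected = np.flatnonzero(state.compartment == INFECTED)
        if infected.size > 1:
            k = int(rng.integers(infected.size - 1))
            pos = int(np.searchsorted(infected, i))
            if k >= pos:
                k += 1
            return i, int(infected[k])
    j = int(rng.integers(n - 1))
    if j >= i:
        j += 1
    return i, j


def interact(
    state: ContagionState,
    i: int,
    j: int,
    config: ContagionConfig,
    rng: np.random.Generator,
) -> tuple[int | None, int | None]:
    """Apply the single applicable pair rule in place.

    Returns ``(newly_infected, newly_recovered)`` individual indices (or
    None) so callers tracking the believer set can update it incrementally.
    """
    comp, prob = state.compartment, state.recovery_prob
    ci, cj = int(comp[i]), int(comp[j])
    if ci == SUSCEPTIBLE and cj == INFECTED:
        comp[i] = INFECTED
        prob[i] = config.recovery_prob_initial
        return i, None
    if cj == SUSCEPTIBLE and ci == INFECTED:
        comp[j] = INFECTED
        prob[j] = config.recovery_prob_initial
        return j, None
    if ci == INFECTED and cj == INFECTED:
        if not config.constant_recovery:
            prob[i] *= config.reinforcement_factor
            prob[j] *= config.reinforcement_factor
        return None, None
    for target, other in ((i, cj), (j, ci)):
        if int(comp[target]) == INFECTED and other in (UNSUSCEPTIBLE, RECOVERED):
            if rng.random() < prob[target]:
                comp[target] = RECOVERED
                return None, target
            if config.cumulative_influence:
                prob[target] = min(1.0, prob[target] * config.influence_factor)
            return None, None
    return None, None


def run_contagion(config: ContagionConfig) -> TrajectoryRecord:
    """Simulate matching + interaction for the configured horizon.

    Counts are sampled every ``n_population // 2`` periods (one unit of mean
    interactions per individual). The run stops early once the infected
    count reaches zero — an absorbing state — and the trajectory is padded
    with the constant tail. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    state = init_population(config, rng)
    comp = state.compartment
    n = config.n_population
    n_periods = config.resolved_n_periods()
    sample_every = max(1, n // 2)

    infected_list: list[int] = [int(x) for x in np.flatnonzero(comp == INFECTED)]
    pos = np.full(n, -1, dtype=np.int64)
    for idx, ind in enumerate(infected_list):
        pos[ind] = idx

    counts = state.counts()
    s_count, i_count, r_count = (
        counts["susceptible"],
        counts["infected"],
        counts["recovered"],
    )
    times = [0.0]
    s_traj, i_traj, r_traj = [s_count], [i_count], [r_count]
    extinction_time: float | None = None

    m = config.assortative_prob
    draws_i = rng.integers(0, n, size=n_periods)
    coins = rng.random(n_periods)

    for t in range(1, n_periods + 1):
        i = int(draws_i[t - 1])
        j = -1
        if comp[i] == INFECTED and coins[t - 1] < m and len(infected_list) > 1:
            k = int(rng.integers(len(infected_list) - 1))
            if k >= pos[i]:
                k += 1
            j = infected_list[k]
        else:
            j = int(rng.integers(n - 1))
            if j >= i:
                j += 1
        newly_inf, newly_rec = interact(state, i, j, config, rng)
        if newly_inf is not None:
            pos[newly_inf] = len(infected_list)
            infected_list.append(newly_inf)
            s_count -= 1
            i_count += 1
        elif newly_rec is not None:
            # swap-remove from the believer list
            p = int(pos[newly_rec])
            last = infected_list[-1]
            infected_list[p] = last
            pos[last] = p
            infected_list.pop()
            pos[newly_rec] = -1
            i_count -= 1
            r_count += 1
        if t % sample_every == 0:
            times.append(2.0 * t / n)
            s_traj.append(s_count)
            i_traj.append(i_count)
            r_traj.append(r_count)
        if i_count == 0:
            extinction_time = 2.0 * t / n
            break

    # pad the constant post-extinction tail to the full horizon
    n_ticks = n_periods // sample_every
    while len(times) < n_ticks + 1:
        tick = len(times)
        times.append(2.0 * tick * sample_every / n)
        s_traj.append(s_count)
        i_traj.append(i_count)
        r_traj.append(r_count)

    return TrajectoryRecord(
        time=np.array(times),
        susceptible=np.array(s_traj),
        infected=np.array(i_traj),
        recovered=np.array(r_traj),
        final_state=state,
        extinction_time=extinction_time,
    )


def sweep_assortativity(
    m_grid,
    replicates: int,
    config: ContagionConfig | None = None,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Runs over a grid of assortative-matching probabilities.

    One row per (m, replicate): final and peak infected counts and the
    extinction time (NaN if the belief persisted). Child seeds derive
    deterministically from the master seed and the cell position, and are
    shared across m values at equal replicate index, giving paired
    comparisons.
    """
    m_grid = list(m_grid)
    if not m_grid:
        raise ValueError("m_grid must be nonempty")
    if any(not 0.0 <= m <= 1.0 for m in m_grid):
        raise ValueError("assortative probabilities must lie in [0, 1]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if config is None:
        config = ContagionConfig()
    if master_seed is None:
        master_seed = config.seed
    rows = []
    for m in m_grid:
        for rep in range(replicates):
            child = np.random.SeedSequence([int(master_seed), rep])
            seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
            cfg = replace(config, assortative_prob=float(m), seed=seed)
            rec = run_contagion(cfg)
            rows.append(
                {
                    "m": float(m),
                    "replicate": rep,
                    "seed": seed,
                    "final_infected": rec.final_infected,
                    "peak_infected": rec.peak_infected,
                    "extinction_time": (
                        np.nan if rec.extinction_time is None else rec.extinction_time
                    ),
                }
            )
    return pd.DataFrame(rows)
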