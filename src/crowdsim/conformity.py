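"""Asynchronous social-learning model of conformity on a small world.

Each of N agents holds a real-valued score: its propensity toward a
behaviour (say, mask wearing). A strictly positive score means the agent
does the behaviour; zero or below means it does not. Scores are spatially
correlated on the underlying ring (like-minded people cluster), with a
moderate pro-behaviour majority and a minority of anti-behaviour agents.

Agents differ in conformism: each agent i is assigned a permissible range
[score_i - r_i, score_i + r_i] centred on its initial score, with the
half-range r_i drawn uniformly from a configured interval. Wide ranges mean
conformist agents whose views can be dragged far by others; narrow ranges
mean stubborn agents.

One period: a uniformly random agent observes one uniformly random social
contact and moves its own score by a small step ``theta`` toward the
contact's behaviour (up if the contact does the behaviour, down otherwise).
A step that would leave the permissible range is rejected outright (the
score stays put); optionally it can be clamped to the boundary instead.
Behaviour is re-derived from the sign of the score after every update.

The rewiring probability of the small world controls the outcome: with
little rewiring, clusters reinforce themselves and the population polarises
toward the range boundaries; with more rewiring, the pro majority reaches
into anti clusters through long-range ties and a near-consensus emerges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import (
    Network,
    ScoreFieldConfig,
    SmallWorldConfig,
    generate_correlated_scores,
    generate_ring_lattice,
    rewire,
)

__all__ = [
    "ConformityConfig",
    "ConformityState",
    "ConformityResult",
    "init_state",
    "learning_step",
    "run_learning",
    "polarization_metrics",
]


@dataclass(frozen=True)
class ConformityConfig:
    """Parameters of one conformity-learning run.

    Defaults give the canonical experiment: N=500 agents each linked to its
    5 nearest neighbours per side (k=10), correlated initial scores with a
    ~25% anti minority, step size theta = 0.02 in units of the score-field
    amplitude, conformism half-ranges uniform on [0.5, 2.0], and 2000
    expected updates per agent — long enough for opinion fronts, whose
    inter-flip waiting times run to hundreds of periods, to finish
    propagating. ``n_periods`` of None means ``periods_per_agent * n_nodes``
    total asynchronous updates, with early convergence declared after
    ``stall_periods_per_agent * n_nodes`` consecutive periods without a
    behaviour flip.
    """

    network_config: SmallWorldConfig = field(
        default_factory=lambda: SmallWorldConfig(n_nodes=500, degree=10, rewiring_prob=0.1)
    )
    score_field_config: ScoreFieldConfig | None = None
    step_size: float = 0.02
    conformism_low: float = 0.5
    conformism_high: float = 2.0
    n_periods: int | None = None
    periods_per_agent: int = 2000
    stall_periods_per_agent: int = 200
    clamp_to_boundary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_size < 0:
            raise ValueError("step_size must be nonnegative")
        if not 0 < self.conformism_low <= self.conformism_high:
            raise ValueError("need 0 < conformism_low <= conformism_high")
        if self.n_periods is not None and self.n_periods < 0:
            raise ValueError("n_periods must be nonnegative")

    def resolved_score_field(self) -> ScoreFieldConfig:
        cfg = self.score_field_config
        if cfg is None:
            cfg = ScoreFieldConfig(n_nodes=self.network_config.n_nodes)
        if cfg.n_nodes != self.network_config.n_nodes:
            raise ValueError("score field and network sizes disagree")
        return cfg

    def resolved_n_periods(self) -> int:
        if self.n_periods is not None:
            return self.n_periods
        return self.periods_per_agent * self.network_config.n_nodes


@dataclass
class ConformityState:
    """Scores, per-agent permissible ranges, and derived behaviour."""

    scores: np.ndarray
    range_low: np.ndarray
    range_high: np.ndarray
    behavior: np.ndarray

    def check(self) -> None:
        """Assert the structural invariants (used heavily in tests)."""
        assert np.all(self.range_low <= self.scores + 1e-12)
        assert np.all(self.scores <= self.range_high + 1e-12)
        assert np.array_equal(self.behavior, self.scores > 0.0)


@dataclass(frozen=True)
class ConformityResult:
    """Initial/final scores plus the sampled pro-behaviour trajectory."""

    initial_scores: np.ndarray
    final_scores: np.ndarray
    range_low: np.ndarray
    range_high: np.ndarray
    pro_fraction_trajectory: np.ndarray
    n_periods_run: int
    converged_early: bool

    def metrics(self) -> dict:
        return polarization_metrics(
            self.initial_scores, self.final_scores, self.range_low, self.range_high
        )


def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    """Four independent child streams: network, scores, ranges, learning."""
    children = np.random.SeedSequence(seed).spawn(4)
    return tuple(np.random.default_rng(c) for c in children)


def init_state(config: ConformityConfig) -> tuple[ConformityState, Network]:
    """Build the small world, the correlated scores, and the conformism ranges.

    Each agent's permissible range is centred on its initial score with a
    half-range drawn uniformly from [conformism_low, conformism_high], so the
    initial score always lies inside the range.
    """
    net_rng, score_rng, range_rng, _ = _streams(config.seed)
    net_cfg = config.network_config
    network = rewire(generate_ring_lattice(net_cfg), net_cfg.rewiring_prob, net_rng)
    scores = generate_correlated_scores(config.resolved_score_field(), score_rng)
    half = range_rng.uniform(config.conformism_low, config.conformism_high, scores.size)
    state = ConformityState(
        scores=scores,
        range_low=scores - half,
        range_high=scores + half,
        behavior=scores > 0.0,
    )
    return state, network


def learning_step(
    state: ConformityState,
    network: Network,
    rng: np.random.Generator,
    step_size: float = 0.02,
    clamp_to_boundary: bool = False,
    _adjacency: list[np.ndarray] | None = None,
) -> ConformityState:
    """One asynchronous period: random agent observes one random contact.

    Mutates and returns ``state``. An isolated agent (no contacts) simply
    skips its turn. The observed contact's behaviour sets the direction of
    the theta step; an out-of-range proposal is rejected (default) or
    clamped to the violated boundary.
    """
    adj = _adjacency if _adjacency is not None else network.adjacency()
    i = int(rng.integers(state.scores.size))
    nbrs = adj[i]
    if nbrs.size == 0:
        return state
    j = int(nbrs[int(rng.integers(nbrs.size))])
    delta = step_size if state.behavior[j] else -step_size
    proposed = state.scores[i] + delta
    if state.range_low[i] <= proposed <= state.range_high[i]:
        state.scores[i] = proposed
    elif clamp_to_boundary:
        state.scores[i] = np.clip(proposed, state.range_low[i], state.range_high[i])
    state.behavior[i] = state.scores[i] > 0.0
    return state


def run_learning(config: ConformityConfig) -> ConformityResult:
    """Simulate the social-learning process over many periods.

    Runs ``resolved_n_periods()`` asynchronous updates (default 1000 per
    agent on average), sampling the pro-behaviour fraction every ``n_nodes``
    periods, and stops early once no behaviour flip has occurred for
    ``stall_periods_per_agent * n_nodes`` consecutive periods — by then
    scores only creep along within fixed sign basins. Deterministic for a
    fixed seed.
    """
    state, network = init_state(config)
    initial_scores = state.scores.copy()
    _, _, _, rng = _streams(config.seed)

    n = state.scores.size
    n_periods = config.resolved_n_periods()
    stall_limit = config.stall_periods_per_agent * n
    theta = config.step_size
    clamp = config.clamp_to_boundary

    flat, offsets = network.adjacency_csr()
    scores = state.scores
    lo, hi = state.range_low, state.range_high
    behavior = state.behavior
    trajectory = [float(behavior.mean())]

    last_flip = 0
    t = 0
    block = 1 << 15
    while t < n_periods and (t - last_flip) <= stall_limit:
        m = min(block, n_periods - t)
        agents = rng.integers(0, n, size=m)
        picks = rng.random(m)
        for s in range(m):
            i = agents[s]
            start, stop = offsets[i], offsets[i + 1]
            deg = stop - start
            if deg == 0:
                t += 1
                if t % n == 0:
                    trajectory.append(float(behavior.mean()))
                continue
            j = flat[start + int(picks[s] * deg)]
            proposed = scores[i] + (theta if behavior[j] else -theta)
            if lo[i] <= proposed <= hi[i]:
                scores[i] = proposed
            elif clamp:
                scores[i] = min(max(proposed, lo[i]), hi[i])
            new_b = scores[i] > 0.0
            if new_b != behavior[i]:
                behavior[i] = new_b
                last_flip = t
            t += 1
            if t % n == 0:
                trajectory.append(float(behavior.mean()))
        if (t - last_flip) > stall_limit:
            break

    return ConformityResult(
        initial_scores=initial_scores,
        final_scores=scores.copy(),
        range_low=lo.copy(),
        range_high=hi.copy(),
        pro_fraction_trajectory=np.array(trajectory),
        n_periods_run=t,
        converged_early=t < n_periods,
    )


def polarization_metrics(
    initial_scores,
    final_scores,
    range_low=None,
    range_high=None,
    boundary_frac: float = 0.1,
) -> dict:
    """Summary statistics operationalising the polarisation-vs-consensus plots.

    Returns the anti-behaviour share before/after, the final/initial score
    variance ratio, and — when the permissible ranges are supplied — the
    shares of agents parked within ``boundary_frac`` of their range
    boundaries on the matching side ("strongly" pro or anti).
    """
    initial = np.asarray(initial_scores, dtype=float)
    final = np.asarray(final_scores, dtype=float)
    if initial.shape != final.shape:
        raise ValueError("initial and final score vectors differ in length")
    var_i = float(np.var(initial))
    var_f = float(np.var(final))
    if var_i > 0:
        variance_ratio = var_f / var_i
    else:
        variance_ratio = 1.0 if var_f == 0 else float("inf")
    out = {
        "fraction_anti_initial": float(np.mean(initial <= 0.0)),
        "fraction_anti_final": float(np.mean(final <= 0.0)),
        "variance_initial": var_i,
        "variance_final": var_f,
        "variance_ratio": variance_ratio,
        "fraction_strongly_pro": None,
        "fraction_strongly_anti": None,
    }
    if range_low is not None and range_high is not None:
        lo = np.asarray(range_low, dtype=float)
        hi = np.asarray(range_high, dtype=float)
        if lo.shape != final.shape or hi.shape != final.shape:
            raise ValueError("range vectors differ in length from scores")
        width = hi - lo
        near_hi = final >= hi - boundary_frac * width
        near_lo = final <= lo + boundary_frac * width
        out["fraction_strongly_pro"] = float(np.mean(near_hi & (final > 0.0)))
        out["fraction_strongly_anti"] = float(np.mean(near_lo & (final <= 0.0)))
    return out
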