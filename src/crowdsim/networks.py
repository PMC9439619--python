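"""Ring lattices, Watts–Strogatz small worlds, and correlated score fields.

The conformity model runs on a small-world network built the classic way:
start from a ring lattice with ``n_nodes`` nodes, each linked to its
``degree / 2`` nearest neighbours on either side, then rewire every lattice
edge independently with probability ``rewiring_prob`` by detaching its
clockwise endpoint and reattaching it to a uniformly random node (self-loops
and duplicate edges are resolved by redrawing the target, so the edge count
is exactly preserved). Low rewiring keeps the lattice's high clustering;
even a little rewiring collapses the average path length — the small-world
combination seen in real social networks.

Initial behavioural propensities ("scores") are spatially correlated on the
ring: neighbours tend to be similar people. :func:`generate_correlated_scores`
produces such a field by circular moving-average smoothing of Gaussian white
noise, so negative-score (anti-behaviour) agents appear in contiguous runs
rather than scattered singletons.

Node indices are 0-based throughout. Descriptions elsewhere that speak of
"agent 100 linked to agents 95–99 and 101–105" use 1-based labels; the same
neighbourhood holds here after subtracting one from every label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.stats import norm

__all__ = [
    "SmallWorldConfig",
    "ScoreFieldConfig",
    "Network",
    "generate_ring_lattice",
    "rewire",
    "generate_small_world",
    "generate_correlated_scores",
    "write_edge_list",
    "read_edge_list",
]


def _edge(u: int, v: int) -> tuple[int, int]:
    """Canonical unordered representation of an edge."""
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class SmallWorldConfig:
    """Parameters of the Watts–Strogatz construction.

    Parameters
    ----------
    n_nodes : int
        Number of nodes N.
    degree : int
        Links per node k in the initial lattice; must be even and < N.
    rewiring_prob : float
        Per-edge rewiring probability p in [0, 1].
    seed : int
        Seed for the rewiring random stream.
    """

    n_nodes: int
    degree: int
    rewiring_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        if self.degree <= 0 or self.degree % 2 != 0:
            raise ValueError("degree must be a positive even integer")
        if self.degree >= self.n_nodes:
            raise ValueError("degree must be smaller than n_nodes")
        if not 0.0 <= self.rewiring_prob <= 1.0:
            raise ValueError("rewiring_prob must lie in [0, 1]")


@dataclass(frozen=True)
class ScoreFieldConfig:
    """Parameters of the spatially correlated initial-score field.

    ``smoothness`` is the moving-average window (in node indices): 1 gives
    uncorrelated white noise, larger windows give longer runs of like-minded
    agents. ``anti_fraction_target`` is the intended share of negative
    (anti-behaviour) scores and must name a minority (< 0.5). When
    ``mean_level`` is None (the default) the offset is calibrated *per
    realization* by a quantile shift, so the realized negative share matches
    the target up to rounding: the anti minority is a controlled initial
    condition of the experiments, not a random outcome. An explicit
    ``mean_level`` disables that and applies the fixed offset instead, under
    which the negative share matches the normal tail mass only in
    expectation.
    """

    n_nodes: int
    anti_fraction_target: float = 0.25
    smoothness: int = 10
    amplitude: float = 1.0
    mean_level: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        if not 0.0 < self.anti_fraction_target < 0.5:
            raise ValueError(
                "anti_fraction_target must lie in (0, 0.5): the anti-behaviour "
                "group is a minority by construction"
            )
        if self.smoothness < 1:
            raise ValueError("smoothness must be a positive integer")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.mean_level is not None and self.mean_level <= 0 and self.amplitude > 0:
            raise ValueError(
                "mean_level <= 0 makes negative scores the majority; the "
                "requested anti_fraction_target < 0.5 is unattainable"
            )

    @property
    def resolved_mean_level(self) -> float:
        if self.mean_level is not None:
            return float(self.mean_level)
        return float(self.amplitude * norm.ppf(1.0 - self.anti_fraction_target))


@dataclass
class Network:
    """Undirected simple graph over 0-based node indices."""

    n_nodes: int
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        canon = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValueError(f"edge ({u}, {v}) out of range for n_nodes={self.n_nodes}")
            canon.add(_edge(int(u), int(v)))
        self.edges = canon

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> list[np.ndarray]:
        """Neighbour index arrays, one per node, each sorted ascending."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            nbrs[u].append(v)
            nbrs[v].append(u)
        return [np.array(sorted(a), dtype=np.int64) for a in nbrs]

    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened neighbour list plus offsets (CSR layout) for tight loops."""
        adj = self.adjacency()
        offsets = np.zeros(self.n_nodes + 1, dtype=np.int64)
        for i, a in enumerate(adj):
            offsets[i + 1] = offsets[i] + len(a)
        flat = np.concatenate(adj) if offsets[-1] else np.empty(0, dtype=np.int64)
        return flat, offsets

    def to_networkx(self):
        """Export as :class:`networkx.Graph` (all nodes present, even isolated)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


def generate_ring_lattice(config: SmallWorldConfig) -> Network:
    """Ring lattice: node i linked to its degree/2 nearest neighbours each side.

    The edge count is exactly ``n_nodes * degree / 2``.
    """
    n, k = config.n_nodes, config.degree
    edges = set()
    for offset in range(1, k // 2 + 1):
        for i in range(n):
            edges.add(_edge(i, (i + offset) % n))
    return Network(n_nodes=n, edges=edges)


def rewire(
    network: Network, rewiring_prob: float, rng: np.random.Generator
) -> Network:
    """Watts–Strogatz rewiring of a fresh ring lattice.

    Each lattice edge (i, i+offset) is independently rewired with probability
    ``rewiring_prob``: the clockwise endpoint i+offset is detached and node i
    reattached to a uniformly random node, redrawing on self-loops and
    duplicates so the edge count is preserved. Edges are visited in the
    lattice order (offset-major, then node index), matching the original
    construction, so a given generator state yields one definite network.

    Raises
    ------
    ValueError
        If the input is not a complete ring lattice (a lattice edge missing).
    """
    if not 0.0 <= rewiring_prob <= 1.0:
        raise ValueError("rewiring_prob must lie in [0, 1]")
    n = network.n_nodes
    if network.n_edges % n == 0:
        k = 2 * network.n_edges // n
    else:
        raise ValueError("input must be a freshly generated ring lattice")
    edges = set(network.edges)
    for offset in range(1, k // 2 + 1):
        for i in range(n):
            old = _edge(i, (i + offset) % n)
            if old not in edges:
                raise ValueError("input must be a freshly generated ring lattice")
            if rewiring_prob == 0.0 or rng.random() >= rewiring_prob:
                continue
            if len(edges) >= n - 1 and _node_saturated(edges, i, n):
                continue  # node i already linked to everyone else
            edges.discard(old)
            while True:
                target = int(rng.integers(n))
                if target != i and _edge(i, target) not in edges:
                    break
            edges.add(_edge(i, target))
    return Network(n_nodes=n, edges=edges)


def _node_saturated(edges: set[tuple[int, int]], i: int, n: int) -> bool:
    deg = sum(1 for e in edges if i in e)
    return deg >= n - 1


def generate_small_world(config: SmallWorldConfig) -> Network:
    """Lattice plus seeded rewiring in one call."""
    rng = np.random.default_rng(config.seed)
    return rewire(generate_ring_lattice(config), config.rewiring_prob, rng)


def generate_correlated_scores(
    config: ScoreFieldConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Smooth initial-score field on the ring.

    Gaussian white noise is smoothed by a circular moving average of window
    ``smoothness``, rescaled to unit marginal variance, then shifted and
    scaled: ``score = offset + amplitude * z``. Adjacent nodes share
    ``smoothness - 1`` noise terms, so their correlation is strictly positive
    for any window above 1; negative scores therefore arrive in contiguous
    runs whose typical length grows with the window.

    With the default auto-calibrated offset, the shift is the realization's
    own ``anti_fraction_target`` quantile, pinning the negative share to the
    target up to rounding; an explicit ``mean_level`` applies that fixed
    offset instead.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, w = config.n_nodes, config.smoothness
    noise = rng.standard_normal(n)
    if w > 1:
        ext = np.concatenate([noise, noise[: w - 1]])
        z = np.convolve(ext, np.full(w, 1.0 / w), mode="valid") * np.sqrt(w)
    else:
        z = noise
    if config.mean_level is None and config.amplitude > 0:
        shift = -config.amplitude * float(np.quantile(z, config.anti_fraction_target))
    else:
        shift = config.resolved_mean_level
    return shift + config.amplitude * z


def write_edge_list(network: Network) -> str:
    """Serialise a network as sorted tab-separated 0-based index pairs."""
    lines = [f"#n_nodes={network.n_nodes}"]
    lines.extend(f"{u}\t{v}" for u, v in sorted(network.edges))
    return "\n".join(lines) + "\n"


def read_edge_list(text: str | Iterable[str]) -> Network:
    """Parse the edge-list format written by :func:`write_edge_list`.

    Raises ``ValueError`` on malformed lines, self-loops, duplicates, or
    out-of-range indices.
    """
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = list(text)
    n_nodes: int | None = None
    edges: set[tuple[int, int]] = set()
    raw_pairs: list[tuple[int, int]] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#n_nodes="):
                n_nodes = int(line.removeprefix("#n_nodes="))
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected two tab-separated indices")
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer node index") from exc
        if u == v:
            raise ValueError(f"line {lineno}: self-loop at node {u}")
        e = _edge(u, v)
        if e in edges:
            raise ValueError(f"line {lineno}: duplicate edge {e}")
        edges.add(e)
        raw_pairs.append(e)
    if n_nodes is None:
        if not edges:
            raise ValueError("empty edge list without a #n_nodes header")
        n_nodes = max(max(e) for e in edges) + 1
    return Network(n_nodes=n_nodes, edges=edges)
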