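"""Synthetic temporal contact networks with tunable concurrency.

The generator builds a temporal network in three stages that mirror how
sexual-contact and proximity data are structured:

1. **Topology** — a configuration-model simple graph whose degrees are drawn
   i.i.d. from a truncated power law p(k) proportional to k^-gamma on
   [k_min, k_max].  Stub matching rejects self- and multi-edges; after
   10^4 consecutive failed attempts the remaining stubs are deleted (a
   logged event, not an error), so realised degrees can fall slightly short
   of the drawn ones.
2. **Activity intervals** — each edge is active during one interval of
   duration mu*T whose start is uniform on [0, (1-mu)*T].  The overlap
   parameter mu in (0, 1] controls how much partnerships are concurrent:
   mu = 1 makes every partnership span the whole sampling time.
3. **Contact times** — L = contacts_per_edge * M contacts in total, bursty
   within each edge: interevent gaps are drawn i.i.d. from a truncated power
   law p(D) proportional to D^-beta on [D_min, D_max], accumulated, and
   rescaled affinely into the edge's activity interval (integer timesteps;
   coincident rounded times are kept as distinct contacts).

Defaults follow a sparse, heavy-tailed regime: N = 5,000, gamma = 2.2,
k in [1, N-1], beta = 2, gaps in [1, 10^4], 10 contacts per edge on average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .contacts import ContactSequence

__all__ = [
    "SyntheticConfig",
    "SyntheticRealization",
    "sample_degrees",
    "truncated_power_law_pmf",
    "configuration_model",
    "assign_intervals",
    "sample_interevents",
    "generate",
    "generate_detailed",
]

GIVE_UP = 10_000  # consecutive failed stub matches before deleting leftovers


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs.

    ``mu`` is the overlap (concurrency) parameter; ``T`` the sampling span in
    timesteps; ``contacts_per_edge`` the mean number of contacts per edge.
    ``k_max=None`` means N - 1.
    """

    N: int = 5000
    gamma: float = 2.2
    k_min: int = 1
    k_max: Optional[int] = None
    beta: float = 2.0
    delta_min: int = 1
    delta_max: int = 10_000
    mu: float = 0.5
    contacts_per_edge: int = 10
    T: int = 100_000
    rng_seed: int = 0

    def __post_init__(self):
        kmax = self.N - 1 if self.k_max is None else self.k_max
        if not (self.gamma > 1 and self.beta > 1):
            raise ValueError("gamma and beta must exceed 1")
        if not (1 <= self.k_min <= kmax <= self.N - 1):
            raise ValueError(f"need 1 <= k_min <= k_max <= N-1, got "
                             f"[{self.k_min}, {kmax}] with N={self.N}")
        if self.delta_min > self.delta_max or self.delta_min < 1:
            raise ValueError("need 1 <= delta_min <= delta_max")
        if not 0 < self.mu <= 1:
            raise ValueError(f"mu must be in (0, 1], got {self.mu}")
        if self.contacts_per_edge < 1 or self.T < 1:
            raise ValueError("contacts_per_edge and T must be positive")

    @property
    def k_max_effective(self) -> int:
        return self.N - 1 if self.k_max is None else self.k_max


@dataclass(frozen=True)
class SyntheticRealization:
    """A generated temporal network plus its intermediate stages."""

    contacts: ContactSequence
    graph: nx.Graph
    intervals: dict[tuple[int, int], tuple[float, float]]
    drawn_degrees: np.ndarray
    leftover_stubs: int
    config: SyntheticConfig
    time_origin: int = 0
    """Raw time of the first emitted contact; the canonical sequence shifts
    times by this amount, so ``t + time_origin`` is in interval coordinates."""


def _truncated_power_law(rng: np.random.Generator, exponent: float,
                         lo: int, hi: int, size: int) -> np.ndarray:
    """Integer draws with a truncated power-law shape on [lo, hi].

    A continuous variate x with density proportional to x^-exponent on
    [lo, hi + 1) is drawn by inverse transform and floored, giving the pmf
    P(k) = (k^a - (k+1)^a) / (lo^a - (hi+1)^a) with a = 1 - exponent, which
    is proportional to k^-exponent for large k.  (The fully discrete zeta
    form p(k) ~ k^-exponent gives a markedly lighter tail at these exponents
    and does not reproduce the edge counts this generator is meant to hit.)
    """
    if lo == hi:
        return np.full(size, lo, dtype=np.int64)
    a = 1.0 - exponent
    u = rng.random(size)
    x = ((1.0 - u) * float(lo) ** a + u * float(hi + 1) ** a) ** (1.0 / a)
    return np.minimum(np.floor(x).astype(np.int64), hi)


def truncated_power_law_pmf(exponent: float, lo: int, hi: int) -> np.ndarray:
    """Exact pmf of :func:`_truncated_power_law` on the support [lo, hi]."""
    a = 1.0 - exponent
    k = np.arange(lo, hi + 2, dtype=float)
    cdf = k ** a
    p = cdf[:-1] - cdf[1:]
    return p / p.sum()


def sample_degrees(config: SyntheticConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """I.i.d. degrees from p(k) ~ k^-gamma on [k_min, k_max]."""
    return _truncated_power_law(rng, config.gamma, config.k_min,
                                config.k_max_effective, config.N)


def configuration_model(degrees: np.ndarray,
                        rng: np.random.Generator) -> tuple[nx.Graph, int]:
    """Uniform stub matching into a simple graph.

    Repeatedly draws two remaining stubs uniformly at random and joins them
    unless that would create a self-edge or duplicate an existing edge.
    After ``GIVE_UP`` consecutive failures the remaining stubs are deleted.
    Returns the graph and the number of deleted stubs; realised degrees are
    pointwise <= the requested ones.
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    if len(degrees) == 0:
        raise ValueError("empty degree sequence")
    stubs = np.repeat(np.arange(len(degrees)), degrees)
    rng.shuffle(stubs)
    n_stubs = len(stubs)
    edge_set: set[int] = set()
    n = len(degrees)
    failures = 0
    g = nx.Graph()
    g.add_nodes_from(range(n))
    while n_stubs >= 2 and failures < GIVE_UP:
        a = int(rng.integers(n_stubs))
        b = int(rng.integers(n_stubs))
        if a == b:
            failures += 1
            continue
        u, v = int(stubs[a]), int(stubs[b])
        if u == v:
            failures += 1
            continue
        if u > v:
            u, v = v, u
        key = u * n + v
        if key in edge_set:
            failures += 1
            continue
        edge_set.add(key)
        g.add_edge(u, v)
        # remove the two matched stubs by swapping them to the tail
        hi_idx, lo_idx = (a, b) if a > b else (b, a)
        stubs[hi_idx] = stubs[n_stubs - 1]
        n_stubs -= 1
        stubs[lo_idx] = stubs[n_stubs - 1]
        n_stubs -= 1
        failures = 0
    return g, n_stubs


def assign_intervals(edges, mu: float, T: float,
                     rng: np.random.Generator) -> dict:
    """One activity interval (a, a + mu*T) per edge, start uniform on
    [0, (1 - mu) * T]."""
    if not 0 < mu <= 1:
        raise ValueError(f"mu must be in (0, 1], got {mu}")
    edges = list(edges)
    starts = rng.uniform(0.0, (1.0 - mu) * T, size=len(edges))
    return {tuple(e): (float(a), float(a + mu * T))
            for e, a in zip(edges, starts)}


def sample_interevents(count: int, beta: float, delta_min: int,
                       delta_max: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. interevent gaps from p(D) ~ D^-beta on [delta_min, delta_max]."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if not (1 <= delta_min <= delta_max):
        raise ValueError("need 1 <= delta_min <= delta_max")
    if count == 0:
        return np.empty(0, dtype=np.int64)
    return _truncated_power_law(rng, beta, delta_min, delta_max, count)


def _edge_contact_times(count: int, interval: tuple[float, float],
                        config: SyntheticConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Bursty contact times for one edge, confined to its interval."""
    a, b = interval
    if count == 1:
        return np.array([round(rng.uniform(a, b))], dtype=np.int64)
    gaps = sample_interevents(count - 1, config.beta, config.delta_min,
                              config.delta_max, rng)
    s = np.concatenate(([0], np.cumsum(gaps))).astype(float)
    times = a + s / s[-1] * (b - a)
    return np.rint(times).astype(np.int64)


def generate_detailed(config: SyntheticConfig) -> SyntheticRealization:
    """Run the full three-stage generator and keep intermediate products."""
    rng = np.random.default_rng(config.rng_seed)
    degrees = sample_degrees(config, rng)
    graph, leftover = configuration_model(degrees, rng)
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    m = len(edges)
    if m == 0:
        raise RuntimeError("configuration model produced no edges")
    intervals = assign_intervals(edges, config.mu, config.T, rng)
    total = config.contacts_per_edge * m
    # every edge gets >= 1 contact; the remainder is split near-evenly at
    # random so the total is exactly contacts_per_edge * M
    extra = rng.multinomial(total - m, np.full(m, 1.0 / m))
    counts = 1 + extra
    rows = []
    for e, c in zip(edges, counts.tolist()):
        times = _edge_contact_times(c, intervals[e], config, rng)
        rows.extend((str(e[0]), str(e[1]), int(t)) for t in times)
    cs = ContactSequence.from_triples(rows)
    origin = min(r[2] for r in rows)
    return SyntheticRealization(contacts=cs, graph=graph,
                                intervals=intervals, drawn_degrees=degrees,
                                leftover_stubs=leftover, config=config,
                                time_origin=origin)


def generate(config: SyntheticConfig) -> ContactSequence:
    """Generate a synthetic contact sequence (see module docstring)."""
    return generate_detailed(config).contacts
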