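"""Static-network diagnostics and the degree-preserving null model.

Degree, coreness, largest-component fraction S, mean intra-component
distance d, and a sequential edge-swap randomisation that preserves the
degree sequence exactly while destroying all other structure.  ``S`` is
measured against the constructed network's own vertex set, which for an
optimised representation need not coincide with the individuals of the
original contact data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO

import networkx as nx
import numpy as np

__all__ = [
    "NetworkSummary",
    "degree",
    "coreness",
    "components",
    "mean_distance",
    "rewire_null",
    "null_summary",
    "summarize",
    "write_summary",
]


@dataclass(frozen=True)
class NetworkSummary:
    """Flat summary of one static network, with null-model references.

    ``s0``/``d0`` are means over degree-preserving randomisations, with
    standard deviations ``s0_sd``/``d0_sd`` (subscript-0 convention).
    """

    n: int
    m: int
    s: float
    d: float
    s0: float | None = None
    s0_sd: float | None = None
    d0: float | None = None
    d0_sd: float | None = None


def degree(net: nx.Graph) -> dict:
    """Number of neighbors of each vertex."""
    return dict(net.degree())


def coreness(net: nx.Graph) -> dict:
    """k-core index: the largest k such that the vertex survives iterative
    removal of all vertices of degree < k."""
    return nx.core_number(net)


def components(net: nx.Graph) -> tuple[float, set]:
    """Fraction S of vertices in the largest connected component, and that
    component's vertex set."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    largest = max(nx.connected_components(net), key=len)
    return len(largest) / net.number_of_nodes(), set(largest)


def mean_distance(net: nx.Graph) -> float:
    """Mean shortest-path length over unordered vertex pairs of the largest
    connected component."""
    _, largest = components(net)
    if len(largest) < 2:
        raise ValueError("largest component has a single vertex: d undefined")
    sub = net.subgraph(largest)
    total = 0
    for _, dists in nx.all_pairs_shortest_path_length(sub):
        total += sum(dists.values())
    n = len(largest)
    return total / (n * (n - 1))  # each unordered pair counted twice


def rewire_null(net: nx.Graph, rng_seed: int | np.random.Generator = 0,
                max_retries: int = 10_000, strict: bool = False) -> nx.Graph:
    """One degree-preserving randomisation of ``net``.

    Goes sequentially through all edge positions; for the edge (i, j) at each
    position, draws a random partner edge (i', j') and, with equal
    probability, replaces the two edges by (i, j') and (i', j) or by
    (i, i') and (j, j').  A replacement that would create a self-edge or a
    multi-edge causes a fresh partner to be drawn.  After ``max_retries``
    failed draws for one position the edge is left in place (with
    ``strict=True`` this raises instead); a rigid graph such as K_n therefore
    maps to itself.  The degree sequence is preserved exactly.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    edges = [tuple(e) for e in net.edges()]
    if len(edges) < 2:
        raise ValueError("rewiring needs at least 2 edges")
    edge_set = {frozenset(e) for e in edges}
    m = len(edges)
    for pos in range(m):
        a, b = edges[pos]
        done = False
        for _ in range(max_retries):
            other = int(rng.integers(m))
            if other == pos:
                continue
            c, d = edges[other]
            if rng.integers(2):
                new1, new2 = (a, d), (c, b)
            else:
                new1, new2 = (a, c), (b, d)
            if new1[0] == new1[1] or new2[0] == new2[1]:
                continue
            f1, f2 = frozenset(new1), frozenset(new2)
            if f1 == f2:
                continue
            old1, old2 = frozenset((a, b)), frozenset((c, d))
            if {f1, f2} == {old1, old2}:
                continue  # a replacement must produce new edges
            remaining = edge_set - {old1, old2}
            if f1 in remaining or f2 in remaining:
                continue
            edge_set = remaining | {f1, f2}
            edges[pos] = new1
            edges[other] = new2
            done = True
            break
        if not done and strict:
            raise RuntimeError(
                f"no valid swap found for edge {edges[pos]} in "
                f"{max_retries} attempts"
            )
    out = nx.Graph()
    out.add_nodes_from(net.nodes())
    out.add_edges_from(edges)
    return out


def null_summary(net: nx.Graph, n_reps: int = 10_000,
                 rng_seed: int = 0) -> tuple[float, float, float, float]:
    """Null-model reference values (S_0 +/- sd, d_0 +/- sd) over ``n_reps``
    independent degree-preserving randomisations."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    s_vals = np.empty(n_reps)
    d_vals = np.empty(n_reps)
    for r in range(n_reps):
        rewired = rewire_null(net, rng)
        s_vals[r], _ = components(rewired)
        d_vals[r] = mean_distance(rewired)
    sd = (lambda x: float(np.std(x, ddof=1))) if n_reps > 1 else (lambda x: 0.0)
    return float(s_vals.mean()), sd(s_vals), float(d_vals.mean()), sd(d_vals)


def summarize(net: nx.Graph, n_reps: int = 0, rng_seed: int = 0) -> NetworkSummary:
    """NetworkSummary of a static network; null-model columns when n_reps > 0."""
    s, _ = components(net)
    d = mean_distance(net)
    if n_reps > 0:
        s0, s0_sd, d0, d0_sd = null_summary(net, n_reps, rng_seed)
        return NetworkSummary(net.number_of_nodes(), net.number_of_edges(),
                              s, d, s0, s0_sd, d0, d0_sd)
    return NetworkSummary(net.number_of_nodes(), net.number_of_edges(), s, d)


def write_summary(summary: NetworkSummary, sink: IO[str] | str) -> None:
    """Key-value table mirroring the usual N / M / S / S_0 / d / d_0 rows."""
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_summary(summary, fh)
        return
    rows = [("N", summary.n), ("M", summary.m), ("S", summary.s),
            ("d", summary.d)]
    if summary.s0 is not None:
        rows += [("S_0", summary.s0), ("S_0_sd", summary.s0_sd),
                 ("d_0", summary.d0), ("d_0_sd", summary.d0_sd)]
    for key, val in rows:
        sink.write(f"{key}\t{val:.6g}\n" if isinstance(val, float)
                   else f"{key}\t{val}\n")
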