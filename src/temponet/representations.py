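"""Static-network representations of a temporal contact sequence.

Three ways of collapsing a contact sequence into a simple undirected graph:

* **time-slice** — an edge for every pair with a contact inside a closed
  window [t_start, t_stop]; the full window [0, T] gives the *accumulated*
  (aggregated) network.
* **ongoing** — the network of concurrent partnerships: an edge for every
  pair with one contact strictly before t_start and another strictly after
  t_stop, i.e. a relationship that straddles the window.
* **exponential-threshold** — every contact at time t adds a weight
  e^(-t/tau) to its pair (time counted from the data's first contact); the
  pair is an edge when its accumulated weight exceeds the threshold Omega.
  As tau -> infinity the weight of a pair tends to its contact count, so
  thresholding at Omega = n - 1/2 recovers "pairs with >= n contacts".

All outputs are :class:`networkx.Graph` objects whose nodes are the original
vertex labels; only vertices incident to at least one representation edge
are included (isolated vertices are handled downstream during evaluation).
Window endpoints are closed for the time slice and strict for the ongoing
network — the two definitions genuinely differ on the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO

import networkx as nx
import numpy as np

from .contacts import ContactSequence

__all__ = [
    "WindowParams",
    "ExpThreshParams",
    "time_slice",
    "ongoing",
    "exp_threshold_weights",
    "exp_threshold",
    "accumulated",
    "write_edgelist",
    "read_edgelist",
]


@dataclass(frozen=True)
class WindowParams:
    """A time window [t_start, t_stop] in the data's native time units."""

    t_start: float
    t_stop: float

    def __post_init__(self):
        if self.t_start > self.t_stop:
            raise ValueError(f"t_start={self.t_start} > t_stop={self.t_stop}")

    @staticmethod
    def from_fractions(f_start: float, f_stop: float, T: float) -> "WindowParams":
        """Window given as fractions of the total sampling time T."""
        return WindowParams(f_start * T, f_stop * T)


@dataclass(frozen=True)
class ExpThreshParams:
    """Decay time tau and threshold Omega of the exponential-threshold net."""

    tau: float
    omega: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")


def _graph_from_pairs(cs: ContactSequence, ii: np.ndarray, jj: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(
        (cs.labels[a], cs.labels[b]) for a, b in zip(ii.tolist(), jj.tolist())
    )
    return g


def time_slice(cs: ContactSequence, p: WindowParams) -> nx.Graph:
    """Pairs with at least one contact t_start <= t <= t_stop (closed)."""
    mask = (cs.t >= p.t_start) & (cs.t <= p.t_stop)
    return _graph_from_pairs(cs, cs.i[mask], cs.j[mask])


def accumulated(cs: ContactSequence) -> nx.Graph:
    """The aggregated network: every pair with at least one contact."""
    return time_slice(cs, WindowParams(0, cs.T))


def ongoing(cs: ContactSequence, p: WindowParams) -> nx.Graph:
    """Concurrent partnerships: contacts strictly before t_start AND strictly
    after t_stop."""
    keys = cs._pair_keys()
    before = np.unique(keys[cs.t < p.t_start])
    after = np.unique(keys[cs.t > p.t_stop])
    both = np.intersect1d(before, after, assume_unique=True)
    return _graph_from_pairs(cs, both // cs.N, both % cs.N)


def exp_threshold_weights(cs: ContactSequence, tau: float) -> dict[tuple[str, str], float]:
    """Per-pair weight w_ij = sum over contacts of e^(-t/tau).

    Times are measured from the data's first contact (t = 0 after the
    canonical shift), so an early contact contributes close to 1 and later
    contacts exponentially less.  Pairs with no contact are absent.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    keys = cs._pair_keys()
    uniq, inv = np.unique(keys, return_inverse=True)
    w = np.zeros(len(uniq))
    np.add.at(w, inv, np.exp(-cs.t / tau))
    out: dict[tuple[str, str], float] = {}
    for key, weight in zip(uniq.tolist(), w.tolist()):
        a, b = cs.labels[key // cs.N], cs.labels[key % cs.N]
        out[(a, b)] = weight
    return out


def exp_threshold(cs: ContactSequence, p: ExpThreshParams) -> nx.Graph:
    """Pairs whose exponential weight strictly exceeds Omega."""
    weights = exp_threshold_weights(cs, p.tau)
    g = nx.Graph()
    g.add_edges_from(pair for pair, w in weights.items() if w > p.omega)
    return g


# ---------------------------------------------------------------------------
# Static-network I/O
# ---------------------------------------------------------------------------

def write_edgelist(net: nx.Graph, sink: IO[str] | str) -> None:
    """Two-column edge list, canonical pair order, sorted — deterministic."""
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_edgelist(net, fh)
        return
    rows = sorted(tuple(sorted((str(u), str(v)))) for u, v in net.edges())
    for a, b in rows:
        sink.write(f"{a}\t{b}\n")


def read_edgelist(source: IO[str] | str) -> nx.Graph:
    """Read a two-column edge list written by :func:`write_edgelist`."""
    if isinstance(source, str):
        with open(source) as fh:
            return read_edgelist(fh)
    g = nx.Graph()
    for line in source:
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        a, b = text.split()
        g.add_edge(a, b)
    return g
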