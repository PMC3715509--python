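"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (per-row recounts, exhaustive
enumeration, hand-rolled BFS / peeling / ranking) and shares no code with
the package under test.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


# -- contact bookkeeping ----------------------------------------------------

def recount(rows):
    """(N, L, M, T) recomputed directly from raw (i, j, t) rows."""
    vertices = set()
    pairs = set()
    times = []
    for a, b, t in rows:
        vertices.update((a, b))
        pairs.add(frozenset((a, b)))
        times.append(t)
    return len(vertices), len(rows), len(pairs), max(times) - min(times)


def interevent_oracle(rows):
    """Pooled per-pair successive time differences, brute force."""
    by_pair = {}
    for a, b, t in rows:
        by_pair.setdefault(frozenset((a, b)), []).append(t)
    out = []
    for times in by_pair.values():
        times.sort()
        out.extend(t2 - t1 for t1, t2 in zip(times, times[1:]))
    return sorted(out)


# -- static representations -------------------------------------------------

def slice_oracle(rows, t0, t_start, t_stop):
    """Edges of the time slice by filtering every contact (times from t0)."""
    return {frozenset((a, b)) for a, b, t in rows
            if t_start <= t - t0 <= t_stop}


def ongoing_oracle(rows, t0, t_start, t_stop):
    """Pairs with a contact strictly before t_start and strictly after
    t_stop (per-pair min/max straddle)."""
    by_pair = {}
    for a, b, t in rows:
        by_pair.setdefault(frozenset((a, b)), []).append(t - t0)
    return {p for p, ts in by_pair.items()
            if min(ts) < t_start and max(ts) > t_stop}


def exp_weight_oracle(rows, t0, tau):
    """Per-pair exponential weights by direct per-contact summation."""
    w = {}
    for a, b, t in rows:
        key = frozenset((a, b))
        w[key] = w.get(key, 0.0) + np.exp(-(t - t0) / tau)
    return w


# -- temporal SIR -----------------------------------------------------------

def reachability_oracle(rows, seed):
    """Ever-infected set for lam=1, delta > T, distinct timestamps.

    Forward closure over time-ordered contacts: a vertex infected at time t
    transmits at every later contact it takes part in.
    """
    t_first = min(t for a, b, t in rows if seed in (a, b))
    infected = {seed: t_first}
    for a, b, t in sorted(rows, key=lambda r: r[2]):
        if a in infected and infected[a] <= t and b not in infected:
            infected[b] = t
        elif b in infected and infected[b] <= t and a not in infected:
            infected[a] = t
    return set(infected)


def exact_expected_size(rows, seed, lam, delta):
    """Exact E[outbreak size] by enumerating all tie orders and coin flips.

    Only feasible for a handful of contacts; contacts sharing a timestep are
    averaged over every permutation (uniform tie order), and each
    infective-susceptible contact branches on transmit / not-transmit.
    """
    t_first = min(t for a, b, t in rows if seed in (a, b))
    groups = {}
    for row in sorted(rows, key=lambda r: r[2]):
        groups.setdefault(row[2], []).append(row)

    def walk(seq, k, inf_t):
        if k == len(seq):
            return float(len(inf_t))
        a, b, t = seq[k]
        a_act = a in inf_t and inf_t[a] <= t < inf_t[a] + delta
        b_act = b in inf_t and inf_t[b] <= t < inf_t[b] + delta
        if a_act and b not in inf_t:
            other = b
        elif b_act and a not in inf_t:
            other = a
        else:
            return walk(seq, k + 1, inf_t)
        expect = 0.0
        if lam > 0:
            expect += lam * walk(seq, k + 1, {**inf_t, other: t})
        if lam < 1:
            expect += (1 - lam) * walk(seq, k + 1, inf_t)
        return expect

    orderings = list(itertools.product(
        *[itertools.permutations(g) for g in groups.values()]))
    total = 0.0
    for combo in orderings:
        seq = [row for group in combo for row in group]
        total += walk(seq, 0, {seed: t_first})
    return total / len(orderings)


# -- static network statistics ----------------------------------------------

def spearman_oracle(x, y):
    """Mid-rank assignment by hand, then the Pearson formula."""
    def midranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    return float(np.corrcoef(rx, ry)[0, 1])


def coreness_oracle(adj):
    """k-core indices by literal repeated peeling.  ``adj``: dict v -> set."""
    adj = {v: set(nb) for v, nb in adj.items()}
    core = {}
    k = 0
    while adj:
        while True:
            low = [v for v, nb in adj.items() if len(nb) <= k]
            if not low:
                break
            for v in low:
                core[v] = k
                for nb in adj[v]:
                    adj[nb].discard(v)
                del adj[v]
        k += 1
    return core


def components_oracle(adj):
    """Connected components by union-find."""
    parent = {v: v for v in adj}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for v, nbrs in adj.items():
        for u in nbrs:
            parent[find(u)] = find(v)
    comps = {}
    for v in adj:
        comps.setdefault(find(v), set()).add(v)
    return sorted(comps.values(), key=len, reverse=True)


def mean_distance_oracle(adj):
    """All-pairs BFS average distance within the largest component."""
    largest = components_oracle(adj)[0]
    total = 0
    count = 0
    for src in largest:
        dist = {src: 0}
        queue = deque([src])
        while queue:
            v = queue.popleft()
            for u in adj[v]:
                if u not in dist:
                    dist[u] = dist[v] + 1
                    queue.append(u)
        for v in largest:
            if v != src:
                total += dist[v]
                count += 1
    return total / count


def graph_adj(net):
    """Adjacency dict of a networkx graph (isolates included)."""
    return {v: set(net.neighbors(v)) for v in net.nodes()}
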