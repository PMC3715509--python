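from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from temponet import ContactSequence

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_rows(rng, n_vertices=10, n_contacts=50, t_max=100,
                distinct_times=False):
    """Raw (label, label, t) rows of a random temporal network."""
    if distinct_times:
        assert n_contacts <= t_max + 1
        times = rng.choice(t_max + 1, size=n_contacts, replace=False)
    else:
        times = rng.integers(0, t_max + 1, size=n_contacts)
    rows = []
    for t in times.tolist():
        a, b = rng.choice(n_vertices, size=2, replace=False)
        rows.append((f"v{a}", f"v{b}", int(t)))
    return rows


@pytest.fixture
def random_cs(rng):
    return ContactSequence.from_triples(random_rows(rng))


def planted_clique_sequence(sizes=range(2, 21), rounds=(0, 1),
                            pollution_start=90, T=100):
    """Temporal network where importance is monotone in early-window degree.

    Disjoint cliques of the given sizes meet completely in each early round;
    at lam=1 with a short infective period the expected outbreak size of any
    vertex is exactly its clique size.  Late "pollution" contacts wire one
    member of each clique to a member of the smallest clique, degrading the
    accumulated network's degrees without ever transmitting (every candidate
    recipient was infected and removed long before).  A time slice covering
    only the early rounds therefore scores rho = 1.

    Returns (rows, signal_stop): contacts plus the native time up to which
    the planted signal extends.
    """
    rows = []
    members = []
    base = 0
    for s in sizes:
        clique = [f"c{base + k}" for k in range(s)]
        members.append(clique)
        base += s
        for t in rounds:
            for x in range(s):
                for y in range(x + 1, s):
                    rows.append((clique[x], clique[y], t))
    hub = members[0][0]  # a vertex of the smallest clique
    for offset, clique in enumerate(members[1:]):
        t = pollution_start + offset % (T - pollution_start)
        rows.append((hub, clique[0], int(t)))
    return rows, max(rounds)
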