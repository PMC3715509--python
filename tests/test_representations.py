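import io
import math

import numpy as np
import pytest

from temponet import (
    ContactSequence,
    ExpThreshParams,
    WindowParams,
    accumulated,
    exp_threshold,
    exp_threshold_weights,
    ongoing,
    read_edgelist,
    time_slice,
    write_edgelist,
)

from conftest import random_rows
from oracles import exp_weight_oracle, ongoing_oracle, slice_oracle


def edges(net):
    return {frozenset(e) for e in net.edges()}


@pytest.fixture
def triangle_cs():
    return ContactSequence.from_triples(
        [("a", "b", 0), ("b", "c", 5), ("a", "c", 9)])


class TestTimeSlice:
    def test_direct_filter(self, triangle_cs):
        net = time_slice(triangle_cs, WindowParams(0, 5))
        assert edges(net) == {frozenset("ab"), frozenset("bc")}

    def test_full_window_equals_accumulated(self, random_cs):
        full = time_slice(random_cs, WindowParams(0, random_cs.T))
        assert edges(full) == edges(accumulated(random_cs))
        assert {frozenset(e) for e in full.edges()} == \
            {frozenset((random_cs.labels[a], random_cs.labels[b]))
             for a, b in random_cs.pairs}

    def test_random_windows_match_oracle(self, rng):
        rows = random_rows(rng, n_vertices=20, n_contacts=500, t_max=300)
        cs = ContactSequence.from_triples(rows)
        t0 = min(r[2] for r in rows)
        for _ in range(20):
            a, b = sorted(rng.uniform(0, cs.T, size=2))
            net = time_slice(cs, WindowParams(a, b))
            assert edges(net) == slice_oracle(rows, t0, a, b)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            WindowParams(5, 2)


class TestOngoing:
    def test_strict_straddle(self):
        cs = ContactSequence.from_triples([("a", "b", 0), ("a", "b", 9)])
        assert edges(ongoing(cs, WindowParams(3, 5))) == {frozenset("ab")}
        # a single contact inside the window is not an ongoing partnership
        cs2 = ContactSequence.from_triples([("a", "b", 4), ("c", "d", 0)])
        assert edges(ongoing(cs2, WindowParams(3, 5))) == set()

    def test_degenerate_window_single_instant(self):
        cs = ContactSequence.from_triples(
            [("a", "b", 0), ("a", "b", 9), ("b", "c", 4), ("b", "c", 5)])
        net = ongoing(cs, WindowParams(4, 4))
        # pairs with contacts strictly before and strictly after t = 4
        assert edges(net) == {frozenset("ab")}

    def test_boundary_contacts_excluded(self):
        cs = ContactSequence.from_triples([("a", "b", 3), ("a", "b", 5), ("x", "y", 0)])
        assert edges(ongoing(cs, WindowParams(3, 5))) == set()

    def test_random_windows_match_oracle(self, rng):
        rows = random_rows(rng, n_vertices=12, n_contacts=400, t_max=200)
        cs = ContactSequence.from_triples(rows)
        t0 = min(r[2] for r in rows)
        for _ in range(20):
            a, b = sorted(rng.uniform(0, cs.T, size=2))
            assert edges(ongoing(cs, WindowParams(a, b))) == \
                ongoing_oracle(rows, t0, a, b)


class TestExpThreshold:
    def test_analytic_single_contact_weights(self):
        cs = ContactSequence.from_triples([("a", "b", 0), ("c", "d", 7)])
        w = exp_threshold_weights(cs, tau=7.0)
        assert w[("a", "b")] == pytest.approx(1.0)
        assert w[("c", "d")] == pytest.approx(math.exp(-1), rel=1e-12)

    def test_threshold_on_analytic_weights(self):
        cs = ContactSequence.from_triples([("a", "b", 0), ("c", "d", 7)])
        net = exp_threshold(cs, ExpThreshParams(tau=7.0, omega=0.5))
        assert edges(net) == {frozenset("ab")}

    def test_weights_match_summation_oracle(self, rng):
        rows = random_rows(rng, n_vertices=10, n_contacts=100, t_max=50)
        cs = ContactSequence.from_triples(rows)
        t0 = min(r[2] for r in rows)
        tau = 13.7
        w = exp_threshold_weights(cs, tau)
        oracle = exp_weight_oracle(rows, t0, tau)
        assert set(map(frozenset, w)) == set(oracle)
        for pair, val in w.items():
            assert val == pytest.approx(oracle[frozenset(pair)], rel=1e-12)

    def test_random_params_match_thresholded_oracle(self, rng):
        rows = random_rows(rng, n_vertices=10, n_contacts=200, t_max=100)
        cs = ContactSequence.from_triples(rows)
        t0 = min(r[2] for r in rows)
        for _ in range(10):
            tau = float(rng.uniform(1, 200))
            omega = float(rng.uniform(0.01, 5))
            net = exp_threshold(cs, ExpThreshParams(tau, omega))
            oracle = exp_weight_oracle(rows, t0, tau)
            assert edges(net) == {p for p, v in oracle.items() if v > omega}

    def test_aggregated_threshold_limit(self, rng):
        # tau >> T: weights tend to contact counts, so Omega = n - 1/2
        # keeps exactly the pairs with >= n contacts
        rows = random_rows(rng, n_vertices=8, n_contacts=120, t_max=60)
        cs = ContactSequence.from_triples(rows)
        counts = {}
        for a, b, _ in rows:
            counts[frozenset((a, b))] = counts.get(frozenset((a, b)), 0) + 1
        for n in (1, 2, 3):
            net = exp_threshold(cs, ExpThreshParams(tau=1e6 * cs.T,
                                                    omega=n - 0.5))
            assert edges(net) == {p for p, c in counts.items() if c >= n}

    @pytest.mark.parametrize("tau", [0.0, -1.0])
    def test_invalid_tau_rejected(self, triangle_cs, tau):
        with pytest.raises(ValueError):
            exp_threshold_weights(triangle_cs, tau)


class TestInvariantsAndProperties:
    def test_window_monotonicity(self, rng):
        rows = random_rows(rng, n_vertices=15, n_contacts=300, t_max=150)
        cs = ContactSequence.from_triples(rows)
        inner = WindowParams(0.3 * cs.T, 0.6 * cs.T)
        outer = WindowParams(0.1 * cs.T, 0.8 * cs.T)
        assert edges(time_slice(cs, inner)) <= edges(time_slice(cs, outer))
        assert edges(ongoing(cs, outer)) <= edges(ongoing(cs, inner))

    def test_omega_monotonicity(self, rng):
        rows = random_rows(rng, n_vertices=15, n_contacts=300, t_max=150)
        cs = ContactSequence.from_triples(rows)
        low = exp_threshold(cs, ExpThreshParams(tau=0.3 * cs.T, omega=0.2))
        high = exp_threshold(cs, ExpThreshParams(tau=0.3 * cs.T, omega=1.0))
        assert edges(high) <= edges(low)

    def test_nesting_in_accumulated(self, rng):
        rows = random_rows(rng, n_vertices=15, n_contacts=300, t_max=150)
        cs = ContactSequence.from_triples(rows)
        acc = edges(accumulated(cs))
        p = WindowParams(0.2 * cs.T, 0.7 * cs.T)
        assert edges(time_slice(cs, p)) <= acc
        assert edges(ongoing(cs, p)) <= acc

    def test_accumulated_collapses_multiedges(self):
        cs = ContactSequence.from_triples(
            [("a", "b", t) for t in range(10)])
        assert accumulated(cs).number_of_edges() == 1

    def test_relabeling_commutes(self, rng):
        rows = random_rows(rng, n_vertices=10, n_contacts=100, t_max=80)
        relabeled = [(a.replace("v", "x"), b.replace("v", "x"), t)
                     for a, b, t in rows]
        cs1 = ContactSequence.from_triples(rows)
        cs2 = ContactSequence.from_triples(relabeled)
        p = WindowParams(0.2 * cs1.T, 0.8 * cs1.T)
        mapped = {frozenset(x.replace("v", "x") for x in e)
                  for e in edges(time_slice(cs1, p))}
        assert mapped == edges(time_slice(cs2, p))


class TestEdgelistIO:
    def test_round_trip_and_determinism(self, rng):
        rows = random_rows(rng, n_vertices=12, n_contacts=80)
        net = accumulated(ContactSequence.from_triples(rows))
        buf = io.StringIO()
        write_edgelist(net, buf)
        again = read_edgelist(io.StringIO(buf.getvalue()))
        assert edges(again) == edges(net)
        buf2 = io.StringIO()
        write_edgelist(again, buf2)
        assert buf.getvalue() == buf2.getvalue()
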