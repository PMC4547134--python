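import math

import networkx as nx
import numpy as np
import pytest

from colonynet.events import (
    FunctionalClass,
    NestTransitEvent,
    ObservationWindow,
    ValidationError,
)
from colonynet.static_nets import build_static_network
from colonynet.synth import generate_colony, scenario
from colonynet.temporal import (
    TemporalNetwork,
    audit_report,
    build_temporal_network,
    earliest_arrival,
    queen_transmission_audit,
    spread_analysis,
)
from conftest import ev, make_roster
from oracles import temporal_reach_bruteforce


def tnet(contacts, extra_nodes=()):
    net = TemporalNetwork(colony="C1", night=1, contacts=sorted(contacts, key=lambda c: c[2]))
    net.nodes.update(extra_nodes)
    return net


class TestBuild:
    def test_contacts_sorted_by_start_time(self):
        events = [ev("A", "B", 50, 60), ev("B", "C", 10, 20)]
        net = build_temporal_network(events)
        assert [t for _, _, t in net.contacts] == [10, 50]

    def test_end_rule_shifts_stamps(self):
        events = [ev("A", "B", 50, 60)]
        assert build_temporal_network(events, rule="end").contacts[0][2] == 60

    def test_empty_event_list(self):
        net = build_temporal_network([], colony="C1", night=1)
        assert net.contacts == [] and net.n_nodes == 0

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            build_temporal_network([], rule="middle")


class TestEarliestArrival:
    def test_forward_chain(self):
        net = tnet([("A", "B", 100.0), ("B", "C", 200.0)])
        assert earliest_arrival(net, "A") == {"A": 0.0, "B": 100.0, "C": 200.0}

    def test_out_of_order_contacts_do_not_relay(self):
        net = tnet([("B", "C", 100.0), ("A", "B", 200.0)])
        arrival = earliest_arrival(net, "A")
        assert "C" not in arrival

    def test_simultaneous_contacts_relay_with_le_rule(self):
        net = tnet([("A", "B", 100.0), ("B", "C", 100.0)])
        assert earliest_arrival(net, "A")["C"] == 100.0
        # and independently of input order within the same timestamp
        net2 = tnet([("B", "C", 100.0), ("A", "B", 100.0)])
        assert earliest_arrival(net2, "A")["C"] == 100.0

    def test_unknown_source_rejected(self):
        with pytest.raises(ValidationError):
            earliest_arrival(tnet([("A", "B", 1.0)]), "Z")

    def test_matches_bruteforce_reachability_on_random_instances(self, rng):
        for _ in range(30):
            n_nodes, n_contacts = 6, 12
            contacts = [
                (f"n{rng.integers(n_nodes)}", f"n{rng.integers(n_nodes)}",
                 float(rng.integers(0, 5) * 10))
                for _ in range(n_contacts)
            ]
            contacts = [(a, b, t) for a, b, t in contacts if a != b]
            net = tnet(contacts, extra_nodes=[f"n{i}" for i in range(n_nodes)])
            reached = set(earliest_arrival(net, "n0"))
            assert reached == temporal_reach_bruteforce(contacts, "n0")

    def test_time_reversal_maps_forward_to_backward_reachability(self, rng):
        """Forward reach from A in the time-reversed network equals the
        set of nodes that can reach A in the original."""
        for _ in range(15):
            contacts = [
                (f"n{rng.integers(5)}", f"n{rng.integers(5)}",
                 float(rng.integers(1, 6) * 10))
                for _ in range(10)
            ]
            contacts = [(a, b, t) for a, b, t in contacts if a != b]
            nodes = [f"n{i}" for i in range(5)]
            T = 100.0
            reversed_contacts = sorted(
                [(a, b, T - t) for a, b, t in contacts], key=lambda c: c[2]
            )
            rev = tnet(reversed_contacts, extra_nodes=nodes)
            fwd_from_A_rev = set(earliest_arrival(rev, "n0"))
            can_reach_A = {
                v
                for v in nodes
                if "n0" in temporal_reach_bruteforce(contacts, v)
            }
            assert fwd_from_A_rev == can_reach_A


class TestSpread:
    def test_chain_fractions_step_by_one_ant(self):
        contacts = [(f"x{i}", f"x{i+1}", 100.0 * (i + 1)) for i in range(4)]
        net = tnet(contacts)
        res = spread_analysis(
            net, n_seeds=1, interval_s=100.0, window_s=400.0, rng=0,
            eligible=["x0"],
        )[0]
        assert res.fraction_reached == pytest.approx([0.2, 0.4, 0.6, 0.8, 1.0])

    def test_isolated_seed_stays_at_one_over_n(self):
        net = tnet([("A", "B", 10.0)], extra_nodes=["iso"])
        res = spread_analysis(
            net, n_seeds=1, interval_s=100.0, window_s=300.0, rng=0,
            eligible=["iso"],
        )[0]
        assert all(f == pytest.approx(1 / 3) for f in res.fraction_reached)

    def test_simultaneous_complete_contacts_saturate_at_first_grid_point(self):
        contacts = [("A", "B", 0.0), ("B", "C", 0.0), ("A", "C", 0.0)]
        net = tnet(contacts)
        for seed in "ABC":
            res = spread_analysis(
                net, n_seeds=1, interval_s=100.0, window_s=200.0, rng=0,
                eligible=[seed],
            )[0]
            assert res.fraction_reached[0] == 1.0

    def test_fractions_monotone_and_bounded(self, small_colony):
        roster = small_colony.roster
        for night in (1, 2):
            events = [e for e in small_colony.events if e.night == night]
            net = build_temporal_network(
                events, colony="C1", night=night,
                extra_nodes=list(roster.classes_for("C1", night)),
            )
            results = spread_analysis(net, roster, n_seeds=10, rng=night)
            for r in results:
                f = r.fraction_reached
                assert f[0] >= 1 / net.n_nodes - 1e-12
                assert all(b >= a for a, b in zip(f, f[1:]))
                assert f[-1] <= 1.0

    def test_reached_set_within_static_component(self, small_colony):
        roster = small_colony.roster
        events = [e for e in small_colony.events if e.night == 2]
        static = build_static_network(
            events, roster, ObservationWindow("C1", 2, 1200.0)
        )
        net = build_temporal_network(events, colony="C1", night=2)
        for seed in sorted(net.nodes)[:10]:
            reached = set(earliest_arrival(net, seed))
            component = nx.node_connected_component(static, seed)
            assert reached <= component

    def test_oversampling_seeds_rejected(self):
        net = tnet([("A", "B", 10.0)])
        with pytest.raises(ValidationError):
            spread_analysis(net, n_seeds=5, rng=0)


class TestQueenAudit:
    ROSTER = make_roster(
        "C1", 1, {"F1": "AF", "N1": "NW", "N2": "NW", "Q1": "Q"}
    )
    WINDOW = ObservationWindow("C1", 1, 1200.0)

    def _transits(self, *times):
        out = []
        for i, t in enumerate(times):
            out.append(
                NestTransitEvent(
                    "C1", 1, "F1", t, "enter" if i % 2 == 0 else "exit"
                )
            )
        return out

    def test_two_hop_chain_after_entry_detected(self):
        transits = self._transits(500.0)
        events = [ev("F1", "N1", 600.0, 620.0), ev("N1", "Q1", 700.0, 710.0)]
        paths = queen_transmission_audit(events, transits, self.ROSTER, self.WINDOW)
        assert len(paths) == 1
        assert len(paths[0].chain) == 2
        assert paths[0].chain[-1][2] == 700.0

    def test_queen_contact_before_entry_is_safe(self):
        transits = self._transits(500.0)
        events = [ev("N1", "Q1", 400.0, 420.0), ev("F1", "N1", 600.0, 620.0)]
        paths = queen_transmission_audit(events, transits, self.ROSTER, self.WINDOW)
        assert paths == []

    def test_direct_contact_after_entry_is_a_length_one_chain(self):
        transits = self._transits(500.0)
        events = [ev("F1", "Q1", 550.0, 580.0)]
        paths = queen_transmission_audit(events, transits, self.ROSTER, self.WINDOW)
        assert len(paths) == 1
        assert len(paths[0].chain) == 1
        report = audit_report(paths)
        assert report["n_chains"] == 1
        assert not report["temporally_segregated"]

    def test_queen_sequestered_scenario_is_temporally_segregated(self):
        """The scenario that confines queen contacts to before any
        forager returns reproduces the empirical finding: zero
        time-respecting forager-to-queen chains."""
        data = generate_colony(scenario("queen_sequestered", seed=2))
        total = []
        for colony in ("C1", "C2"):
            for night in range(1, 9):
                w = ObservationWindow(colony, night, 1200.0)
                events = [
                    e for e in data.events
                    if e.colony == colony and e.night == night
                ]
                total.extend(
                    queen_transmission_audit(
                        events, data.transits, data.roster, w
                    )
                )
        assert total == []
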