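import math

import numpy as np
import pytest

from colonynet.events import ValidationError
from colonynet.movement import (
    CTDSModel,
    CTDSRecords,
    CTDSSpec,
    GridSpec,
    MovementTrack,
    build_ctds_records,
    ctds_loglik,
    movement_contrasts,
    read_tracks,
    residence_map,
    simulate_ctds,
    spatial_spread_index,
    write_tracks,
)
from conftest import make_roster
from oracles import trajectory_loglik


@pytest.fixture(scope="module")
def grid():
    return GridSpec.paper_like()


@pytest.fixture(scope="module")
def small_grid():
    return GridSpec.single_chamber(3, 3, queen_cell=(0, 0))


def track(visits, ant="a1", night=1, window=1200.0):
    return MovementTrack(
        colony="C1", night=night, ant=ant, visits=visits, window_s=window
    )


class TestGrid:
    def test_paper_like_has_63_cells_in_4_chambers(self, grid):
        assert grid.n_cells == 63
        assert len({grid.chamber(c) for c in grid.cells}) == 4

    def test_chambers_communicate_only_through_passages(self, grid):
        cross = [
            (a, b)
            for a in grid.cells
            for b in grid.neighbors(a)
            if grid.chamber(a) != grid.chamber(b)
        ]
        assert len(cross) == 2 * len(grid.passages)

    def test_queen_distance_is_geodesic(self, grid):
        assert grid.distance_to_queen(grid.queen_cell) == 0
        for c in grid.cells:
            d = grid.distance_to_queen(c)
            assert math.isfinite(d)
            if c != grid.queen_cell:
                assert any(
                    grid.distance_to_queen(nb) == d - 1 for nb in grid.neighbors(c)
                )

    def test_json_round_trip(self, grid, tmp_path):
        p = tmp_path / "grid.json"
        grid.to_json(p)
        g2 = GridSpec.from_json(p)
        assert g2.chambers == grid.chambers
        assert g2.queen_cell == grid.queen_cell
        assert {frozenset(e) for e in g2.passages} == {
            frozenset(e) for e in grid.passages
        }


class TestResidence:
    def test_single_ant_single_cell_full_window(self, small_grid):
        rmap = residence_map([track([((1, 1), 0.0)])], small_grid)
        assert rmap["all"][(1, 1)] == pytest.approx(1200.0)

    def test_two_ants_accumulate(self, small_grid):
        tracks = [
            track([((1, 1), 0.0), ((1, 2), 600.0)], ant="a1"),
            track([((1, 1), 0.0), ((0, 1), 600.0)], ant="a2"),
        ]
        rmap = residence_map(tracks, small_grid)
        assert rmap["all"][(1, 1)] == pytest.approx(1200.0)

    def test_ant_day_conversion(self, small_grid):
        tracks = [
            track([((1, 1), 0.0)], ant=f"a{i}", window=86_400.0 / 4)
            for i in range(4)
        ]
        rmap = residence_map(tracks, small_grid, ant_days=True)
        assert rmap["all"][(1, 1)] == pytest.approx(1.0)

    def test_total_residence_conserves_tracked_time(self, small_colony):
        grid = small_colony.config.grid
        rmap = residence_map(small_colony.tracks, grid, small_colony.roster)
        total = sum(s for acc in rmap.values() for s in acc.values())
        assert total == pytest.approx(
            sum(t.tracked_seconds for t in small_colony.tracks)
        )

    def test_visit_outside_grid_rejected(self, small_grid):
        with pytest.raises(ValidationError):
            residence_map([track([((9, 9), 0.0)])], small_grid)

    def test_spread_index_counts_occupied_fraction(self, grid):
        rmap = {"g": {c: 5.0 for c in grid.cells[:21]}}
        idx = spatial_spread_index(rmap, grid)
        assert idx["g"] == pytest.approx(21 / 63)
        assert spatial_spread_index({"e": {}}, grid)["e"] == 0.0
        full = {"f": {c: 1.0 for c in grid.cells}}
        assert spatial_spread_index(full, grid)["f"] == 1.0

    def test_tracks_csv_round_trip(self, tmp_path, small_colony):
        p = tmp_path / "tracks.csv"
        write_tracks(small_colony.tracks, p)
        back = read_tracks(p)
        key = lambda t: (t.colony, t.night, t.ant)
        orig = sorted(small_colony.tracks, key=key)
        assert [t.visits for t in back] == [t.visits for t in orig]


class TestRecords:
    def test_interior_visit_yields_one_record_per_neighbour(self, small_grid):
        tr = track([((1, 1), 0.0), ((0, 1), 100.0)], window=100.0 + 50.0)
        rec = build_ctds_records([tr], small_grid, spec=CTDSSpec.intercept_only())
        first = rec.meta.visit == 0
        assert int(first.sum()) == 4  # center cell of a 3x3 grid
        assert rec.y[first.to_numpy()].sum() == 1.0
        assert np.all(rec.exposure[first.to_numpy()] == 100.0)

    def test_final_visit_censored_to_window_end(self, small_grid):
        tr = track([((0, 0), 0.0)], window=77.0)
        rec = build_ctds_records([tr], small_grid, spec=CTDSSpec.intercept_only())
        assert rec.n_moves == 0
        assert np.all(rec.exposure == 77.0)
        assert rec.n_records == 2  # corner cell has two neighbours

    def test_non_adjacent_jump_excluded(self, small_grid):
        tr = track([((0, 0), 0.0), ((2, 2), 100.0)], window=200.0)
        rec = build_ctds_records([tr], small_grid, spec=CTDSSpec.intercept_only())
        # the gap visit is dropped; only the final (2,2) visit remains
        assert set(rec.meta.visit) == {1}


class TestLikelihood:
    def test_closed_form_single_record(self):
        rec = CTDSRecords(
            Z=np.array([[1.0]]), exposure=np.array([2.0]), y=np.array([0.0]),
            param_names=["log_rate"],
            meta=__import__("pandas").DataFrame({"ant": ["a"], "group": ["g"], "visit": [0]}),
        )
        assert ctds_loglik(np.array([0.0]), rec) == pytest.approx(-2.0)
        rec.y[0] = 1.0
        assert ctds_loglik(np.array([0.0]), rec) == pytest.approx(-2.0)
        assert ctds_loglik(np.array([-40.0]), rec) < -30.0

    def test_intercept_only_mle_matches_closed_form(self, small_grid, rng):
        beta = np.array([math.log(0.02)])
        tracks = [
            simulate_ctds(beta, small_grid, 600.0, (1, 1), rng,
                          spec=CTDSSpec.intercept_only(), ant=f"a{i}")
            for i in range(5)
        ]
        rec = build_ctds_records(tracks, small_grid, spec=CTDSSpec.intercept_only())
        res = CTDSModel(rec).fit()
        closed_form = rec.n_moves / rec.exposure.sum()
        assert math.exp(res.params[0]) == pytest.approx(closed_form, rel=1e-8)

    def test_ten_moves_over_fifty_exposure_gives_rate_point_two(self):
        import pandas as pd

        # 10 visits, each with one neighbour, exposure 5, all moving
        rec = CTDSRecords(
            Z=np.ones((10, 1)), exposure=np.full(10, 5.0), y=np.ones(10),
            param_names=["log_rate"],
            meta=pd.DataFrame({"ant": ["a"] * 10, "group": ["g"] * 10,
                               "visit": range(10)}),
        )
        res = CTDSModel(rec).fit()
        assert math.exp(res.params[0]) == pytest.approx(10 / 50.0, rel=1e-8)

    def test_poisson_form_equals_trajectory_likelihood_up_to_constant(
        self, small_grid, rng
    ):
        spec = CTDSSpec(
            per_group_intercepts=True, queen_chamber_by_group=True,
            toward_queen=True, toward_queen_by_group=True,
        )
        beta = np.array([-3.5, -3.0, -5.0, 0.4, 0.0, 0.1, -0.2])
        tracks = [
            simulate_ctds(beta, small_grid, 400.0, (1, 1), rng, group=g,
                          spec=spec, ant=f"{g}{i}")
            for i in range(3)
            for g in ("forager", "nest_worker")
        ]
        roster = make_roster(
            "sim", 1,
            {f"forager{i}": "AF" for i in range(3)}
            | {f"nest_worker{i}": "NW" for i in range(3)},
        )
        rec = build_ctds_records(tracks, small_grid, roster, spec)

        def oracle_ll(b):
            return sum(
                trajectory_loglik(
                    b, t.visits, t.window_s, small_grid,
                    "forager" if t.ant.startswith("forager") else "nest_worker",
                    spec,
                )
                for t in tracks
            )

        b2 = beta + rng.normal(0, 0.3, size=beta.size)
        diff_impl = ctds_loglik(b2, rec) - ctds_loglik(beta, rec)
        diff_oracle = oracle_ll(b2) - oracle_ll(beta)
        assert diff_impl == pytest.approx(diff_oracle, abs=1e-8)

    def test_zero_moves_is_an_error(self, small_grid):
        tr = track([((0, 0), 0.0)], window=10.0)
        rec = build_ctds_records([tr], small_grid, spec=CTDSSpec.intercept_only())
        with pytest.raises(ValidationError):
            CTDSModel(rec).fit()

    def test_optimum_independent_of_start(self, small_grid, rng):
        beta = np.array([math.log(0.01)])
        tracks = [
            simulate_ctds(beta, small_grid, 600.0, (0, 0), rng,
                          spec=CTDSSpec.intercept_only(), ant=f"a{i}")
            for i in range(4)
        ]
        rec = build_ctds_records(tracks, small_grid, spec=CTDSSpec.intercept_only())
        fits = [
            CTDSModel(rec).fit(start=np.array([s])).params[0]
            for s in (-8.0, -4.0, -1.0, 0.5, 2.0)
        ]
        assert np.ptp(fits) < 1e-6


class TestSimulate:
    def test_vanishing_rates_leave_the_ant_in_place(self, small_grid, rng):
        tr = simulate_ctds(
            np.array([-60.0]), small_grid, 1200.0, (1, 1), rng,
            spec=CTDSSpec.intercept_only(),
        )
        assert tr.visits == [((1, 1), 0.0)]

    def test_two_cell_grid_long_run_occupancy_is_even(self, rng):
        g = GridSpec.single_chamber(1, 2, queen_cell=(0, 0))
        beta = np.array([math.log(0.05)])
        occ = {(0, 0): 0.0, (0, 1): 0.0}
        for i in range(30):
            tr = simulate_ctds(beta, g, 2000.0, (0, i % 2), rng,
                               spec=CTDSSpec.intercept_only())
            for cell, _, hold in tr.residences():
                occ[cell] += hold
        frac = occ[(0, 0)] / sum(occ.values())
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_doubling_rates_halves_mean_holding(self, small_grid, rng):
        def mean_holding(log_rate, seed):
            r = np.random.default_rng(seed)
            holds = []
            for i in range(40):
                tr = simulate_ctds(
                    np.array([log_rate]), small_grid, 3000.0, (1, 1), r,
                    spec=CTDSSpec.intercept_only(),
                )
                holds.extend(h for _, _, h in tr.residences()[:-1])
            return np.mean(holds)

        slow = mean_holding(math.log(0.01), 5)
        fast = mean_holding(math.log(0.02), 5)
        assert fast == pytest.approx(slow / 2, rel=0.15)


class TestContrasts:
    def test_identical_tracks_give_null_contrasts(self, grid):
        roster = make_roster(
            "C1", 1,
            {"F1": "AF", "F2": "IF", "N1": "NW", "N2": "NW"},
        )
        visits = [((1, 1), 0.0), ((1, 2), 300.0), ((1, 1), 600.0)]
        tracks = [track(visits, ant=a) for a in ("F1", "F2", "N1", "N2")]
        tab = movement_contrasts(tracks, roster, grid).set_index("contrast")
        row = tab.loc["overall_mobility"]
        assert row.t == pytest.approx(0.0)
        assert row.p == pytest.approx(1.0)

    def test_ants_never_near_queen_excluded_from_modulation(self, grid):
        roster = make_roster(
            "C1", 1, {"F1": "AF", "F2": "IF", "N1": "NW", "N2": "NW"}
        )
        # all ants stay in chamber 0 (queen is in chamber 3)
        visits = [((1, 1), 0.0), ((1, 2), 300.0)]
        tracks = [track(visits, ant=a) for a in ("F1", "F2", "N1", "N2")]
        tab = movement_contrasts(tracks, roster, grid).set_index("contrast")
        row = tab.loc["queen_chamber_modulation"]
        assert "skipped" in row.note

    def test_queen_chamber_speedup_detected_with_high_power(self, grid):
        """Foragers simulated with an e^0.7 queen-chamber rate boost are
        flagged by the modulation contrast at alpha = 0.01 in >= 80% of
        replicates at study-like sample sizes."""
        spec = CTDSSpec()
        beta = np.array(
            [math.log(1 / 240), math.log(1 / 120), -8.0, 0.7, 0.0, 0.0, 0.0]
        )
        roster_map = {f"F{i}": ("AF" if i % 2 else "IF") for i in range(5)}
        roster_map.update({f"N{i}": "NW" for i in range(5)})
        n_detected = 0
        n_reps = 60
        for rep in range(n_reps):
            r = np.random.default_rng(1000 + rep)
            roster = None
            tracks = []
            for night in range(1, 17):  # 2 colonies x 8 nights equivalent
                for ant, short in roster_map.items():
                    g = "forager" if short in ("AF", "IF") else "nest_worker"
                    start = grid.cells[r.integers(grid.n_cells)]
                    tracks.append(
                        simulate_ctds(beta, grid, 1200.0, start, r, group=g,
                                      spec=spec, colony="C1", night=night, ant=ant)
                    )
            from colonynet.events import ClassRoster
            roster = ClassRoster()
            from conftest import SHORT
            for night in range(1, 17):
                for ant, short in roster_map.items():
                    roster.assignments[("C1", night, ant)] = SHORT[short]
            tab = movement_contrasts(tracks, roster, grid).set_index("contrast")
            row = tab.loc["queen_chamber_modulation"]
            if row.p < 0.01 and row.t > 0:
                n_detected += 1
        assert n_detected / n_reps >= 0.8
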