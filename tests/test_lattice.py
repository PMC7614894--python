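"""Lattice mechanics: geometry validation, division push-up, relocation
swaps, exact event statistics and structural invariants of the simulator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cryptdrift as cd
from cryptdrift import _kernels
from cryptdrift.errors import ConfigurationError, SimulationError


class TestGeometry:
    def test_defaults_match_crypt_measurements(self):
        g = cd.CryptGeometry()
        assert (g.n_rows, g.cells_per_row) == (8, 5)
        assert g.lgr5_rows == (0, 3)
        assert g.centre_rows == (0, 1) and g.border_rows == (2, 3)
        assert g.n_sites == 40

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cells_per_row": 1},
            {"n_rows": 3},  # does not clear the Lgr5+ band
            {"centre_rows": (0, 2)},  # overlaps border
            {"centre_rows": (0, 0)},  # centre+border do not tile the band
            {"lgr5_rows": (3, 0)},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            cd.CryptGeometry(**kwargs)

    @given(n_extra=st.integers(1, 6), width=st.integers(2, 9))
    def test_any_valid_band_partition_accepted(self, n_extra, width):
        g = cd.CryptGeometry(n_rows=4 + n_extra, cells_per_row=width)
        assert g.n_sites == (4 + n_extra) * width


class TestStateConstruction:
    def test_all_distinct_gives_unique_label_per_site(self, geom):
        s = cd.build_homeostatic_state(geom, "all-distinct")
        assert s.mode == "homeostasis"
        assert len(np.unique(s.grid)) == 40

    def test_single_label_is_monoclonal_over_any_band(self, geom):
        s = cd.build_homeostatic_state(geom, "single-label")
        assert s.is_monoclonal()
        assert s.is_monoclonal((0, 7))

    def test_rates(self, geom, si):
        s = cd.build_homeostatic_state(geom)
        assert cd.total_event_rate(s, si) == pytest.approx(40 * (1.4 + 2.8))
        assert cd.total_event_rate(s, cd.KineticParams(1.4, 0.0)) == pytest.approx(56.0)
        cd.ablate(s, (0, 7))
        assert cd.total_event_rate(s, si) == 0.0

    def test_operations_on_vacant_site_rejected(self, geom, rng):
        s = cd.build_homeostatic_state(geom)
        cd.ablate(s, (0, 3))
        with pytest.raises(SimulationError):
            cd.apply_division(s, (0, 0), rng)
        with pytest.raises(SimulationError):
            cd.apply_relocation(s, (2, 1), rng)


class TestDivision:
    def test_conservation_one_duplicated_one_lost(self, geom, rng):
        s = cd.build_homeostatic_state(geom, "all-distinct")
        before = np.sort(s.grid.ravel())
        cd.apply_division(s, (0, 2), rng)
        after = s.grid.ravel()
        assert s.n_occupied == 40
        gained = np.setdiff1d(before, after)
        counts = np.bincount(after, minlength=40)
        assert (counts == 2).sum() == 1  # one label duplicated
        assert gained.size == 1  # one former top-row label pushed out

    def test_insertion_above_moves_clone_upward(self, geom):
        s = cd.build_homeostatic_state(geom, "single-label")
        s.grid[0, 2] = 1  # clone confined to row 0
        _kernels._division_at(s.grid, 0, 2, 2)  # choice 2 = directly above
        assert s.row_counts(1).tolist()[:2] == [1, 1]

    def test_daughter_above_top_row_exits_immediately(self, geom):
        s = cd.build_homeostatic_state(geom, "all-distinct")
        before = s.grid.copy()
        exited, nr, _ = _kernels._division_at(s.grid, 7, 0, 2)
        assert nr == 8 and exited == before[7, 0]
        assert (s.grid == before).all()

    def test_orientation_uniform_over_three_neighbours(self, geom, rng):
        counts = {(-1): 0, (+1): 0, "up": 0}
        base = cd.build_homeostatic_state(geom, "all-distinct")
        for _ in range(6000):
            s = base.copy()
            cd.apply_division(s, (3, 2), rng)
            dup = np.flatnonzero(np.bincount(s.grid.ravel(), minlength=40) == 2).item()
            sites = [tuple(map(int, rc)) for rc in np.argwhere(s.grid == dup)]
            (r, c) = next(rc for rc in sites if rc != (3, 2))  # the daughter
            if (r, c) == (4, 2):
                counts["up"] += 1
            else:
                counts[c - 2] += 1
        for v in counts.values():
            assert abs(v / 6000 - 1 / 3) < 4 * np.sqrt((1 / 3) * (2 / 3) / 6000)


class TestRelocation:
    def test_down_swap_is_retrograde(self, geom):
        s = cd.build_homeostatic_state(geom, "all-distinct")
        lab = s.grid[1, 3]
        _kernels._relocation_at(s.grid, 1, 3, 3)  # choice 3 = down
        assert s.grid[0, 3] == lab

    def test_neighbour_choice_uniform_at_interior_site(self, geom, rng):
        hits = {}
        base = cd.build_homeostatic_state(geom, "all-distinct")
        lab = base.grid[3, 2]
        for _ in range(8000):
            s = base.copy()
            cd.apply_relocation(s, (3, 2), rng)
            pos = tuple(map(int, np.argwhere(s.grid == lab)[0]))
            hits[pos] = hits.get(pos, 0) + 1
        assert set(hits) == {(3, 1), (3, 3), (4, 2), (2, 2)}
        for v in hits.values():
            assert abs(v / 8000 - 0.25) < 4 * np.sqrt(0.25 * 0.75 / 8000)

    def test_bottom_row_has_no_down_neighbour(self, geom, rng):
        base = cd.build_homeostatic_state(geom, "all-distinct")
        lab = base.grid[0, 0]
        seen = set()
        for _ in range(500):
            s = base.copy()
            cd.apply_relocation(s, (0, 0), rng)
            seen.add(tuple(map(int, np.argwhere(s.grid == lab)[0])))
        assert seen == {(0, 4), (0, 1), (1, 0)}


class TestSimulate:
    def test_zero_duration_returns_input_snapshot(self, geom, si, rng):
        s = cd.build_homeostatic_state(geom)
        snaps, events = cd.simulate(s, si, 0.0, rng=rng)
        assert len(snaps) == 1 and events == []
        assert (snaps[0][1].grid == s.grid).all()

    def test_negative_duration_rejected(self, geom, si, rng):
        s = cd.build_homeostatic_state(geom)
        with pytest.raises(ConfigurationError):
            cd.simulate(s, si, -1.0, rng=rng)

    def test_no_relocation_events_when_kr_zero(self, geom, rng):
        s = cd.build_homeostatic_state(geom)
        _, events = cd.simulate(
            s, cd.KineticParams(1.4, 0.0), 10.0, rng=rng, log_events=True
        )
        assert events and all(e.kind == "division" for e in events)

    def test_deterministic_conveyor_rows_never_decrease(self, geom, rng):
        # with k_r = 0 the only movements are upward pushes, so the minimum
        # row of every surviving lineage is non-decreasing
        s = cd.build_homeostatic_state(geom, "all-distinct")
        snaps, _ = cd.simulate(
            s, cd.KineticParams(1.4, 0.0), 20.0, record_times=np.arange(0, 21, 2.0), rng=rng
        )
        prev = {}
        for _, snap in snaps:
            current = {
                int(lab): int(np.argwhere(snap.grid == lab)[:, 0].min())
                for lab in snap.labels()
            }
            for lab, row in current.items():
                if lab in prev:
                    assert row >= prev[lab]
            prev = current

    def test_mean_event_count_matches_total_rate(self, geom, si, rng):
        # 40 cells x 4.2 events/cell/day x 56 days = 9408 expected events
        s = cd.build_homeostatic_state(geom)
        _, events = cd.simulate(s, si, 56.0, rng=rng, log_events=True)
        assert abs(len(events) - 9408) < 5 * np.sqrt(9408)

    def test_snapshots_fully_occupied_in_homeostasis(self, si, rng):
        s = cd.build_homeostatic_state(cd.CryptGeometry(n_rows=5, cells_per_row=3))
        snaps, _ = cd.simulate(s, si, 8.0, record_times=[2, 4, 6, 8], rng=rng)
        for _, snap in snaps:
            assert snap.n_occupied == 15

    def test_export_schemas(self, geom, si, rng):
        s = cd.build_homeostatic_state(geom)
        snaps, events = cd.simulate(s, si, 2.0, record_times=[1, 2], rng=rng, log_events=True)
        sf = cd.snapshots_to_frame(snaps)
        assert list(sf.columns) == ["time", "row", "column", "label"]
        assert len(sf) == 2 * 40
        ef = cd.events_to_frame(events)
        assert list(ef.columns) == [
            "time", "kind", "site_row", "site_col", "target_row", "target_col",
        ]
        # every event target is a lattice neighbour of its site
        dr = (ef.target_row - ef.site_row).abs()
        dc = (ef.target_col - ef.site_col) % 5
        assert (((dr == 0) & dc.isin([1, 4])) | ((dr == 1) & (dc == 0))).all()


class TestStatisticalInvariances:
    def test_cylinder_symmetry_of_retention(self, geom, si):
        # starting column is immaterial on the cylinder
        times = np.array([28.0])
        n = 3000
        fractions = []
        for col in (0, 2):
            seeds = np.random.default_rng(5).integers(0, 2**31 - 1, n)
            counts = _kernels.lineage_batch(
                8, 5,
                np.full(n, 2, dtype=np.int64), np.full(n, col, dtype=np.int64),
                times, si.k_d, si.k_r, seeds,
            )
            fractions.append((counts[:, 0, :4].sum(axis=1) > 0).mean())
        se = np.sqrt(2 * fractions[0] * (1 - fractions[0]) / n)
        assert abs(fractions[0] - fractions[1]) < 4 * max(se, 1e-3)

    def test_rate_rescaling_leaves_retention_unchanged(self, geom, rng):
        # doubling both rates and halving the horizon is a pure change of
        # time units; retention depends only on k_r/k_d
        n = 3000
        out = []
        for params, t in [(cd.KineticParams(1.4, 2.8), 42.0), (cd.KineticParams(2.8, 5.6), 21.0)]:
            obs = cd.run_lineage_tracing(params, geom, [1], n, [t], rng)
            out.append(obs.retained.mean())
        se = np.sqrt(2 * max(out[0], 0.01) * (1 - out[0]) / n)
        assert abs(out[0] - out[1]) < 4 * se

    def test_retention_insensitive_to_lattice_height(self, geom, si, rng):
        # doubling n_rows leaves 8-week retention in the Lgr5+ zone unchanged
        tall = cd.CryptGeometry(n_rows=16)
        n = 2000
        for row in (1, 2):
            vals = []
            for g in (geom, tall):
                obs = cd.run_lineage_tracing(si, g, [row], n, [56.0], rng)
                vals.append(obs.retained.mean())
            se = np.sqrt(2 * max(vals[0], 0.01) * (1 - vals[0]) / n)
            assert abs(vals[0] - vals[1]) < 4 * se
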