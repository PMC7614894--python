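"""Virtual experiments: lineage tracing, compartment scoring, monoclonal
drift, clone fragmentation and ablation recovery."""

import numpy as np
import pandas as pd
import pytest

import cryptdrift as cd
from cryptdrift import experiments as ex
from cryptdrift.errors import (
    ConfigurationError,
    EmptyInputError,
    EstimationError,
    SimulationError,
)


class TestLineageTracing:
    def test_observation_table_schema(self, geom, si, rng):
        obs = ex.run_lineage_tracing(si, geom, [0, 2], 20, [2.0, 14.0], rng, "SI")
        assert set(ex.OBSERVATION_COLUMNS) <= set(obs.columns)
        assert len(obs) == 2 * 20 * 2
        row_cols = [f"cells_row{r}" for r in range(8)]
        assert (obs[row_cols].sum(axis=1) == obs.n_cells).all()
        assert (obs.retained == (obs.in_centre | obs.in_border)).all()

    def test_zero_clones_gives_empty_table(self, geom, si, rng):
        obs = ex.run_lineage_tracing(si, geom, [0, 1], 0, [14.0], rng)
        assert len(obs) == 0 and set(ex.OBSERVATION_COLUMNS) <= set(obs.columns)

    def test_start_row_outside_lattice_rejected(self, geom, si, rng):
        with pytest.raises(ConfigurationError):
            ex.run_lineage_tracing(si, geom, [8], 5, [14.0], rng)

    def test_time_zero_observation_is_the_induced_cell(self, geom, si, rng):
        obs = ex.run_lineage_tracing(si, geom, [3], 10, [0.0], rng)
        assert (obs.n_cells == 1).all()
        assert (obs.cells_row3 == 1).all() and obs.in_border.all()

    def test_retention_gradient_decreases_from_centre_to_border(self, geom, si, rng):
        obs = ex.run_lineage_tracing(si, geom, [0, 1, 2, 3], 1500, [56.0], rng)
        ret = obs.groupby("start_row").retained.mean()
        se = np.sqrt(ret * (1 - ret) / 1500).max()
        assert (np.diff(ret.values) <= 4 * se).all()

    def test_li_gradient_steeper_than_si(self, geom, si, li, rng):
        norms = {}
        for name, p in (("SI", si), ("LI", li)):
            obs = ex.run_lineage_tracing(p, geom, [0, 1, 2, 3], 1500, [56.0], rng)
            ret = obs.groupby("start_row").retained.mean()
            norms[name] = (ret / ret[0]).values
        assert (norms["LI"][1:] < norms["SI"][1:]).all()


class TestCompartmentSummary:
    def _obs(self, rows, centre, border):
        return pd.DataFrame(
            {
                "clone_id": range(len(rows)),
                "condition": "X",
                "start_row": rows,
                "time_days": 3.0,
                "in_centre": centre,
                "in_border": border,
                "retained": np.array(centre) | np.array(border),
                "n_cells": 1,
                "fragmented": False,
            }
        )

    def test_partition_matches_definitions(self, geom):
        # centre-present / border-only / lost partition the outcome space
        obs = self._obs([0, 2, 3], [True, False, False], [False, True, False])
        out = ex.compartment_transition_summary(obs, geom)
        centre = out[out.start_compartment == "centre"].iloc[0]
        assert centre.p_centre == 1.0 and centre.p_lost == 0.0
        border = out[out.start_compartment == "border"].iloc[0]
        assert border.p_border_only == 0.5 and border.p_lost == 0.5

    def test_probabilities_sum_to_one(self, geom, si, rng):
        obs = ex.run_lineage_tracing(si, geom, [0, 1, 2, 3], 100, [2.0, 4.0], rng)
        out = ex.compartment_transition_summary(obs, geom)
        total = out.p_centre + out.p_border_only + out.p_lost
        assert np.allclose(total, 1.0)

    def test_empty_input_rejected(self, geom):
        with pytest.raises(EmptyInputError):
            ex.compartment_transition_summary(pd.DataFrame(), geom)


class TestMonoclonalDrift:
    def test_all_distinct_start_is_polyclonal(self, geom, si, rng):
        series = ex.run_monoclonal_drift(si, geom, 20, [0.0, 7.0], rng)
        assert series.fraction_monoclonal[0] == 0.0
        assert ((series.fraction_monoclonal >= 0) & (series.fraction_monoclonal <= 1)).all()

    def test_large_intestine_converts_faster(self, geom, si, li, rng):
        fs = ex.run_monoclonal_drift(si, geom, 300, [7.0, 14.0], rng).fraction_monoclonal
        fl = ex.run_monoclonal_drift(li, geom, 300, [7.0, 14.0], rng).fraction_monoclonal
        assert (fl > fs).all()

    def test_fixation_certain_without_relocation(self, geom, rng):
        # neutral drift fixes every crypt; fastest in the deterministic
        # conveyor-belt limit
        times = ex.run_monoclonal_conversion_times(
            cd.KineticParams(1.4, 0.0), geom, 50, rng, horizon=200.0
        )
        assert np.isfinite(times).all()

    def test_invalid_band_rejected(self, geom, si, rng):
        with pytest.raises(ConfigurationError):
            ex.run_monoclonal_drift(si, geom, 5, [7.0], rng, monoclonal_band=(0, 9))


class TestFragmentation:
    def _state_with_rows(self, geom, rows):
        s = cd.build_homeostatic_state(geom, "single-label")
        for r in rows:
            s.grid[r, 0] = 1
        return s

    def test_contiguous_clone_not_fragmented(self, geom):
        assert not ex.is_fragmented(self._state_with_rows(geom, [0, 1]), 1)

    def test_row_gap_is_fragmentation(self, geom):
        assert ex.is_fragmented(self._state_with_rows(geom, [0, 2]), 1)

    def test_single_cell_clone_not_fragmented(self, geom):
        assert not ex.is_fragmented(self._state_with_rows(geom, [3]), 1)

    def test_lateral_split_within_one_row_not_counted(self, geom):
        s = cd.build_homeostatic_state(geom, "single-label")
        s.grid[1, 0] = 1
        s.grid[1, 3] = 1
        assert not ex.is_fragmented(s, 1)

    def test_extinct_clone_rejected(self, geom):
        s = cd.build_homeostatic_state(geom, "single-label")
        with pytest.raises(SimulationError):
            ex.is_fragmented(s, 99)

    def test_assay_requires_clones(self, geom, si, rng):
        with pytest.raises(EstimationError):
            ex.run_fragmentation_assay(si, geom, 0, 7.0, rng)

    def test_relocation_increases_fragmentation(self, geom, si, li, rng):
        p_si = ex.run_fragmentation_assay(si, geom, 8000, 7.0, rng).probability
        p_kr0 = ex.run_fragmentation_assay(
            cd.KineticParams(1.4, 0.0), geom, 8000, 7.0, rng
        ).probability
        assert p_si > p_kr0


class TestAblation:
    def test_band_vacated_and_mode_switches(self, geom):
        s = cd.build_homeostatic_state(geom)
        cd.ablate(s, geom.lgr5_rows)
        assert (s.grid[:4] == cd.VACANT).all()
        assert s.n_occupied == 20 and s.mode == "ablation"

    def test_empty_band_is_noop(self, geom):
        s = cd.build_homeostatic_state(geom)
        before = s.grid.copy()
        cd.ablate(s, ())
        assert (s.grid == before).all() and s.mode == "homeostasis"

    def test_double_ablation_idempotent(self, geom):
        s = cd.build_homeostatic_state(geom)
        cd.ablate(s, (0, 3))
        first = s.grid.copy()
        cd.ablate(s, (0, 3))
        assert (s.grid == first).all()

    def test_band_outside_lattice_rejected(self, geom):
        with pytest.raises(ConfigurationError):
            cd.ablate(cd.build_homeostatic_state(geom), (0, 8))

    def test_refill_restores_homeostasis_mode(self, geom, si, rng):
        s = cd.build_homeostatic_state(geom, "single-label")
        cd.ablate(s, (0, 3))
        snaps, _ = cd.simulate(s, si, 40.0, rng=rng)
        assert snaps[0][1].mode == "homeostasis"

    def test_recovery_starts_just_above_the_ablated_band(self, geom, si, rng):
        traj = ex.run_ablation_recovery(si, geom, 30, [0.0], rng)
        assert (traj.lowest_row[:, 0] == 4).all()

    def test_mean_lowest_row_decreases_over_time(self, geom, si, rng):
        traj = ex.run_ablation_recovery(si, geom, 250, [0.5, 1, 2, 4, 7], rng)
        mean = traj.mean_lowest_row
        se = traj.lowest_row.std(axis=0).max() / np.sqrt(250)
        assert (np.diff(mean) <= 4 * se).all()
        assert mean[-1] < mean[0]
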