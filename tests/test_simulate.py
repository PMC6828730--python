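"""Simulator: division law, event bookkeeping, determinism, rendering."""

import numpy as np
import pytest

from cmscreen.platemodel import WellCondition
from cmscreen.simulate import (
    DrugEffect,
    ImagingParams,
    SimulationConfig,
    division_probability,
    expected_fold_change,
    render_boundary_labels,
    render_nuclei_image,
    sample_binucleated_population,
    simulate_screen,
    simulate_well,
    split_tiles,
)

CONTROL = WellCondition(role="control", compound_id="DMSO", plating_density=333.0)


def cfg_with(**kw) -> SimulationConfig:
    kw.setdefault("imaging", ImagingParams(tile_grid=(2, 2), tile_px=200, tile_overlap_px=16))
    kw.setdefault("n_timepoints", 7)
    return SimulationConfig(**kw)


class TestDivisionProbability:
    def test_ramp_endpoints_and_midpoint(self):
        cfg = cfg_with(p_max=0.08, p_confluent=0.02)
        assert division_probability(cfg.d_lo, cfg) == pytest.approx(0.08)
        assert division_probability(cfg.d_hi, cfg) == pytest.approx(0.02)
        mid = (cfg.d_lo + cfg.d_hi) / 2
        assert division_probability(mid, cfg) == pytest.approx((0.08 + 0.02) / 2)

    def test_saturates_outside_knots(self):
        cfg = cfg_with(p_max=0.08, p_confluent=0.02)
        assert division_probability(0.0, cfg) == pytest.approx(cfg.p_max)
        assert division_probability(34.0, cfg) == pytest.approx(cfg.p_max)
        assert division_probability(10 * cfg.d_hi, cfg) == pytest.approx(cfg.p_confluent)

    def test_continuous_and_non_increasing(self):
        cfg = cfg_with(p_max=0.1, p_confluent=0.01)
        dens = np.linspace(0, 800, 400)
        p = np.array([division_probability(d, cfg) for d in dens])
        assert np.all(np.diff(p) <= 1e-12)
        assert np.max(np.abs(np.diff(p))) < 0.01  # no jumps


class TestWellDynamics:
    def test_no_events_means_constant_counts(self):
        cfg = cfg_with(p_max=0.0, p_confluent=0.0)
        sw = simulate_well(CONTROL, cfg, seed=1)
        assert len(set(sw.series.counts.tolist())) == 1

    def test_certain_death_at_onset_zero(self):
        cfg = cfg_with(drug_effects={"X": DrugEffect(death_hazard=1.0, death_onset_h=0.0)})
        cond = WellCondition(role="treated", compound_id="X", concentration_um=10.0,
                             plating_density=333.0)
        sw = simulate_well(cond, cfg, seed=1)
        assert sw.series.counts[0] > 0
        assert np.all(sw.series.counts[1:] == 0)

    def test_delayed_death_spares_earlier_steps(self):
        cfg = cfg_with(p_max=0.0, p_confluent=0.0,
                       drug_effects={"X": DrugEffect(death_hazard=1.0, death_onset_h=24.0)})
        cond = WellCondition(role="treated", compound_id="X", concentration_um=10.0,
                             plating_density=333.0)
        sw = simulate_well(cond, cfg, seed=2)
        assert sw.series.count_at(24.0) == sw.series.count_at(0.0)
        assert sw.series.count_at(36.0) == 0

    def test_forced_binucleation_single_cell(self):
        # one mononucleated cell, certain division, beta=1, one step, no death
        imaging = ImagingParams(tile_grid=(1, 1), tile_px=28)  # tiny arena -> 1 cell
        cfg = SimulationConfig(p_max=1.0, p_confluent=1.0, beta=1.0,
                               initial_binucleated_fraction=0.0,
                               n_timepoints=2, imaging=imaging)
        cond = WellCondition(role="control", compound_id="DMSO",
                             plating_density=1.0 / cfg.imaging.area_mm2)
        sw = simulate_well(cond, cfg, seed=3)
        assert sw.series.counts.tolist() == [1, 2]
        live = [c for c in sw.trajectories if c.alive_at(12.0)]
        assert len(live) == 1 and live[0].nuclei_at(12.0) == 2

    def test_nuclei_bookkeeping_every_step(self):
        cfg = cfg_with(p_max=0.3, p_confluent=0.1, beta=0.3,
                       drug_effects={"X": DrugEffect(death_hazard=0.05)})
        cond = WellCondition(role="treated", compound_id="X", concentration_um=10.0,
                             plating_density=333.0)
        sw = simulate_well(cond, cfg, seed=4)
        for t in sw.series.times_h:
            live = [c for c in sw.trajectories if c.alive_at(t)]
            mono = sum(1 for c in live if c.nuclei_at(t) == 1)
            binu = sum(1 for c in live if c.nuclei_at(t) == 2)
            assert sw.series.count_at(t) == mono + 2 * binu

    def test_determinism_bit_identical(self):
        cfg = cfg_with(p_max=0.2, beta=0.2)
        a = simulate_well(CONTROL, cfg, seed=5)
        b = simulate_well(CONTROL, cfg, seed=5)
        assert np.array_equal(a.series.counts, b.series.counts)
        assert [(c.cell_id, c.x_um, c.y_um, c.birth_h, c.death_h, c.binucleation_h)
                for c in a.trajectories] == [
                   (c.cell_id, c.x_um, c.y_um, c.birth_h, c.death_h, c.binucleation_h)
                   for c in b.trajectories]

    def test_empty_well_has_no_cells(self):
        cfg = cfg_with()
        sw = simulate_well(WellCondition(role="empty", plating_density=0.0), cfg, seed=6)
        assert np.all(sw.series.counts == 0) and not sw.trajectories

    def test_mean_field_oracle_matches_monte_carlo(self):
        cfg = cfg_with(seed=0)
        expected = expected_fold_change(CONTROL, cfg, window=(0.0, 72.0))
        fcs = []
        for s in range(60):
            sw = simulate_well(CONTROL, cfg, seed=900 + s)
            fcs.append(sw.series.count_at(72.0) / sw.series.count_at(0.0))
        sem = np.std(fcs, ddof=1) / np.sqrt(len(fcs))
        assert np.mean(fcs) == pytest.approx(expected, abs=max(5 * sem, 0.01))


class TestScreenSimulation:
    def test_adding_wells_leaves_existing_wells_untouched(self, toy_platemap):
        cfg = cfg_with(p_max=0.2)
        full = simulate_screen(toy_platemap, cfg, n_screens=1, seed=7)[0]
        reduced_map = type(toy_platemap)(
            plate_id="toy", plate_format=384,
            wells={k: v for k, v in toy_platemap.wells.items() if k != "A04"},
        )
        reduced = simulate_screen(reduced_map, cfg, n_screens=1, seed=7)[0]
        for addr in reduced.wells:
            np.testing.assert_array_equal(
                reduced.wells[addr].series.counts, full.wells[addr].series.counts
            )

    def test_screens_are_independent_replicates(self, toy_platemap):
        cfg = cfg_with(p_max=0.2)
        screens = simulate_screen(toy_platemap, cfg, n_screens=2, seed=8)
        assert not np.array_equal(
            screens[0].wells["A01"].series.counts, screens[1].wells["A01"].series.counts
        )

    def test_missing_effect_without_default_errors(self, toy_platemap):
        cfg = cfg_with(default_effect=None, drug_effects={"CMPD-1": DrugEffect()})
        with pytest.raises(KeyError, match="CMPD-2"):
            simulate_screen(toy_platemap, cfg, n_screens=1, seed=9)

    def test_division_multiplier_raises_terminal_counts(self):
        cfg = cfg_with(drug_effects={"X": DrugEffect(division_multiplier=2.0)})
        cond_t = WellCondition(role="treated", compound_id="X", concentration_um=10.0,
                               plating_density=333.0)
        terminal_t, terminal_c = [], []
        for s in range(60):
            terminal_c.append(simulate_well(CONTROL, cfg, seed=3000 + s).series.counts[-1])
            terminal_t.append(simulate_well(cond_t, cfg, seed=6000 + s).series.counts[-1])
        assert np.mean(terminal_t) > np.mean(terminal_c)

    def test_certain_death_after_onset_everywhere(self, toy_platemap):
        cfg = cfg_with(drug_effects={
            "CMPD-1": DrugEffect(death_hazard=1.0, death_onset_h=24.0),
            "CMPD-2": DrugEffect(death_hazard=1.0, death_onset_h=24.0)})
        scr = simulate_screen(toy_platemap, cfg, n_screens=1, seed=10)[0]
        for addr in ("A03", "A04"):
            assert scr.wells[addr].series.count_at(36.0) == 0


class TestDensityAndBinucleationLaws:
    def test_fold_change_non_increasing_with_density(self):
        cfg = cfg_with()
        means = []
        for dens in (136.0, 340.0, 544.0):
            cond = WellCondition(role="control", compound_id="DMSO", plating_density=dens)
            fcs = [
                simulate_well(cond, cfg, seed=s).series.count_at(72.0)
                / simulate_well(cond, cfg, seed=s).series.count_at(0.0)
                for s in range(40)
            ]
            means.append(np.mean(fcs))
        assert means[0] >= means[1] >= means[2]

    def test_binucleation_proportion_density_independent(self):
        cfg = cfg_with(beta=0.15)
        props = []
        for dens in (136.0, 544.0):
            cond = WellCondition(role="control", compound_id="DMSO", plating_density=dens)
            bi = tot = 0
            for s in range(20):
                sw = simulate_well(cond, cfg, seed=400 + s)
                live = [c for c in sw.trajectories if c.alive_at(72.0)]
                bi += sum(1 for c in live if c.nuclei_at(72.0) == 2)
                tot += len(live)
            props.append(bi / tot)
        # both binomial estimates of the same beta; allow 4 pooled sigma
        sigma = np.sqrt(0.15 * 0.85 * 2 / tot)
        assert abs(props[0] - props[1]) < 4 * sigma


class TestRendering:
    def test_zero_nuclei_pure_noise_tile(self):
        cfg = cfg_with()
        tiles, truth = render_nuclei_image([], 0.0, cfg, seed=1)
        assert truth.empty
        img = np.concatenate([t.ravel() for t in tiles.values()])
        assert img.mean() == pytest.approx(cfg.imaging.background_level, rel=0.1)

    def test_single_nucleus_argmax_at_centroid(self):
        from cmscreen.simulate import CellTrajectory, _render_field
        imaging = ImagingParams(tile_grid=(1, 1), tile_px=101, background_level=0.0)
        cfg = SimulationConfig(imaging=imaging)
        cell = CellTrajectory(cell_id=0, x_um=101.0, y_um=101.0)  # pixel (50, 50) center
        tiles, truth = render_nuclei_image([cell], 0.0, cfg)
        img = tiles[(0, 0)]
        assert np.unravel_index(np.argmax(img), img.shape) == (50, 50)

    def test_ground_truth_count_conservation(self):
        cfg = cfg_with()
        cond = WellCondition(role="control", compound_id="DMSO", plating_density=136.0)
        sw = simulate_well(cond, cfg, seed=12)
        _, truth = render_nuclei_image(sw.trajectories, 0.0, cfg, seed=13)
        live_nuclei = sum(c.nuclei_at(0.0) for c in sw.trajectories if c.alive_at(0.0))
        assert len(truth) == live_nuclei  # pre-clipping, off-field rows included

    def test_off_field_nuclei_flagged_not_dropped(self):
        from cmscreen.simulate import CellTrajectory
        cfg = cfg_with()
        cells = [CellTrajectory(cell_id=0, x_um=-50.0, y_um=100.0),
                 CellTrajectory(cell_id=1, x_um=100.0, y_um=100.0)]
        _, truth = render_nuclei_image(cells, 0.0, cfg, seed=1)
        assert len(truth) == 2
        assert truth.set_index("cell_id")["in_field"].to_dict() == {0: False, 1: True}

    def test_boundary_labels_contain_their_nuclei(self):
        cfg = cfg_with(beta=0.3)
        cells = sample_binucleated_population(150, 0.3, cfg, seed=14)
        labels, true_counts, label_to_cell = render_boundary_labels(cells, 0.0, cfg)
        by_id = {c.cell_id: c for c in cells}
        px = cfg.imaging.pixel_size_um
        for lab, cell_id in label_to_cell.items():
            for x, y in by_id[cell_id].nucleus_positions_at(0.0, cfg.imaging.inter_nucleus_um):
                i, j = int(y / px), int(x / px)
                if 0 <= i < labels.shape[0] and 0 <= j < labels.shape[1]:
                    assert labels[i, j] == lab

    def test_mononucleated_history_gives_single_centroid_regions(self):
        cfg = cfg_with(beta=0.0, initial_binucleated_fraction=0.0)
        cells = sample_binucleated_population(100, 0.0, cfg, seed=15)
        _, true_counts, _ = render_boundary_labels(cells, 0.0, cfg)
        assert set(true_counts.values()) == {1}

    def test_tiles_reassemble_to_field(self):
        cfg = cfg_with()
        rng = np.random.default_rng(0)
        h, w = cfg.imaging.field_shape_px
        field = rng.random((h, w))
        tiles = split_tiles(field, cfg.imaging)
        from cmscreen.imaging import stitch_tiles
        np.testing.assert_allclose(
            stitch_tiles(tiles, cfg.imaging.tile_overlap_px), field, atol=1e-12
        )
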