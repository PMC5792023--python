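import numpy as np
import pytest
from scipy import stats

from fociquant.config import ConfigError, SimulationConfig
from fociquant.foci import detect_peaks
from fociquant.sim import (PlacementError, draw_bleach_times,
                           expression_time_course, generate_rapid_acquisition,
                           generate_timelapse, place_molecules, render_frame,
                           replisome_sites_for_cell, simulate_bleaching,
                           simulate_cells, timelapse_times_min,
                           volume_growth_factor, MoleculeSet,
                           STATE_DISPERSED, STATE_FREE, STATE_TIGHT)


class TestExpressionTimeCourse:
    def test_baseline_at_zero(self):
        cfg = SimulationConfig()
        assert expression_time_course(cfg, 0.0) == pytest.approx(20.0)

    def test_plateau(self):
        cfg = SimulationConfig()
        assert expression_time_course(cfg, 180.0) == pytest.approx(280.0)
        assert expression_time_course(cfg, 90.0) == pytest.approx(280.0)

    def test_constant_when_levels_equal(self):
        cfg = SimulationConfig(N_baseline=50.0, N_plateau=50.0)
        t = np.linspace(0, 180, 50)
        assert np.allclose(expression_time_course(cfg, t), 50.0)

    def test_monotone_rise_between_onset_and_plateau(self):
        cfg = SimulationConfig()
        t = np.linspace(0, 180, 361)
        n = expression_time_course(cfg, t)
        assert np.all(np.diff(n) >= -1e-9)
        assert expression_time_course(cfg, 19.9) == pytest.approx(20.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            expression_time_course(SimulationConfig(), -1.0)


class TestSimulateCells:
    def test_growth_disabled_lengths_identical(self):
        cfg = SimulationConfig(field_height_px=160, field_width_px=160,
                               filament_volume_cap=1.0)
        c0 = simulate_cells(cfg, 5, 0.0, seed=1)
        c120 = simulate_cells(cfg, 5, 120.0, seed=1)
        assert [c.length_um for c in c0] == [c.length_um for c in c120]

    def test_volume_inflation_2p5_fold(self):
        cfg = SimulationConfig(field_height_px=600, field_width_px=600)
        v0, v120 = [], []
        for s in range(4):
            for c in simulate_cells(cfg, 50, 0.0, seed=s):
                v0.append(c.volume_fl)
            for c in simulate_cells(cfg, 50, 120.0, seed=s):
                v120.append(c.volume_fl)
        ratio = np.mean(v120) / np.mean(v0)
        assert ratio == pytest.approx(2.5, rel=0.10)

    def test_masks_disjoint(self):
        cfg = SimulationConfig(field_height_px=160, field_width_px=160)
        cells = simulate_cells(cfg, 6, 0.0, seed=2)
        total = sum(c.mask.astype(int) for c in cells)
        assert total.max() <= 1

    def test_placement_error_names_constraint(self):
        cfg = SimulationConfig(field_height_px=64, field_width_px=64)
        with pytest.raises(PlacementError, match="field|overlap"):
            simulate_cells(cfg, 60, 0.0, seed=3)

    def test_growth_factor_capped(self):
        cfg = SimulationConfig()
        assert volume_growth_factor(cfg, 0.0) == 1.0
        assert volume_growth_factor(cfg, 120.0) == pytest.approx(2.5)
        assert volume_growth_factor(cfg, 180.0) == pytest.approx(2.5)


class TestPlaceMolecules:
    def _cell(self, cfg, seed=4):
        return simulate_cells(cfg, 1, 0.0, seed=seed)[0]

    def test_tight_only_at_sites(self, small_config, rng):
        cell = self._cell(small_config)
        sites = replisome_sites_for_cell(cell, 3, rng)
        mols = place_molecules(cell, 200, (1.0, 0.0, 0.0), sites, rng,
                               small_config)
        assert np.all(mols.state == STATE_TIGHT)
        d = np.min(np.linalg.norm(
            mols.pos_nm[:, None, :] - sites[None, :, :], axis=2), axis=1)
        assert np.all(d < 1e-9)

    def test_dispersed_uniform_chi_square(self, small_config, rng):
        cell = self._cell(small_config)
        mols = place_molecules(cell, 10_000, (0.0, 0.0, 1.0), np.zeros((0, 2)),
                               rng, small_config)
        assert np.all(mols.state == STATE_DISPERSED)
        px = small_config.pixel_size_nm
        i = (mols.pos_nm[:, 1] / px).astype(int)
        j = (mols.pos_nm[:, 0] / px).astype(int)
        assert np.all(cell.mask[i, j])
        flat = np.ravel_multi_index((i, j), cell.mask.shape)
        pix = np.flatnonzero(cell.mask.ravel())
        counts = np.array([(flat == p).sum() for p in pix])
        _, p_val = stats.chisquare(counts)
        assert p_val > 0.01

    def test_loose_rayleigh_median(self, small_config, rng):
        cell = self._cell(small_config)
        sites = replisome_sites_for_cell(cell, 1, rng)
        cfg = small_config.replace(loose_offset_sigma_nm=300.0)
        mols = place_molecules(cell, 10_000, (0.0, 1.0, 0.0), sites, rng, cfg)
        d = np.linalg.norm(mols.pos_nm - sites[0], axis=1)
        expected = 300.0 * np.sqrt(2.0 * np.log(2.0))   # Rayleigh median
        assert np.median(d) == pytest.approx(expected, rel=0.05)

    def test_no_sites_with_bound_fraction_errors(self, small_config, rng):
        cell = self._cell(small_config)
        with pytest.raises(ConfigError):
            place_molecules(cell, 10, (0.5, 0.0, 0.5), np.zeros((0, 2)),
                            rng, small_config)


class TestBleaching:
    def test_infinite_tau_never_bleaches(self, rng):
        bt = draw_bleach_times(1000, np.inf, rng)
        assert np.all(np.isinf(bt))

    def test_survival_at_tau_is_e_minus_one(self, rng):
        bt = draw_bleach_times(10_000, 6.0, rng)
        assert (bt > 6.0).mean() == pytest.approx(np.exp(-1.0), abs=0.015)

    def test_survival_curve_is_exponential_ks(self, rng):
        bt = draw_bleach_times(10_000, 6.0, rng)
        assert stats.kstest(bt, "expon", args=(0, 6.0)).pvalue > 0.01

    def test_zero_return_rate_monotone_counts(self):
        cfg = SimulationConfig(return_rate_per_s=0.0, field_height_px=96,
                               field_width_px=96, f_dispersed=1.0,
                               f_tight=0.0, f_loose=0.0)
        acq = generate_rapid_acquisition(cfg, "undamaged", n_cells=2, seed=5,
                                         n_molecules=40)
        bt = acq.ground_truth.molecules.bleach_time_s
        t = acq.yfp.timestamps_s
        alive = (bt[None, :] > t[:, None]).sum(axis=1)
        assert np.all(np.diff(alive) <= 0)
        assert acq.ground_truth.molecules.return_times_s == []

    def test_return_events_only_after_bleach(self, small_config, rng):
        mols = MoleculeSet(cell_id=np.zeros(500, int),
                           state=np.full(500, STATE_DISPERSED, np.int8),
                           pos_nm=np.zeros((500, 2)))
        cfg = small_config.replace(return_rate_per_s=0.05, tau_bleach_s=1.0)
        simulate_bleaching(mols, cfg, rng, illuminated_s=10.0)
        assert len(mols.return_times_s) > 0
        for m, t in mols.return_times_s:
            assert t >= mols.bleach_time_s[m]


class TestRenderFrame:
    def test_empty_frame_is_offset(self, quiet_config):
        img = render_frame(np.zeros((0, 2)), np.zeros(0), quiet_config,
                           noise=False)
        assert np.allclose(img, quiet_config.camera_offset_au)

    def test_single_molecule_integrates_to_i_single(self, quiet_config):
        img = render_frame(np.array([[4800.0, 4800.0]]), np.array([1850.0]),
                           quiet_config, noise=False)
        total = img.sum() - quiet_config.camera_offset_au * img.size
        assert total == pytest.approx(1850.0, rel=1e-3)

    def test_photometric_linearity_with_exposure(self, quiet_config):
        # 25 molecules at 50/34 exposure scaling
        rng = np.random.default_rng(0)
        pos = rng.uniform(2000, 7000, size=(25, 2))
        scale = 50.0 / 34.0
        img = render_frame(pos, np.full(25, 1850.0 * scale), quiet_config,
                           noise=False)
        total = img.sum() - quiet_config.camera_offset_au * img.size
        assert total == pytest.approx(25 * 1850.0 * scale, rel=1e-3)

    def test_free_molecule_smear_defeats_detector(self):
        cfg = SimulationConfig(field_height_px=128, field_width_px=128,
                               f_tight=0.0, f_loose=0.0, f_dispersed=0.0,
                               autofluor_amplitude_au=0.0,
                               tau_bleach_s=1e12, n_frames_rapid=3)
        acq = generate_rapid_acquisition(cfg, "undamaged", n_cells=1, seed=6,
                                         n_molecules=1, noise=False)
        img = acq.yfp.data[0].astype(float) - cfg.camera_offset_au
        assert np.all(acq.ground_truth.molecules.state == STATE_FREE)
        # intensity-weighted RMS spread far exceeds the PSF scale
        ii, jj = np.mgrid[0:128, 0:128]
        w = np.clip(img, 0, None)
        if w.sum() > 0:
            cy = (ii * w).sum() / w.sum()
            cx = (jj * w).sum() / w.sum()
            rms = np.sqrt(((ii - cy) ** 2 + (jj - cx) ** 2 * 1.0)
                          [w > 0].mean())
            assert rms * cfg.pixel_size_nm > 10 * cfg.psf_sigma_px * 100.0
        # under realistic noise the smear stays below the detection threshold
        noisy = generate_rapid_acquisition(
            cfg.replace(autofluor_amplitude_au=100.0, read_noise_sd_au=3.0),
            "undamaged", n_cells=1, seed=6, n_molecules=1, noise=True)
        union = acq.ground_truth.cells[0].mask
        peaks = detect_peaks(noisy.yfp.data[0].astype(float), 100.0,
                             threshold_sd=5.0, mask=union)
        assert len(peaks) == 0


class TestSchedules:
    def test_default_timelapse_has_37_points(self):
        assert len(timelapse_times_min(SimulationConfig())) == 37

    def test_rapid_duration(self):
        cfg = SimulationConfig(field_height_px=96, field_width_px=96,
                               n_frames_rapid=300)
        acq = generate_rapid_acquisition(cfg, "undamaged", n_cells=1, seed=7,
                                         n_molecules=0)
        assert acq.yfp.n_frames == 300
        dt = cfg.frame_interval_rapid_s
        assert acq.yfp.timestamps_s[-1] + dt == pytest.approx(10.2)

    def test_undamaged_copy_number_constant(self):
        cfg = SimulationConfig(field_height_px=200, field_width_px=200,
                               timelapse_duration_min=30.0)
        tl = generate_timelapse(cfg, "undamaged", n_cells=4, seed=8,
                                noise=False)
        means = [g.n_molecules_per_cell.mean() for g in tl.ground_truths]
        # Poisson(20) draws around a flat expectation
        assert np.mean(means) == pytest.approx(20.0, rel=0.2)
        assert max(means) - min(means) < 15.0

    def test_channel_lag_in_timestamps(self):
        cfg = SimulationConfig(field_height_px=160, field_width_px=160,
                               timelapse_duration_min=10.0)
        tl = generate_timelapse(cfg, "damage", n_cells=2, seed=9)
        lag = tl.red.timestamps_s - tl.yfp.timestamps_s
        assert np.allclose(lag, cfg.channel_lag_s)


class TestDeterminismAndMotion:
    def test_same_seed_bitwise_identical(self, small_config):
        a = generate_rapid_acquisition(
            small_config.replace(n_frames_rapid=20), "damage", n_cells=3,
            seed=10, t_min=60.0)
        b = generate_rapid_acquisition(
            small_config.replace(n_frames_rapid=20), "damage", n_cells=3,
            seed=10, t_min=60.0)
        assert np.array_equal(a.yfp.data, b.yfp.data)
        assert np.array_equal(a.brightfield.data, b.brightfield.data)

    def test_different_seed_differs(self, small_config):
        a = generate_rapid_acquisition(
            small_config.replace(n_frames_rapid=5), "damage", n_cells=3,
            seed=10, t_min=60.0)
        b = generate_rapid_acquisition(
            small_config.replace(n_frames_rapid=5), "damage", n_cells=3,
            seed=11, t_min=60.0)
        assert not np.array_equal(a.yfp.data, b.yfp.data)

    def test_bound_rms_step_matches_d_bound(self):
        cfg = SimulationConfig(field_height_px=128, field_width_px=128,
                               D_bound_um2_s=0.01, tau_bleach_s=1e12,
                               f_dispersed=1.0, f_tight=0.0, f_loose=0.0,
                               autofluor_amplitude_au=0.0,
                               n_frames_rapid=210)
        acq = generate_rapid_acquisition(cfg, "undamaged", n_cells=2, seed=11,
                                         n_molecules=25, noise=False,
                                         store_trajectories=True)
        traj = acq.ground_truth.bound_trajectories
        steps = np.diff(traj, axis=0)                 # (frames-1, n, 2)
        rms = np.sqrt((steps ** 2).sum(axis=2).mean())
        expected = np.sqrt(4.0 * 0.01 * cfg.frame_interval_rapid_s) * 1000.0
        assert rms == pytest.approx(expected, rel=0.05)


def test_dead_scenario_has_no_bound_molecules(small_config):
    acq = generate_rapid_acquisition(
        small_config.replace(n_frames_rapid=5), "dead", n_cells=2, seed=12,
        n_molecules=30)
    assert np.all(acq.ground_truth.molecules.state == STATE_FREE)
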