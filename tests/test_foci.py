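import numpy as np
import pytest

from fociquant.config import SimulationConfig
from fociquant.foci import (detect_peaks, extract_trajectory,
                            fit_gaussian_2d, foci_density, foci_per_cell,
                            local_background_correct, Focus,
                            IntensityTrajectory)
from fociquant.geometry import outline_from_mask
from fociquant.sim import (generate_rapid_acquisition, render_frame,
                           simulate_cells)
from fociquant.stack import MovieStack


def _sampled_gaussian(shape, amp, cx, cy, sigma, bg=0.0):
    """Pixel-centre-sampled Gaussian (matches the fit model exactly)."""
    ii, jj = np.mgrid[0:shape[0], 0:shape[1]]
    return bg + amp * np.exp(-((jj + 0.5 - cx) ** 2 + (ii + 0.5 - cy) ** 2)
                             / (2.0 * sigma ** 2))


class TestDetectPeaks:
    def test_false_positive_rate_on_noise(self):
        cfg = SimulationConfig(field_height_px=512, field_width_px=512)
        cells = simulate_cells(cfg, 50, 0.0, seed=1)
        rng = np.random.default_rng(1)
        union = np.zeros((512, 512), dtype=bool)
        for c in cells:
            union |= c.mask
        n_peaks = 0
        n_cell_trials = 0
        for rep in range(2):
            img = render_frame(np.zeros((0, 2)), np.zeros(0), cfg,
                               autofluor_map=union * 100.0, rng=rng,
                               noise=True)
            n_peaks += len(detect_peaks(img, 100.0, threshold_sd=5.0,
                                        mask=union))
            n_cell_trials += len(cells)
        assert n_peaks / n_cell_trials < 0.1

    def test_bright_molecule_found_within_one_pixel(self):
        cfg = SimulationConfig(field_height_px=64, field_width_px=64)
        rng = np.random.default_rng(2)
        hits = 0
        for k in range(20):
            pos = rng.uniform(2500, 3500, size=2)
            img = render_frame(pos[None, :], np.array([5000.0]), cfg,
                               rng=rng, noise=True)
            peaks = detect_peaks(img, 100.0, threshold_sd=5.0)
            if len(peaks) == 1:
                err = np.hypot(peaks[0][1] + 0.5 - pos[0] / 100.0,
                               peaks[0][0] + 0.5 - pos[1] / 100.0)
                hits += err <= 1.5
        assert hits >= 18

    def test_close_pair_merged(self):
        cfg = SimulationConfig(field_height_px=64, field_width_px=64,
                               read_noise_sd_au=0.0,
                               autofluor_amplitude_au=0.0)
        pos = np.array([[3200.0, 3200.0], [3350.0, 3200.0]])   # 150 nm apart
        img = render_frame(pos, np.array([3000.0, 2500.0]), cfg, noise=False)
        img = img + np.random.default_rng(3).normal(0, 1.0, img.shape)
        peaks = detect_peaks(img, 100.0, min_separation_nm=300.0,
                             threshold_sd=5.0)
        assert len(peaks) == 1

    def test_blank_allowed(self):
        img = np.random.default_rng(4).normal(100.0, 3.0, (64, 64))
        assert detect_peaks(img, 100.0, threshold_sd=6.0).shape[1:] == (2,)


class TestFitGaussian2D:
    def test_closed_form_volume(self):
        img = _sampled_gaussian((21, 21), 10.0, 10.5, 10.5, 1.5)
        f = fit_gaussian_2d(img, (10, 10), 100.0)
        assert f.accepted
        expected = 2.0 * np.pi * 10.0 * 1.5 ** 2
        assert f.integrated_au == pytest.approx(expected, abs=1e-4)
        assert f.integrated_au == pytest.approx(141.37, abs=0.01)

    def test_internal_consistency_invariant(self):
        img = _sampled_gaussian((21, 21), 7.0, 9.8, 11.2, 1.2, bg=5.0)
        f = fit_gaussian_2d(img, (11, 10), 100.0)
        recomputed = (2.0 * np.pi * f.amplitude
                      * (f.sigma_x_nm / 100.0) * (f.sigma_y_nm / 100.0))
        assert f.integrated_au == pytest.approx(recomputed, rel=1e-6)

    def test_rendered_single_molecule_near_1850(self):
        cfg = SimulationConfig(field_height_px=48, field_width_px=48,
                               autofluor_amplitude_au=0.0)
        rng = np.random.default_rng(5)
        img = render_frame(np.array([[2400.0, 2400.0]]), np.array([1850.0]),
                           cfg, rng=rng, noise=True)
        f = fit_gaussian_2d(img - cfg.camera_offset_au, (24, 24), 100.0)
        assert f.accepted
        assert f.integrated_au == pytest.approx(1850.0, rel=0.15)

    def test_flat_background_rejected(self):
        img = np.full((21, 21), 50.0)
        f = fit_gaussian_2d(img, (10, 10), 100.0)
        assert not f.accepted and "amplitude" in f.status

    def test_pure_noise_rejected_mostly(self):
        rng = np.random.default_rng(6)
        rejected = 0
        for _ in range(10):
            img = rng.normal(0.0, 3.0, (21, 21))
            f = fit_gaussian_2d(img, (10, 10), 100.0)
            rejected += not f.accepted
        assert rejected >= 8

    def test_window_clipped_rejected(self):
        img = np.zeros((21, 21))
        f = fit_gaussian_2d(img, (1, 10), 100.0)
        assert not f.accepted and "clipped" in f.status

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_2d(np.zeros((21, 21)), (10, 10), 100.0, window_px=5)

    def test_centroid_rms_error_below_30nm(self):
        cfg = SimulationConfig(field_height_px=48, field_width_px=48,
                               autofluor_amplitude_au=0.0)
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(100):
            pos = rng.uniform(2300, 2500, size=2)
            img = render_frame(pos[None, :], np.array([1850.0]), cfg,
                               rng=rng, noise=True)
            f = fit_gaussian_2d(img - cfg.camera_offset_au, (24, 24), 100.0)
            if f.accepted:
                errs.append((f.x_nm - pos[0]) ** 2 + (f.y_nm - pos[1]) ** 2)
        assert len(errs) >= 90
        assert np.sqrt(np.mean(errs)) <= 30.0

    def test_integrated_intensity_unbiased_within_3_percent(self):
        cfg = SimulationConfig(field_height_px=48, field_width_px=48,
                               autofluor_amplitude_au=0.0)
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(500):
            pos = rng.uniform(2300, 2500, size=2)
            img = render_frame(pos[None, :], np.array([1850.0]), cfg,
                               rng=rng, noise=True)
            f = fit_gaussian_2d(img - cfg.camera_offset_au, (24, 24), 100.0)
            if f.accepted:
                vals.append(f.integrated_au)
        assert np.mean(vals) == pytest.approx(1850.0, rel=0.03)


class TestLocalBackground:
    def test_uniform_image_corrects_to_zero(self):
        img = np.full((32, 32), 123.0)
        bg, corrected = local_background_correct(img, (16, 16), roi_px=5)
        assert bg == pytest.approx(123.0)
        assert corrected == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_on_offset(self):
        img = _sampled_gaussian((33, 33), 40.0, 16.5, 16.5, 1.3, bg=100.0)
        bg, corrected = local_background_correct(img, (16, 16), roi_px=5)
        # analytic oracle: evaluate the offset-free Gaussian over the same
        # ROI and ring; the offset must cancel exactly
        pure = _sampled_gaussian((33, 33), 40.0, 16.5, 16.5, 1.3)
        roi = pure[14:19, 14:19]
        ring = pure[12:21, 12:21].sum() - roi.sum()
        expected = roi.sum() - ring / (81 - 25) * 25
        assert corrected == pytest.approx(expected, rel=1e-9)
        true_volume = 2.0 * np.pi * 40.0 * 1.3 ** 2
        assert corrected == pytest.approx(true_volume * 0.87, rel=0.05)
        assert bg == pytest.approx(100.0, abs=2.0)

    def test_linear_gradient_cancels_first_order(self):
        yy, xx = np.mgrid[0:33, 0:33]
        grad = 10.0 * xx / 32.0
        focus = _sampled_gaussian((33, 33), 40.0, 16.5, 16.5, 1.3)
        _, corrected = local_background_correct(grad + focus, (16, 16))
        _, pure = local_background_correct(focus, (16, 16))
        assert abs(corrected - pure) < 0.03 * pure

    def test_ring_clipped_errors(self):
        with pytest.raises(ValueError, match="ring"):
            local_background_correct(np.zeros((20, 20)), (2, 10))


class TestExtractTrajectory:
    def _stack(self, data):
        return MovieStack(data=np.asarray(data, float), pixel_size_nm=100.0,
                          timestamps_s=np.arange(len(data)) * 0.034,
                          exposure_ms=34.0, channel="yfp")

    def test_constant_stack_constant_trajectory(self):
        st = self._stack(np.full((10, 32, 32), 55.0))
        tr = extract_trajectory(st, (1600.0, 1600.0))
        assert np.allclose(tr.intensities_au, 0.0, atol=1e-9)
        assert len(tr.times_s) == 10

    def test_bleach_step_visible(self):
        cfg = SimulationConfig(field_height_px=48, field_width_px=48,
                               autofluor_amplitude_au=0.0,
                               read_noise_sd_au=0.0)
        rng = np.random.default_rng(9)
        frames = []
        for f in range(20):
            flux = np.array([1850.0]) if f < 8 else np.zeros(1)
            frames.append(render_frame(np.array([[2400.0, 2400.0]])[:flux.size],
                                       flux, cfg, rng=rng, noise=True))
        st = self._stack(np.stack(frames))
        tr = extract_trajectory(st, (2400.0, 2400.0))
        assert tr.intensities_au[:8].mean() > 5 * abs(
            tr.intensities_au[10:].mean() + 1e-9)

    def test_single_frame_spike(self):
        cfg = SimulationConfig(field_height_px=48, field_width_px=48,
                               autofluor_amplitude_au=0.0,
                               read_noise_sd_au=0.0)
        rng = np.random.default_rng(10)
        frames = [render_frame(np.array([[2400.0, 2400.0]]),
                               np.array([1850.0 if f == 7 else 0.0]), cfg,
                               rng=rng, noise=True) for f in range(15)]
        st = self._stack(np.stack(frames))
        tr = extract_trajectory(st, (2400.0, 2400.0))
        assert np.argmax(tr.intensities_au) == 7
        others = np.delete(tr.intensities_au, 7)
        assert tr.intensities_au[7] > others.max() + 5 * others.std()

    def test_trajectory_invariants(self):
        with pytest.raises(ValueError):
            IntensityTrajectory(times_s=[0.0, 1.0], intensities_au=[1.0],
                                center_nm=(0, 0))
        with pytest.raises(ValueError):
            IntensityTrajectory(times_s=[1.0, 0.5],
                                intensities_au=[1.0, 2.0], center_nm=(0, 0))


def _focus_at(x_nm, y_nm):
    return Focus(x_nm=x_nm, y_nm=y_nm, sigma_x_nm=130.0, sigma_y_nm=130.0,
                 amplitude=100.0, background=0.0, integrated_au=1850.0,
                 residual=1.0, pixel_size_nm=100.0)


class TestFociPerCellAndDensity:
    def test_density_zero_and_simple(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:25, 5:45 - 5] = True
        o = outline_from_mask(mask, 100.0)
        assert foci_density([], o) == 0.0
        o.area_um2 = 8.0
        assert foci_density([_focus_at(0, 0)] * 4, o) == pytest.approx(0.5)

    def test_mean_and_sem_hand_computed(self):
        masks = []
        for k in range(3):
            m = np.zeros((60, 60), dtype=bool)
            m[5 + 15 * k: 15 + 15 * k, 10:30] = True
            masks.append(outline_from_mask(m, 100.0, cell_id=k))
        foci = [_focus_at(1500.0, 2500.0),                    # cell 1
                _focus_at(1500.0, 3600.0),                    # cell 2
                _focus_at(2500.0, 3800.0)]                    # cell 2
        res = foci_per_cell(foci, masks)
        assert res["counts"] == {0: 0, 1: 1, 2: 2}
        assert res["mean"] == pytest.approx(1.0)
        assert res["sem"] == pytest.approx(1.0 / np.sqrt(3.0), rel=1e-6)

    def test_unassigned_counted(self):
        m = np.zeros((40, 40), dtype=bool)
        m[10:20, 10:20] = True
        o = outline_from_mask(m, 100.0, cell_id=0)
        res = foci_per_cell([_focus_at(3500.0, 3500.0)], [o])
        assert res["n_unassigned"] == 1

    def test_overlapping_masks_error(self):
        m1 = np.zeros((40, 40), dtype=bool)
        m1[10:20, 10:20] = True
        m2 = np.zeros((40, 40), dtype=bool)
        m2[15:25, 15:25] = True
        o1 = outline_from_mask(m1, 100.0, cell_id=0)
        o2 = outline_from_mask(m2, 100.0, cell_id=1)
        with pytest.raises(ValueError, match="overlap"):
            foci_per_cell([], [o1, o2])


def test_null_scenario_focus_rate_matches_noise_only():
    """A no-binding analogue produces no more foci than pure noise."""
    cfg = SimulationConfig(field_height_px=256, field_width_px=256,
                           n_frames_rapid=10)
    dead = generate_rapid_acquisition(cfg, "dead", n_cells=8, seed=20,
                                      t_min=120.0, n_molecules=40)
    empty = generate_rapid_acquisition(cfg, "undamaged", n_cells=8, seed=20,
                                       n_molecules=0)
    def count(acq):
        union = np.zeros((256, 256), dtype=bool)
        for c in acq.ground_truth.cells:
            union |= c.mask
        n = 0
        for f in range(acq.yfp.n_frames):
            n += len(detect_peaks(acq.yfp.data[f].astype(float), 100.0,
                                  threshold_sd=5.0, mask=union))
        return n
    n_dead, n_empty = count(dead), count(empty)
    assert n_dead <= n_empty + 5
    assert n_dead / (8 * cfg.n_frames_rapid) < 0.1
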