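import json

import numpy as np
import pytest
from scipy import ndimage

from drydown import synthetic as syn
from drydown.exceptions import ConfigError, GenerationError


class TestConduitPopulation:
    def test_determinism(self, small_config, small_truth):
        p1 = syn.gen_conduit_population(small_config, small_truth)
        p2 = syn.gen_conduit_population(small_config, small_truth)
        np.testing.assert_array_equal(p1.diameters, p2.diameters)
        np.testing.assert_array_equal(p1.positions, p2.positions)
        np.testing.assert_array_equal(p1.thresholds, p2.thresholds)

    def test_seed_changes_population(self, small_config, small_truth):
        other = syn.DrydownTruth.linear_ramp(3.54, 5.86, seed=small_truth.seed + 1,
                                             psi_end=-7.0, duration_s=7200.0)
        p1 = syn.gen_conduit_population(small_config, small_truth)
        p2 = syn.gen_conduit_population(small_config, other)
        assert not np.array_equal(p1.diameters, p2.diameters)

    def test_small_class_mass_fraction(self):
        cfg = syn.SyntheticConfig(n_conduits=2000, region_um=(2000.0, 2000.0),
                                  small_class_fraction=0.14)
        truth = syn.DrydownTruth.linear_ramp(3.54, 5.86, seed=11, duration_s=7200)
        pop = syn.gen_conduit_population(cfg, truth)
        frac = np.mean((pop.diameters >= 0.5) & (pop.diameters < 1.5))
        tol = 3 * np.sqrt(0.14 * 0.86 / 2000)  # binomial 3-sigma
        assert abs(frac - 0.14) < tol

    def test_threshold_median_closed_form(self):
        cfg = syn.SyntheticConfig(n_conduits=100_000, region_um=(5000.0, 5000.0))
        truth = syn.DrydownTruth.linear_ramp(3.54, 5.86, seed=5, duration_s=7200)
        pop = syn.gen_conduit_population(cfg, truth)
        med_tension = np.median(-pop.thresholds)
        expected = 3.54 * np.log(2.0) ** (1 / 5.86)  # closed-form Weibull median
        assert med_tension == pytest.approx(expected, abs=0.02)

    def test_coupling_shifts_small_class(self):
        cfg = syn.SyntheticConfig(n_conduits=4000, region_um=(2000.0, 2000.0),
                                  small_class_fraction=0.2,
                                  small_threshold_shift_mpa=-1.5)
        truth = syn.DrydownTruth.linear_ramp(3.54, 5.86, seed=2, duration_s=7200)
        pop = syn.gen_conduit_population(cfg, truth)
        small = pop.diameters < 1.5
        assert np.median(pop.thresholds[small]) < np.median(pop.thresholds[~small]) - 1.0

    def test_invalid_config(self):
        with pytest.raises(ConfigError):
            syn.SyntheticConfig(n_conduits=0)
        with pytest.raises(ConfigError):
            syn.SyntheticConfig(small_class_fraction=1.0)
        with pytest.raises(ConfigError):
            syn.DrydownTruth.linear_ramp(-1.0, 5.86, seed=0, duration_s=7200)

    def test_invariants(self, small_config, small_truth):
        pop = syn.gen_conduit_population(small_config, small_truth)
        assert np.all(pop.diameters > 0)
        assert np.all(pop.thresholds < 0)
        assert len(pop.positions) == len(pop.diameters) == len(pop.thresholds)


class TestPsiTrajectory:
    def test_linear_ramp_arithmetic(self):
        # -0.1 MPa/h for 20 h from -0.2 -> terminal -2.2
        truth = syn.DrydownTruth.linear_ramp(3.54, 5.86, seed=0, psi_start=-0.2,
                                             psi_end=-2.2, duration_s=72_000.0)
        assert truth.psi_true(0) == -0.2
        assert truth.psi_true(72_000) == pytest.approx(-2.2)
        assert truth.psi_true(36_000) == pytest.approx(-1.2)

    def test_knots_evaluated_exactly(self):
        truth = syn.DrydownTruth(psi_knots_t=[0.0, 3600.0, 7200.0],
                                 psi_knots_mpa=[-0.2, -1.0, -4.0],
                                 weibull_scale=3.54, weibull_shape=5.86,
                                 seed=0, duration_s=7200.0)
        tl = syn.gen_psi_trajectory(truth)
        np.testing.assert_array_equal(tl(np.array([0.0, 3600.0, 7200.0])),
                                      [-0.2, -1.0, -4.0])

    def test_monotone_dense_grid_scan(self, small_truth):
        tl = syn.gen_psi_trajectory(small_truth)
        grid = np.linspace(0, small_truth.duration_s, 5000)
        vals = tl(grid)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_duration_limit(self):
        with pytest.raises(ConfigError):
            syn.DrydownTruth.linear_ramp(3.54, 5.86, seed=0, duration_s=80_000.0)

    def test_increasing_psi_rejected(self):
        with pytest.raises(ConfigError):
            syn.DrydownTruth(psi_knots_t=[0.0, 100.0], psi_knots_mpa=[-1.0, -0.5],
                             weibull_scale=1.0, weibull_shape=1.0,
                             seed=0, duration_s=100.0)


class TestAEStream:
    def test_threshold_counting_oracle(self, small_config, small_truth):
        pop = syn.gen_conduit_population(small_config, small_truth)
        log = syn.gen_ae_stream(pop, small_truth, small_config)  # nuisance off
        for t in (1000.0, 3000.0, 6000.0):
            psi_t = small_truth.psi_true(t)
            expected = int(np.sum(pop.thresholds >= psi_t))
            assert int(np.sum(log.times <= t)) == expected

    def test_conservation_total_hits(self, small_config, small_truth):
        pop = syn.gen_conduit_population(small_config, small_truth)
        log = syn.gen_ae_stream(pop, small_truth, small_config)
        crossed = np.sum(pop.thresholds >= small_truth.psi_true(small_truth.duration_s))
        assert len(log) == crossed

    def test_unreachable_thresholds_no_hits(self, small_config):
        truth = syn.DrydownTruth.linear_ramp(3.54, 5.86, seed=3, psi_end=-0.25,
                                             duration_s=7200.0)
        pop = syn.gen_conduit_population(small_config, truth)
        pop.thresholds = np.full(len(pop), -5.0)  # all below terminal psi
        log = syn.gen_ae_stream(pop, truth, small_config)
        assert len(log) == 0

    def test_nuisance_keeps_rate_up_late(self, small_truth):
        cfg = syn.SyntheticConfig(n_conduits=50, region_um=(200.0, 200.0),
                                  nuisance_rate0_hz=0.05,
                                  nuisance_growth_per_s=5e-4,
                                  nuisance_onset_frac=0.5)
        pop = syn.gen_conduit_population(cfg, small_truth)
        log = syn.gen_ae_stream(pop, small_truth, cfg)
        last_hour = np.sum(log.times > small_truth.duration_s - 3600)
        assert last_hour > 0

    def test_amplitudes_above_detection_threshold(self, small_config, small_truth):
        pop = syn.gen_conduit_population(small_config, small_truth)
        log = syn.gen_ae_stream(pop, small_truth, small_config)
        assert np.all(log.amplitudes >= 35.0)
        assert np.all(np.diff(log.times) >= 0)

    def test_empty_population_warns(self, small_config, small_truth):
        empty = syn.ConduitPopulation(diameters=np.empty(0),
                                      positions=np.empty((0, 2)),
                                      thresholds=np.empty(0))
        with pytest.warns(UserWarning, match="empty"):
            log = syn.gen_ae_stream(empty, small_truth, small_config)
        assert len(log) == 0

    def test_determinism(self, small_config, small_truth):
        pop = syn.gen_conduit_population(small_config, small_truth)
        l1 = syn.gen_ae_stream(pop, small_truth, small_config)
        l2 = syn.gen_ae_stream(pop, small_truth, small_config)
        np.testing.assert_array_equal(l1.times, l2.times)
        np.testing.assert_array_equal(l1.amplitudes, l2.amplitudes)


class TestOVStack:
    def _one_conduit(self, diameter, threshold=-2.0, noise_sd=0.0):
        cfg = syn.SyntheticConfig(n_conduits=1, region_um=(40.0, 40.0),
                                  noise_sd=noise_sd)
        truth = syn.DrydownTruth.linear_ramp(3.54, 5.86, seed=1, psi_end=-4.0,
                                             duration_s=1200.0)
        pop = syn.ConduitPopulation(diameters=np.array([diameter]),
                                    positions=np.array([[20.0, 20.0]]),
                                    thresholds=np.array([threshold]))
        return cfg, truth, pop

    def test_frame_spacing_150s(self, small_config, small_truth):
        pop = syn.gen_conduit_population(small_config, small_truth)
        stack = syn.gen_ov_stack(pop, small_truth, small_config)
        np.testing.assert_allclose(np.diff(stack.times), 150.0)

    def test_noise_free_frames_identical_without_embolism(self):
        cfg, truth, pop = self._one_conduit(6.0, threshold=-3.9)
        stack = syn.gen_ov_stack(pop, truth, cfg)
        # threshold crossed near the end; early frames identical
        np.testing.assert_array_equal(stack.frames[0], stack.frames[1])

    def test_single_step_component_pixel_count_oracle(self):
        cfg, truth, pop = self._one_conduit(4.0, threshold=-2.0)
        stack = syn.gen_ov_stack(pop, truth, cfg)
        diffs = np.abs(np.diff(stack.frames.astype(float), axis=0))
        stepped = [k for k in range(len(diffs)) if diffs[k].max() > 0]
        assert len(stepped) == 1
        dmap = diffs[stepped[0]] > 0
        labels, n = ndimage.label(dmap)  # independent component labeling
        assert n == 1
        # area equals the rendered disk pixel count (r = 2 px, pixels
        # strictly inside the radius)
        rr, cc = np.nonzero(dmap)
        assert len(rr) == np.sum(
            (np.arange(40)[:, None] - 20) ** 2 + (np.arange(40)[None, :] - 20) ** 2
            < 2.0 ** 2)

    def test_sub_resolution_invisible(self):
        cfg, truth, pop = self._one_conduit(1.0, threshold=-2.0)  # area < 1 px
        stack = syn.gen_ov_stack(pop, truth, cfg)
        assert np.ptp(stack.frames) == 0  # nothing ever rendered
        assert not syn.visible_mask(pop, cfg).any()

    def test_conduit_outside_frame_errors(self):
        cfg, truth, pop = self._one_conduit(6.0)
        pop.positions[0] = [39.0, 39.0]
        with pytest.raises(GenerationError, match="conduit 0"):
            syn.gen_ov_stack(pop, truth, cfg)

    def test_noise_determinism(self):
        cfg, truth, pop = self._one_conduit(6.0, noise_sd=2.0)
        s1 = syn.gen_ov_stack(pop, truth, cfg)
        s2 = syn.gen_ov_stack(pop, truth, cfg)
        np.testing.assert_array_equal(s1.frames, s2.frames)

    def test_area_conservation_disjoint_disks(self, small_config, small_truth):
        pop = syn.gen_conduit_population(small_config, small_truth)
        stack = syn.gen_ov_stack(pop, small_truth, small_config)
        visible = syn.visible_mask(pop, small_config)
        crossed = pop.thresholds >= small_truth.psi_true(small_truth.duration_s)
        emb_t = syn.first_crossing_times(pop.thresholds, small_truth)
        after_start = emb_t > 0
        total_step_px = int((np.abs(np.diff(stack.frames.astype(float), axis=0))
                             > 0).any(axis=0).sum())
        # with min_separation the disks are disjoint: stepped pixels = sum of
        # rendered areas of visible conduits that embolize during the record
        from skimage import draw
        expected = 0
        for i in range(len(pop)):
            if not (visible[i] and crossed[i] and after_start[i]):
                continue
            rr, _ = draw.disk(tuple(pop.positions[i]), pop.diameters[i] / 2,
                              shape=stack.frames.shape[1:])
            expected += len(rr)
        assert total_step_px == expected


class TestPsiMeasurements:
    def test_noise_free_exact(self, small_config, small_truth):
        ms = syn.gen_psi_measurements(small_truth, small_config)
        for m in ms:
            assert m.psi == pytest.approx(small_truth.psi_true(m.time))

    def test_plants_per_timepoint(self, small_config, small_truth):
        ms = syn.gen_psi_measurements(small_truth, small_config)
        times = np.array([m.time for m in ms])
        for t in np.unique(times):
            assert np.sum(times == t) in (2, 3)

    def test_replicate_mean_converges(self):
        cfg = syn.SyntheticConfig(n_conduits=5, region_um=(100.0, 100.0),
                                  psi_noise_sd_mpa=0.05,
                                  psi_sample_interval_s=25.0,
                                  plants_per_timepoint=(3,))
        truth = syn.DrydownTruth.linear_ramp(3.54, 5.86, seed=9, psi_start=-2.0,
                                             psi_end=-2.0, duration_s=7200.0)
        ms = syn.gen_psi_measurements(truth, cfg)
        vals = np.array([m.psi for m in ms])
        se = 0.05 / np.sqrt(len(vals))
        assert abs(vals.mean() - (-2.0)) < 4 * se


class TestBiasProperty:
    def test_observable_thresholds_less_negative(self):
        cfg = syn.SyntheticConfig(n_conduits=3000, region_um=(2000.0, 2000.0),
                                  small_class_fraction=0.14,
                                  small_threshold_shift_mpa=-1.5)
        truth = syn.DrydownTruth.linear_ramp(3.54, 5.86, seed=4, duration_s=7200)
        pop = syn.gen_conduit_population(cfg, truth)
        vis = syn.visible_mask(pop, cfg)
        assert 0 < vis.sum() < len(pop)
        t_vis = -pop.thresholds[vis]
        t_all = -pop.thresholds
        # stochastic dominance: visible tension CDF sits above the full CDF
        for q in np.quantile(t_all, [0.25, 0.5, 0.75]):
            assert np.mean(t_vis <= q) >= np.mean(t_all <= q) - 1e-12
        assert np.median(t_vis) < np.median(t_all)


class TestWriteDataset(object):
    def test_roundtrip_and_truth_sidecar(self, tmp_path, small_config, small_truth):
        ds = syn.simulate(small_config, small_truth)
        out = syn.write_dataset(tmp_path / "ds", ds)
        from drydown import io as dio
        logs = dio.read_ae_csv(out / "ae.csv")
        assert len(logs["synthetic"]) == len(ds.ae_log)
        np.testing.assert_allclose(logs["synthetic"].times, ds.ae_log.times)
        stack = dio.read_image_stack(out)
        np.testing.assert_allclose(stack.frames, ds.stack.frames)
        np.testing.assert_allclose(stack.times, ds.stack.times)
        truth = json.loads((out / "truth.json").read_text())
        assert truth["weibull_scale"] == small_truth.weibull_scale
        assert truth["weibull_shape"] == small_truth.weibull_shape
        ms = dio.read_psi_csv(out / "psi.csv")
        assert len(ms) == len(ds.psi_measurements)
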