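"""Phantom generator: kinetic closed forms, noise statistics, determinism, cohorts."""

import numpy as np
import pytest

import sonoperf as sp
from sonoperf.simulate import RAYLEIGH_REL_SD, _draw_multiplier


class TestSimulateTic:
    def test_replenishment_closed_form(self, clean_scenario):
        """One time constant after the flash the curve sits at A(1-1/e)."""
        cfg = clean_scenario
        cfg.recirculation_delay = 0.0
        curve = sp.simulate_tic(cfg, "treated")
        # treated: A=10, beta=0.05, y0=0.5; flash at 300 s; 1/beta = 20 s later
        i = np.argmin(np.abs(curve.times - 320.0))
        expected = 0.5 + 10.0 * (1.0 - np.exp(-1.0))
        assert curve.intensities[i] == pytest.approx(expected, rel=1e-12)
        assert curve.intensities[i] == pytest.approx(0.5 + 6.321, abs=5e-4)

    def test_zero_amplitude_region_is_flat(self, clean_scenario):
        curve = sp.simulate_tic(clean_scenario, "background")
        assert np.all(curve.intensities == 0.2)

    def test_flash_frame_resets_to_baseline(self, clean_scenario):
        curve = sp.simulate_tic(clean_scenario, "treated")
        for flash in clean_scenario.flash_times:
            i = np.argmin(np.abs(curve.times - flash))
            assert curve.intensities[i] == pytest.approx(0.5)

    def test_replenishment_monotone_and_bounded(self, clean_scenario):
        """Noiseless signal never decreases within a replenishment window and
        never exceeds y0 + A."""
        cfg = clean_scenario
        curve = sp.simulate_tic(cfg, "treated")
        t = curve.times
        for flash, end in [(300.0, 630.0), (630.0, cfg.duration)]:
            sel = (t >= flash) & (t < end)
            seg = curve.intensities[sel]
            assert np.all(np.diff(seg) >= 0)
        assert curve.intensities.max() <= 0.5 + 10.0 + 1e-12

    def test_rayleigh_noise_preserves_plateau_mean(self):
        """Monte-Carlo: speckle is mean-preserving at the configured plateau."""
        cfg = sp.default_scenario(seed=7, noise_scale=0.1)
        cfg.n_frames = 10_000
        cfg.frame_rate = 100.0  # keep flashes inside a short wall-clock window
        cfg.flash_times = (99.0,)
        cfg.infusion_tau = 1.0
        curve = sp.simulate_tic(cfg, "treated", seed=7)
        plateau = curve.intensities[(curve.times > 50) & (curve.times < 99)]
        assert plateau.mean() == pytest.approx(10.5, rel=0.01)

    def test_unknown_region_label_raises(self, clean_scenario):
        with pytest.raises(KeyError):
            sp.simulate_tic(clean_scenario, "nonexistent")

    def test_flash_outside_duration_rejected(self, clean_scenario):
        clean_scenario.flash_times = (300.0, 5000.0)
        with pytest.raises(ValueError, match="within the sequence duration"):
            sp.simulate_tic(clean_scenario, "treated")


class TestSimulateSequence:
    def test_noiseless_frames_equal_analytic_model(self, short_scenario):
        seq, _ = sp.simulate_sequence(short_scenario)
        masks = short_scenario.masks()
        for label in ("treated", "control"):
            expected = sp.region_curve(short_scenario, label)
            pixel = seq.frames[:, masks[label]]
            assert np.array_equal(pixel, np.broadcast_to(expected[:, None], pixel.shape))
        # outside every region: identically zero
        outside = ~(masks["treated"] | masks["control"])
        assert np.all(seq.frames[:, outside] == 0)

    def test_seed_determinism_bit_identical(self, short_scenario):
        short_scenario.noise = sp.NoiseSpec("rayleigh_multiplicative", 0.1)
        seq1, _ = sp.simulate_sequence(short_scenario)
        seq2, _ = sp.simulate_sequence(short_scenario)
        assert seq1.frames.tobytes() == seq2.frames.tobytes()

    def test_overlapping_masks_rejected(self, short_scenario):
        short_scenario.regions[1].geometry = {"shape": "disk", "center": (8, 6), "radius": 3}
        with pytest.raises(ValueError, match="overlapping"):
            sp.simulate_sequence(short_scenario)

    def test_ground_truth_records_treatment_multiplier(self, short_scenario):
        short_scenario.flash_times = (20.0, 60.0)
        short_scenario.treatment = sp.Treatment("treated", beta_multiplier=0.5)
        _, gt = sp.simulate_sequence(short_scenario)
        assert gt.regions["treated"]["beta_post"] == pytest.approx(
            gt.regions["treated"]["beta_pre"] * 0.5
        )
        assert gt.regions["control"]["beta_post"] == gt.regions["control"]["beta_pre"]

    def test_end_to_end_parameter_recovery(self):
        """extract_tic + fit on a generated sequence recovers (A, beta) within
        5% of ground truth at speckle scale 0.1."""
        cfg = sp.default_scenario(seed=2, noise_scale=0.1, beta_multiplier=0.5)
        seq, gt = sp.simulate_sequence(cfg)
        tic = sp.extract_tic(seq, cfg.masks(), "treated")
        segments = sp.segment_replenishment(tic, cfg.flash_times, recirc_delay=30.0)
        pre = sp.fit_replenishment(segments[0])
        post = sp.fit_replenishment(segments[1])
        truth = gt.regions["treated"]
        assert pre.A == pytest.approx(truth["A"], rel=0.05)
        assert pre.beta == pytest.approx(truth["beta_pre"], rel=0.05)
        assert post.beta == pytest.approx(truth["beta_post"], rel=0.05)

    def test_log_compression_recorded_in_metadata(self, short_scenario):
        short_scenario.compression = sp.LogCompression(dynamic_range=60.0, max_code=255.0)
        seq, _ = sp.simulate_sequence(short_scenario)
        assert seq.intensity_scale == "log_compressed"
        assert seq.compression.dynamic_range == 60.0
        assert seq.compression.linear_ref is not None


class TestSimulateSweep:
    def test_sphere_closed_form_volume(self):
        _, analytic = sp.simulate_sweep({"solid": "sphere", "radius": 5.0})
        assert analytic == pytest.approx(4.0 / 3.0 * np.pi * 125.0, rel=1e-12)
        assert analytic == pytest.approx(523.60, abs=0.005)

    def test_box_closed_form_volume(self):
        _, analytic = sp.simulate_sweep({"solid": "box", "size": (2.0, 3.0, 4.0)})
        assert analytic == 24.0

    def test_sphere_discretization_within_two_percent(self):
        sweep, analytic = sp.simulate_sweep(
            {"solid": "sphere", "radius": 5.0}, step=0.2, pixel_spacing=0.1
        )
        assert sp.tumor_volume(sweep) == pytest.approx(analytic, rel=0.02)

    def test_subvoxel_solid_rejected(self):
        with pytest.raises(ValueError, match="smaller than one voxel"):
            sp.simulate_sweep({"solid": "box", "size": (0.01, 0.01, 0.01)},
                              step=0.2, pixel_spacing=0.1)


class TestSimulateCohort:
    def test_constant_null_effect_recovers_zero(self):
        records = sp.simulate_cohort(6, effect=1.0, seed=4, curves_only=True)
        _, res = sp.analyze_cohort(records)
        assert abs(res.mean) < 3.0

    def test_constant_half_effect_recovers_minus_fifty(self):
        records = sp.simulate_cohort(6, effect=0.5, seed=4, curves_only=True)
        comps, res = sp.analyze_cohort(records)
        for comp in comps:
            assert comp.delta_rr_pct == pytest.approx(-50.0, abs=3.0)

    def test_lognormal_multiplier_mean_matches_distribution(self):
        """Empirical mean of lognormal(ln 0.5, 0.2) draws vs the closed-form
        mean 0.5*exp(0.02) = 0.5101."""
        effect = {"dist": "lognormal", "mu": float(np.log(0.5)), "sigma": 0.2}
        records = sp.simulate_cohort(200, effect=effect, seed=11, curves_only=True)
        drawn = [r.ground_truth.beta_multiplier for r in records]
        assert np.mean(drawn) == pytest.approx(0.51, rel=0.05)

    def test_subject_seeds_derived_deterministically(self):
        r1 = sp.simulate_cohort(3, effect=0.5, seed=9, curves_only=True)
        r2 = sp.simulate_cohort(3, effect=0.5, seed=9, curves_only=True)
        for a, b in zip(r1, r2):
            assert a.config.seed == b.config.seed
            for lbl in a.tics:
                assert np.array_equal(a.tics[lbl].intensities, b.tics[lbl].intensities)

    def test_nonpositive_constant_multiplier_rejected(self, rng):
        with pytest.raises(ValueError):
            _draw_multiplier(rng, -0.5)

    def test_nonpositive_draws_redrawn(self, rng):
        value = _draw_multiplier(rng, {"dist": "normal", "mean": 0.05, "sd": 1.0})
        assert value > 0


class TestScenarioRoundTrip:
    def test_yaml_dict_round_trip(self, short_scenario, tmp_path):
        from sonoperf.io import load_config, save_config
        from sonoperf.simulate import scenario_from_dict, scenario_to_dict

        path = save_config(scenario_to_dict(short_scenario), tmp_path / "scenario.yaml")
        rebuilt = scenario_from_dict(load_config(path))
        assert rebuilt.flash_times == short_scenario.flash_times
        assert rebuilt.regions[0].label == "treated"
        a = sp.region_curve(short_scenario, "treated")
        b = sp.region_curve(rebuilt, "treated")
        assert np.array_equal(a, b)
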