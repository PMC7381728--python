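"""Paired pre/post treatment-effect analysis and cohort statistics."""

import itertools

import numpy as np
import pytest

import sonoperf as sp
from sonoperf.analysis import cohort_statistics
from sonoperf.model import NonConvergedError


def _fit(A=10.0, beta=0.05, y0=0.0):
    return sp.PerfusionFit(A=A, beta=beta, y0=y0, sse=0.0, r2=1.0, n_samples=100)


class TestComparePrePost:
    def test_identical_fits_give_zero_deltas(self):
        assert sp.compare_pre_post(_fit(), _fit()) == (0.0, 0.0)

    def test_halved_beta_is_minus_fifty(self):
        drr, drbv = sp.compare_pre_post(_fit(beta=0.05), _fit(beta=0.025))
        assert drr == pytest.approx(-50.0)
        assert drbv == 0.0

    def test_reported_magnitude_decrease(self):
        """beta 0.05 -> 0.0105 is a 79.0% RR decrease."""
        drr, _ = sp.compare_pre_post(_fit(beta=0.05), _fit(beta=0.0105))
        assert drr == pytest.approx(-79.0)

    def test_nonconverged_input_carries_reason(self):
        bad = sp.PerfusionFit(A=0, beta=float("nan"), y0=0, sse=0, r2=0,
                              n_samples=5, converged=False, reason="unidentifiable beta")
        with pytest.raises(NonConvergedError, match="unidentifiable"):
            sp.compare_pre_post(bad, _fit())


class TestControlNormalize:
    def test_difference_mode_passthrough_when_control_flat(self):
        assert sp.control_normalize((-50.0, 0.0), (0.0, 0.0)) == (-50.0, 0.0)

    def test_difference_mode_cancels_systemic_drift(self):
        assert sp.control_normalize((20.0, 5.0), (20.0, 5.0)) == (0.0, 0.0)

    def test_ratio_mode(self):
        """treated post/pre 0.5 against control 1.25 -> 100*(0.4-1) = -60."""
        out = sp.control_normalize((-50.0, 0.0), (25.0, 0.0), mode="ratio")
        assert out[0] == pytest.approx(-60.0)

    def test_ratio_mode_zero_control_rejected(self):
        with pytest.raises(ZeroDivisionError):
            sp.control_normalize((-50.0, 0.0), (-100.0, 0.0), mode="ratio")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            sp.control_normalize((0.0, 0.0), (0.0, 0.0), mode="bogus")


class TestMonitoringPipeline:
    def test_constructed_effect_recovered(self):
        """beta multiplier 0.5 on the treated ROI, low noise: normalized
        Delta-RR = -50 +/- 3."""
        cfg = sp.default_scenario(seed=1, noise_scale=0.1, beta_multiplier=0.5)
        seq, _ = sp.simulate_sequence(cfg)
        comp = sp.run_monitoring_pipeline(seq, masks=cfg.masks(), subject_id="s1")
        assert not comp.qc
        assert comp.delta_rr_pct == pytest.approx(-50.0, abs=3.0)

    def test_null_subject_centers_at_zero(self):
        cfg = sp.default_scenario(seed=2, noise_scale=0.1, beta_multiplier=1.0)
        seq, _ = sp.simulate_sequence(cfg)
        comp = sp.run_monitoring_pipeline(seq, masks=cfg.masks())
        assert comp.delta_rr_pct == pytest.approx(0.0, abs=3.0)

    def test_protocol_flashes_autodetected_as_anchors(self):
        cfg = sp.default_scenario(seed=3, noise_scale=0.1)
        seq, _ = sp.simulate_sequence(cfg)
        comp = sp.run_monitoring_pipeline(seq, masks=cfg.masks())
        assert comp.flash_times[0] == pytest.approx(300.0, abs=0.26)
        assert comp.flash_times[1] == pytest.approx(630.0, abs=0.26)

    def test_single_flash_without_config_errors(self, short_scenario):
        seq, _ = sp.simulate_sequence(short_scenario)
        with pytest.raises(ValueError, match="two flash events"):
            sp.run_monitoring_pipeline(seq, masks=short_scenario.masks())

    def test_tic_dict_input_equivalent_to_sequence(self):
        cfg = sp.default_scenario(seed=4, noise_scale=0.0, beta_multiplier=0.5)
        cfg.noise.model = "none"
        seq, _ = sp.simulate_sequence(cfg)
        masks = cfg.masks()
        proto = sp.ProtocolConfig(flash_times=(300.0, 630.0))
        from_seq = sp.run_monitoring_pipeline(seq, masks=masks, protocol=proto)
        tics = {lbl: sp.extract_tic(seq, masks, lbl) for lbl in ("treated", "control")}
        from_tics = sp.run_monitoring_pipeline(tics, protocol=proto)
        assert from_tics.delta_rr_pct == pytest.approx(from_seq.delta_rr_pct, rel=1e-12)

    def test_pre_post_pair_input(self):
        """Two separate acquisitions, one flash each, fit as pre and post."""
        pre_cfg = sp.default_scenario(seed=5, noise_scale=0.0)
        pre_cfg.noise.model = "none"
        pre_cfg.n_frames, pre_cfg.flash_times = 1600, (100.0,)
        post_cfg = sp.default_scenario(seed=6, noise_scale=0.0)
        post_cfg.noise.model = "none"
        post_cfg.n_frames, post_cfg.flash_times = 1600, (100.0,)
        post_cfg.treatment = sp.Treatment("treated", 0.5, after_flash_index=-1)
        pre_seq, _ = sp.simulate_sequence(pre_cfg)
        post_seq, _ = sp.simulate_sequence(post_cfg)
        comp = sp.run_monitoring_pipeline(
            (pre_seq, post_seq), masks=pre_cfg.masks(),
            protocol=sp.ProtocolConfig(flash_times=(100.0,)),
        )
        assert comp.delta_rr_pct == pytest.approx(-50.0, abs=1.0)

    def test_determinism_byte_identical_tables(self, tmp_path):
        cfg = sp.default_scenario(seed=7, noise_scale=0.1, beta_multiplier=0.5)
        seq, _ = sp.simulate_sequence(cfg)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        for out in (out1, out2):
            sp.run_monitoring_pipeline(seq, masks=cfg.masks(), subject_id="s", outdir=out)
        assert (out1 / "s_fits.csv").read_bytes() == (out2 / "s_fits.csv").read_bytes()

    def test_artifacts_written(self, tmp_path):
        cfg = sp.default_scenario(seed=8, noise_scale=0.1)
        seq, _ = sp.simulate_sequence(cfg)
        sp.run_monitoring_pipeline(seq, masks=cfg.masks(), subject_id="s", outdir=tmp_path)
        assert (tmp_path / "tic_treated.csv").exists()
        assert (tmp_path / "tic_control.csv").exists()
        assert (tmp_path / "s_fits.csv").exists()


def wilcoxon_exact_enumeration(diffs):
    """Exhaustive signed-rank null: two-sided p of W+ for small n."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_plus = float(ranks[diffs > 0].sum())
    w_all = []
    for signs in itertools.product((0, 1), repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.asarray(w_all)
    mean_w = n * (n + 1) / 4.0
    observed_dev = abs(w_plus - mean_w)
    p = np.mean(np.abs(w_all - mean_w) >= observed_dev - 1e-12)
    return w_plus, float(p)


class TestCohortStatistics:
    def _comps(self, deltas):
        comps = []
        for i, d in enumerate(deltas):
            comp = sp.TreatmentComparison(
                subject_id=f"s{i}", fits={},
                delta_treated=(d, 0.0), delta_control=(0.0, 0.0),
                normalized=(d, 0.0),
            )
            comps.append(comp)
        return comps

    def test_constant_deltas(self):
        res = cohort_statistics(self._comps([-50.0] * 6))
        assert res.mean == pytest.approx(-50.0)
        assert res.sd == 0.0

    def test_wilcoxon_matches_exhaustive_enumeration(self):
        """Signed-rank p for differences {1, 2, 3, -4, 5} equals the
        brute-force enumeration over all 2^5 sign patterns."""
        diffs = [1.0, 2.0, 3.0, -4.0, 5.0]
        _, p_oracle = wilcoxon_exact_enumeration(diffs)
        res = cohort_statistics(self._comps(diffs))
        assert res.wilcoxon_p == pytest.approx(p_oracle, rel=1e-12)

    def test_all_zero_differences_reported_undefined(self):
        res = cohort_statistics(self._comps([0.0] * 5))
        assert res.wilcoxon_p is None
        assert "undefined" in res.wilcoxon_note

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError, match=">= 2"):
            cohort_statistics(self._comps([-50.0]))

    def test_qc_flagged_subjects_excluded(self):
        comps = self._comps([-50.0, -48.0, -52.0])
        comps.append(
            sp.TreatmentComparison(subject_id="bad", fits={}, qc=["treated/pre: x"])
        )
        res = cohort_statistics(comps)
        assert res.n == 3

    def test_primary_test_switches_with_cohort_size(self):
        small = cohort_statistics(self._comps([-50, -48, -52, -49, -51.0]))
        assert small.primary_test == "wilcoxon"
        big = cohort_statistics(self._comps(list(np.linspace(-55, -45, 12))))
        assert big.primary_test == "t"


class TestCohortRecovery:
    def test_effect_direction_monotone_in_multiplier(self):
        """Larger beta multipliers never map to smaller recovered Delta-RR."""
        medians = []
        for m in (0.5, 1.0, 2.0):
            records = sp.simulate_cohort(4, effect=m, seed=21, curves_only=True)
            comps, _ = sp.analyze_cohort(records)
            medians.append(np.median([c.delta_rr_pct for c in comps]))
        assert medians[0] < medians[1] < medians[2]

    def test_power_at_half_multiplier(self):
        """n=8 cohorts with multiplier 0.5 reject the null in >= 90% of runs."""
        rejections = 0
        reps = 20
        for rep in range(reps):
            records = sp.simulate_cohort(8, effect=0.5, seed=3000 + rep, curves_only=True)
            _, res = sp.analyze_cohort(records)
            if res.primary_p < 0.05:
                rejections += 1
        assert rejections >= 0.9 * reps
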