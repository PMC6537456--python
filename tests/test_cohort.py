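"""Synthetic cohort generator: truth draws, rendering, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from myofatigue import (GeneratorConfig, draw_subject_truth, generate_cohort,
                        render_swe_clip, render_twitch)
from myofatigue.calibration import QuantityCalibration
from myofatigue.cohort import render_mvc_trial
from myofatigue.elastography import roi_frame_modulus
from myofatigue.errors import InvalidCalibrationError, InvalidTruthError
from myofatigue.signals import RESTING, SUPERIMPOSED
from myofatigue.torque import doublet_amplitude
from myofatigue.twitch import solve_twitch_shape


def _zero_sd_config() -> GeneratorConfig:
    return GeneratorConfig().noiseless()


class TestDrawSubjectTruth:
    def test_degenerate_draw_follows_generative_identity(self, rng):
        """With all SDs at zero every subject's trajectory is
        B * (1 + d * g(t)) with B and d at the configured means."""
        cfg = _zero_sd_config()
        truth = draw_subject_truth(cfg, 0, rng)
        traj = np.array([352, 270, 226, 208, 202, 192, 211], dtype=float)
        g = (traj / traj[0] - 1.0) / (traj[-1] / traj[0] - 1.0)
        expected = 352.0 * (1.0 - 0.384 * g)
        np.testing.assert_allclose(truth.values["mvc"], expected, rtol=1e-12)

    def test_unchanged_quantity_is_flat(self, rng):
        cfg = _zero_sd_config()
        truth = draw_subject_truth(cfg, 0, rng)
        np.testing.assert_array_equal(truth.values["mmax"],
                                      np.full(7, 5.2))
        np.testing.assert_array_equal(truth.values["val"],
                                      np.full(7, 89.0))

    def test_monte_carlo_recovers_configured_end_change(self):
        """Mean per-subject end change over many draws matches the
        configured value (generative identity, modulus)."""
        cfg = GeneratorConfig()
        rngs = np.random.default_rng(99).spawn(10_000)
        chg = np.empty(len(rngs))
        for i, r in enumerate(rngs):
            v = draw_subject_truth(cfg, i, r).values["mu"]
            chg[i] = 100.0 * (v[6] / v[0] - 1.0)
        assert abs(chg.mean() + 34.7) < 0.2

    def test_positivity_and_val_bounds(self):
        cfg = GeneratorConfig()
        for r in np.random.default_rng(3).spawn(200):
            t = draw_subject_truth(cfg, 0, r)
            for q, v in t.values.items():
                assert np.all(v > 0), q
            assert np.all(t.values["val"] <= 100.0)
            # twitch shape factor stays solvable at every time point
            s = t.values["mrtd"] * t.values["ct"] / t.values["tw_pot"]
            assert np.all((s > 1.44) & (s < 4.6))

    def test_invalid_calibration_rejected(self):
        with pytest.raises(InvalidCalibrationError):
            QuantityCalibration("bad", "Nm", -1.0, 2.0, (1.0,) * 7)


class TestRenderTwitch:
    SHAPE = solve_twitch_shape(47.7, 128.2, 4.8 / 77.9)

    def test_noiseless_peak_and_timing(self):
        tr = render_twitch(self.SHAPE, 77.9, 28.8, t_stim=0.5)
        assert tr.samples.max() == pytest.approx(77.9, rel=2e-3)
        i_pk = int(np.argmax(tr.samples))
        ct_measured = (i_pk / tr.rate - 0.5 - 0.0288) * 1000.0
        assert abs(ct_measured - 47.7) <= 1000.0 / tr.rate  # one sample

    def test_zero_peak_gives_zero_trace(self):
        tr = render_twitch(self.SHAPE, 0.0, 28.8)
        assert np.all(tr.samples == 0.0)

    def test_peak_extraction_unbiased_under_noise(self):
        from myofatigue import twitch_properties
        rng = np.random.default_rng(8)
        peaks = []
        for _ in range(100):
            tr = render_twitch(self.SHAPE, 77.9, 28.8, noise_sd=0.05,
                               rng=rng)
            peaks.append(twitch_properties(tr, 0.5).p)
        assert abs(np.mean(peaks) - 77.9) < 0.05


class TestRenderMvcTrial:
    def test_full_activation_means_no_increment(self, rng):
        cfg = _zero_sd_config()
        truth = draw_subject_truth(cfg, 0, rng)
        truth.values["val"] = np.full(7, 100.0)
        torque, _ = render_mvc_trial(truth, 0, cfg, rng)
        sup = torque.events_of(context=SUPERIMPOSED)[0]
        assert doublet_amplitude(torque, sup.time, SUPERIMPOSED) == \
            pytest.approx(0.0, abs=1e-9)

    def test_superimposed_increment_amplitude(self, rng):
        """Increment = Db_pot * (1 - VAL/100): 114.3 * 0.11 = 12.57 Nm."""
        cfg = _zero_sd_config()
        truth = draw_subject_truth(cfg, 0, rng)
        torque, _ = render_mvc_trial(truth, 0, cfg, rng)
        sup = torque.events_of(context=SUPERIMPOSED)[0]
        inc = doublet_amplitude(torque, sup.time, SUPERIMPOSED)
        assert inc == pytest.approx(114.3 * (1 - 89.0 / 100.0), rel=5e-3)

    def test_noiseless_resting_doublet_amplitude_exact(self, rng):
        cfg = _zero_sd_config()
        truth = draw_subject_truth(cfg, 0, rng)
        torque, _ = render_mvc_trial(truth, 0, cfg, rng)
        db = torque.events_of(context=RESTING, kind="doublet100Hz")[0]
        assert doublet_amplitude(torque, db.time, RESTING) == \
            pytest.approx(114.3, rel=2e-3)

    def test_event_log_grouping(self, rng):
        cfg = _zero_sd_config()
        truth = draw_subject_truth(cfg, 0, rng)
        torque, emg = render_mvc_trial(truth, 0, cfg, rng)
        kinds = [(ev.kind, ev.context) for ev in torque.events]
        assert kinds == [("doublet100Hz", "superimposed"),
                         ("doublet100Hz", "resting"),
                         ("single", "resting")]
        times = [ev.time for ev in torque.events]
        assert times == sorted(times)

    def test_invalid_val_rejected(self, rng):
        cfg = _zero_sd_config()
        truth = draw_subject_truth(cfg, 0, rng)
        truth.values["val"] = np.full(7, 140.0)
        with pytest.raises(InvalidTruthError):
            render_mvc_trial(truth, 0, cfg, rng)


class TestRenderSweClip:
    def test_noiseless_pixels_and_modulus(self, rng):
        cfg = _zero_sd_config()
        clip = render_swe_clip(9.3, cfg, rng)
        for f in clip.frames:
            np.testing.assert_allclose(f, np.sqrt(9.3))
        np.testing.assert_allclose(roi_frame_modulus(clip), 9.3, rtol=1e-12)

    def test_unit_speed(self, rng):
        clip = render_swe_clip(1.0, _zero_sd_config(), rng)
        assert clip.frames[0][0, 0] == pytest.approx(1.0)

    def test_frame_to_frame_modulus_scatter(self, rng):
        """Error propagation: SD of the five frame-ROI means per clip is
        ~ 2*Vs*sqrt(frame_sd^2 + pixel_sd^2/n_roi) ~ 0.26-0.29 kPa."""
        cfg = GeneratorConfig()
        sds = [np.std(roi_frame_modulus(render_swe_clip(9.3, cfg, rng)),
                      ddof=1) for _ in range(1000)]
        assert np.mean(sds) == pytest.approx(0.26, rel=0.15)

    def test_nonpositive_modulus_rejected(self, rng):
        with pytest.raises(InvalidTruthError):
            render_swe_clip(0.0, GeneratorConfig(), rng)


class TestGenerateCohort:
    def test_seed_determinism_byte_identical(self, small_config):
        a = generate_cohort(small_config, seed=1)
        b = generate_cohort(small_config, seed=1)
        for ta, tb in zip(a.truths, b.truths):
            for q in ta.values:
                np.testing.assert_array_equal(ta.values[q], tb.values[q])
        for sa, sb in zip(a.sessions, b.sessions):
            for xa, xb in zip(sa, sb):
                np.testing.assert_array_equal(xa.torque.samples,
                                              xb.torque.samples)
                np.testing.assert_array_equal(xa.emg_vl.samples,
                                              xb.emg_vl.samples)
                for fa, fb in zip(xa.swe.frames, xb.swe.frames):
                    np.testing.assert_array_equal(fa, fb)

    def test_control_mvc_near_calibration(self, default_config):
        cohort = generate_cohort(default_config, seed=0)
        ctrl = np.array([t.at("mvc", 0) for t in cohort.truths])
        assert abs(ctrl.mean() - 352.0) < 2 * 68.0 / np.sqrt(15)

    def test_degenerate_cohort_subjects_identical(self, noiseless_small_cohort):
        truths = noiseless_small_cohort.truths
        for q in truths[0].values:
            for other in truths[1:]:
                np.testing.assert_array_equal(truths[0].values[q],
                                              other.values[q])
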