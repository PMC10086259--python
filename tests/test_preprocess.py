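"""Reduction chain: filtering, rejection, blink removal, interpolation,
referencing, baseline, plus-minus noise, evoked averaging."""

import numpy as np
import pandas as pd
import pytest

from ihtt.montage import EVENT_COLUMNS, ContinuousRecording
from ihtt.preprocess import (
    RejectionThresholds,
    average_reference,
    baseline_correct,
    default_blink_templates,
    detect_bad_channels,
    filter_recording,
    interpolate_channels,
    make_evoked,
    preprocess_session,
    reject_trials,
    remove_blink_components,
    residual_noise_rms,
    segment,
)
from ihtt.simulate import SimulationParams, blink_pattern, simulate_session
from ihtt.task import TaskConfig, generate_schedule
from tests.conftest import make_epochs

TH = RejectionThresholds()


def _recording(montage, data):
    return ContinuousRecording(data, 1000.0, montage,
                               pd.DataFrame(columns=EVENT_COLUMNS))


class TestFilter:
    def test_passband_and_stopband(self, montage):
        t = np.arange(20000) / 1000.0
        mid = slice(3000, 17000)
        for f, bound, kind in [(5.0, 0.05, "pass"), (50.0, 0.10, "stop")]:
            x = np.tile(np.sin(2 * np.pi * f * t), (128, 1))
            out = filter_recording(_recording(montage, x)).data
            gain = out[0, mid].std() / x[0, mid].std()
            if kind == "pass":
                assert abs(gain - 1) < bound
            else:
                assert gain < bound  # >= 90% attenuation

    def test_white_noise_spectrum_matches_squared_magnitude(self, montage):
        # FFT oracle: output spectrum = input spectrum x |H_hp|^2 |H_lp|^2
        from scipy import fft as sfft, signal as sps

        rng = np.random.default_rng(0)
        x = rng.standard_normal((128, 8000))
        out = filter_recording(_recording(montage, x)).data
        freqs = sfft.rfftfreq(8000, 1 / 1000)
        gain = np.ones_like(freqs)
        for kind, fc in (("highpass", 0.1), ("lowpass", 15.0)):
            sos = sps.butter(4, fc, btype=kind, fs=1000, output="sos")
            _, h = sps.sosfreqz(sos, worN=freqs, fs=1000)
            gain *= np.abs(h) ** 2
        expected = sfft.irfft(sfft.rfft(x[3]) * gain, n=8000)
        np.testing.assert_allclose(out[3], expected, atol=1e-8)

    def test_iir_realization_agrees_in_passband(self, montage):
        # both realizations pass a 5 Hz tone at unit gain; they differ only
        # by the IIR edge transients of the 0.1 Hz high-pass stage
        t = np.arange(20000) / 1000.0
        x = np.tile(np.sin(2 * np.pi * 5 * t), (128, 1))
        a = filter_recording(_recording(montage, x), realization="fft").data
        b = filter_recording(_recording(montage, x), realization="iir").data
        mid = slice(5000, 15000)
        gain_a = a[0, mid].std() / x[0, mid].std()
        gain_b = b[0, mid].std() / x[0, mid].std()
        assert abs(gain_a - 1) < 0.01 and abs(gain_b - 1) < 0.01
        assert abs(gain_a - gain_b) < 0.01

    def test_lowpass_above_nyquist_rejected(self, montage):
        with pytest.raises(ValueError, match="Nyquist"):
            filter_recording(_recording(montage, np.zeros((128, 1000))),
                             lp_hz=600.0)


class TestSegment:
    def _events(self, onsets, vfs):
        n = len(onsets)
        return pd.DataFrame({
            "trial_id": np.arange(1, n + 1),
            "onset_sample": onsets,
            "block": 1,
            "visual_field": vfs,
            "match": True,
            "response_hand": "left",
            "response": "match",
            "rt_ms": 500.0,
            "correct": True,
        })[EVENT_COLUMNS]

    def test_epoch_window_slicing(self, montage):
        data = np.tile(np.arange(8000, dtype=float), (128, 1))
        rec = ContinuousRecording(data, 1000.0, montage,
                                  self._events([5000], ["LVF"]))
        ep = segment(rec)
        assert ep.data.shape == (1, 128, 1200)
        np.testing.assert_array_equal(ep.data[0, 0], np.arange(4800, 6000))

    def test_bilateral_and_practice_trials_excluded(self, montage):
        ev = self._events([2000, 4000, 6000], ["LVF", "bilateral", "RVF"])
        ev.loc[2, "block"] = 0  # practice
        rec = ContinuousRecording(np.zeros((128, 9000)), 1000.0, montage, ev)
        ep = segment(rec)
        assert ep.n_trials == 1
        assert list(ep.meta["visual_field"]) == ["LVF"]

    def test_edge_trial_flagged(self, montage):
        rec = ContinuousRecording(np.zeros((128, 3000)), 1000.0, montage,
                                  self._events([100, 2500], ["LVF", "RVF"]))
        ep = segment(rec)
        assert ep.trial_status == ["rejected:edge", "rejected:edge"]

    def test_epoch_count_matches_schedule_unilateral_count(self, montage):
        cfg = TaskConfig(n_blocks=1, trials_per_block=24, n_practice=4)
        sched = generate_schedule(cfg, seed=3)
        rec, events, _ = simulate_session(
            SimulationParams(noise_rms_uv=1.0, seed=5), sched, task_config=cfg
        )
        ep = segment(rec)
        expected = sum(
            t.visual_field in ("LVF", "RVF") and not t.practice for t in sched
        )
        assert ep.n_trials == expected


class TestRejectTrials:
    def test_amplitude_rule(self, epochs_factory):
        data = np.zeros((2, 128, 1200))
        data[0, 10, 600] = 120.0
        ep = reject_trials(epochs_factory(data), TH)
        assert ep.trial_status[0] == "rejected:amplitude"
        assert ep.trial_status[1] == "retained"

    def test_transition_rule_with_brute_force_oracle(self, epochs_factory):
        rng = np.random.default_rng(4)
        data = 20 * rng.standard_normal((8, 128, 1200))
        data[2, 50, 700] += 130.0  # one big step up and down
        ep = reject_trials(epochs_factory(data), TH)
        scalp = ep.montage.scalp_rows
        for i in range(8):
            x = data[i][scalp]
            exceed_amp = np.abs(x).max() > 100
            exceed_step = np.abs(np.diff(x, axis=1)).max() > 100
            expected = "retained"
            if exceed_amp:
                expected = "rejected:amplitude"
            elif exceed_step:
                expected = "rejected:transition"
            assert ep.trial_status[i] == expected

    def test_eye_channel_rule(self, epochs_factory, montage):
        data = np.zeros((1, 128, 1200))
        data[0, montage.eye_rows[0], 300] = 80.0
        ep = reject_trials(epochs_factory(data), TH)
        assert ep.trial_status[0] == "rejected:eye"

    def test_all_zero_epoch_retained(self, epochs_factory):
        ep = reject_trials(epochs_factory(np.zeros((1, 128, 1200))), TH)
        assert ep.trial_status[0] == "retained"

    def test_rejection_monotone_in_thresholds(self, epochs_factory):
        rng = np.random.default_rng(9)
        data = 45 * rng.standard_normal((12, 128, 1200))
        loose = reject_trials(epochs_factory(data), TH)
        tight = reject_trials(
            epochs_factory(data),
            RejectionThresholds(epoch_abs_uv=60, transition_uv=60, eye_abs_uv=40),
        )
        assert tight.retained.sum() <= loose.retained.sum()
        # every trial retained under tight thresholds survives loose ones
        assert np.all(loose.retained[tight.retained])


class TestBlinkRemoval:
    def test_rank_one_blink_removed(self, montage, epochs_factory):
        rng = np.random.default_rng(5)
        pat = blink_pattern(montage)
        course = 80 * rng.standard_normal((6, 1200))
        data = np.einsum("c,ts->tcs", pat, course)
        data += 0.5 * rng.standard_normal(data.shape)
        ep = epochs_factory(data)
        out = remove_blink_components(ep, default_blink_templates(montage))
        assert out.flags["blink_components_removed"] >= 1
        assert np.sqrt((out.data**2).mean()) < 0.05 * np.sqrt((data**2).mean())

    def test_below_threshold_component_kept(self, montage, epochs_factory):
        rng = np.random.default_rng(6)
        # build a pattern correlating ~0.85 with the blink templates
        tpl = default_blink_templates(montage)[0].pattern
        z = (tpl - tpl.mean()) / tpl.std()
        q = rng.standard_normal(128)
        q = (q - q.mean())
        q -= (q @ z) / (z @ z) * z
        q /= q.std()
        pat = 0.85 * z + np.sqrt(1 - 0.85**2) * q
        for t in default_blink_templates(montage):
            r = np.corrcoef(pat, t.pattern)[0, 1]
            assert abs(r) < 0.9
        course = 50 * rng.standard_normal((6, 1200))
        data = np.einsum("c,ts->tcs", pat, course)
        data += 0.5 * rng.standard_normal(data.shape)
        out = remove_blink_components(epochs_factory(data),
                                      default_blink_templates(montage))
        assert out.flags["blink_components_removed"] == 0
        # data unchanged
        np.testing.assert_allclose(out.data, data)

    def test_two_source_mix_preserves_signal(self, montage, epochs_factory):
        # known mixing of a blink source and a dipolar signal source; after
        # removal, unmix with the known matrix and check the signal source
        rng = np.random.default_rng(7)
        blink = blink_pattern(montage)
        from ihtt.simulate import component_patterns

        sig = component_patterns(montage)["right"]
        t = np.arange(1200) / 1000.0
        n_tr = 20
        s_blink = np.zeros((n_tr, 1200))
        for i in range(n_tr):  # blink bursts at random latencies
            o = rng.integers(0, 900)
            s_blink[i, o : o + 300] = rng.uniform(60, 140) * np.hanning(300)
        s_sig = 8 * np.sin(2 * np.pi * 7 * t + rng.uniform(0, 2 * np.pi,
                                                           (n_tr, 1)))
        data = (np.einsum("c,ts->tcs", blink, s_blink)
                + np.einsum("c,ts->tcs", sig, s_sig))
        data += 0.1 * rng.standard_normal(data.shape)
        out = remove_blink_components(epochs_factory(data),
                                      default_blink_templates(montage))
        assert out.flags["blink_components_removed"] >= 1
        mix = np.c_[blink, sig]  # channels x 2
        unmix = np.linalg.pinv(mix)
        rec_sig = np.einsum("kc,tcs->tks", unmix, out.data)[:, 1, :]
        err = np.sqrt(((rec_sig - s_sig) ** 2).mean())
        assert err < 0.10 * np.sqrt((s_sig**2).mean())


class TestBadChannels:
    def test_clamped_channel_flagged(self, epochs_factory, montage):
        data = np.zeros((3, 128, 1200))
        data[:, montage.row(40), :] = 150.0
        assert 40 in detect_bad_channels(epochs_factory(data), TH)

    def test_all_zero_gives_empty_set(self, epochs_factory):
        assert detect_bad_channels(epochs_factory(np.zeros((2, 128, 1200))),
                                   TH) == set()

    def test_differential_rule_hand_computed(self, epochs_factory, montage):
        # channel 12 swings +-60 around a zero mean waveform across trials:
        # fast average = 60 (< 100), differential average = 60 (> 50)
        data = np.zeros((4, 128, 1200))
        row = montage.row(12)
        data[0, row], data[1, row] = 60.0, -60.0
        data[2, row], data[3, row] = 60.0, -60.0
        flagged = detect_bad_channels(epochs_factory(data), TH)
        assert flagged == {12}

    def test_eye_channels_exempt(self, epochs_factory, montage):
        data = np.zeros((2, 128, 1200))
        data[:, montage.eye_rows[0], :] = 150.0
        assert detect_bad_channels(epochs_factory(data), TH) == set()


class TestInterpolation:
    def test_constant_neighbors_give_constant(self, epochs_factory, montage):
        data = np.full((2, 128, 1200), 3.0)
        out = interpolate_channels(epochs_factory(data), {40})
        np.testing.assert_allclose(out.data[:, montage.row(40)], 3.0)
        assert out.channel_status[montage.row(40)] == "interpolated"

    def test_matches_hand_computed_weights(self, epochs_factory, montage):
        from ihtt.montage import nearest_neighbors

        rng = np.random.default_rng(8)
        data = rng.standard_normal((3, 128, 1200))
        bad = 57
        out = interpolate_channels(epochs_factory(data), {bad})
        nbrs = nearest_neighbors(montage, bad, 6)
        p = montage.positions[montage.row(bad)]
        d = np.array([
            np.arccos(np.clip(montage.positions[montage.row(j)] @ p, -1, 1))
            for j in nbrs
        ])
        w = (1 / d) / (1 / d).sum()
        expected = sum(
            w[k] * data[:, montage.row(j), :] for k, j in enumerate(nbrs)
        )
        np.testing.assert_allclose(out.data[:, montage.row(bad)], expected)

    def test_quality_floor(self, epochs_factory):
        data = np.zeros((1, 128, 1200))
        with pytest.raises(ValueError, match="quality floor"):
            interpolate_channels(epochs_factory(data), set(range(1, 29)))


class TestReferenceAndBaseline:
    def test_average_reference_zero_mean(self, epochs_factory):
        rng = np.random.default_rng(10)
        ep = epochs_factory(rng.standard_normal((3, 128, 1200)))
        out = average_reference(ep)
        scalp = out.montage.scalp_rows
        assert np.abs(out.data[:, scalp, :].mean(axis=1)).max() < 1e-9

    def test_average_reference_idempotent(self, epochs_factory):
        rng = np.random.default_rng(11)
        ep = average_reference(epochs_factory(rng.standard_normal((2, 128, 1200))))
        out = average_reference(ep)
        np.testing.assert_allclose(out.data, ep.data, atol=1e-12)

    def test_average_reference_closed_form(self, epochs_factory, montage):
        # two scalp channels at +a/-a, all else zero: each loses the pair mean
        data = np.zeros((1, 128, 1200))
        r1, r2 = montage.scalp_rows[:2]
        data[0, r1], data[0, r2] = 6.0, -2.0
        out = average_reference(epochs_factory(data))
        n_scalp = len(montage.scalp_rows)
        mean = (6.0 - 2.0) / n_scalp
        np.testing.assert_allclose(out.data[0, r1], 6.0 - mean)
        np.testing.assert_allclose(out.data[0, r2], -2.0 - mean)

    def test_baseline_constant_epoch_zeroed(self, epochs_factory):
        out = baseline_correct(epochs_factory(np.full((2, 128, 1200), 7.0)))
        np.testing.assert_allclose(out.data, 0.0)

    def test_baseline_ramp_closed_form(self, epochs_factory, times_ms):
        # v(t) = t: baseline mean over [-200, 0) is (-200 + -1)/2 = -100.5
        data = np.tile(times_ms, (1, 128, 1)).astype(float)
        out = baseline_correct(epochs_factory(data))
        np.testing.assert_allclose(out.data[0, 0], times_ms + 100.5)

    def test_zero_mean_baseline_unchanged(self, epochs_factory, times_ms):
        rng = np.random.default_rng(12)
        data = rng.standard_normal((1, 128, 1200))
        base = times_ms < 0
        data[:, :, base] -= data[:, :, base].mean(axis=2, keepdims=True)
        out = baseline_correct(epochs_factory(data.copy()))
        np.testing.assert_allclose(out.data, data, atol=1e-12)


class TestResidualNoise:
    def test_identical_trials_cancel(self, epochs_factory):
        rng = np.random.default_rng(13)
        one = rng.standard_normal((128, 1200))
        ep = epochs_factory(np.stack([one] * 6))
        assert residual_noise_rms(ep, 65) == pytest.approx(0.0, abs=1e-12)

    def test_iid_noise_scales_as_sigma_over_sqrt_n(self, epochs_factory):
        rng = np.random.default_rng(14)
        sigma, n = 4.0, 100
        ep = epochs_factory(sigma * rng.standard_normal((n, 128, 1200)))
        measured = residual_noise_rms(ep, 65)
        expected = sigma / np.sqrt(n)
        assert abs(measured - expected) / expected < 0.20

    def test_odd_trial_dropped(self, epochs_factory):
        rng = np.random.default_rng(15)
        data = rng.standard_normal((5, 128, 1200))
        ep5 = epochs_factory(data)
        ep4 = epochs_factory(data[:4])
        assert residual_noise_rms(ep5, 90) == residual_noise_rms(ep4, 90)

    def test_too_few_trials_raises(self, epochs_factory):
        with pytest.raises(ValueError):
            residual_noise_rms(epochs_factory(np.zeros((1, 128, 1200))), 65)


class TestMakeEvoked:
    def test_identical_epochs_equal_evoked(self, epochs_factory):
        rng = np.random.default_rng(16)
        one = rng.standard_normal((128, 1200))
        ev = make_evoked(epochs_factory(np.stack([one] * 6)), "LVF")
        np.testing.assert_allclose(ev.data, one)
        assert ev.usable

    def test_small_cell_not_usable(self, epochs_factory):
        ev = make_evoked(epochs_factory(np.zeros((4, 128, 1200))), "LVF")
        assert ev.n_trials == 4 and not ev.usable

    def test_mean_matches_oracle_and_excludes_incorrect(self, epochs_factory):
        rng = np.random.default_rng(17)
        data = rng.standard_normal((6, 128, 1200))
        correct = [True, True, False, True, True, True]
        ep = epochs_factory(data, correct=correct)
        ev = make_evoked(ep, "LVF")
        oracle = data[[0, 1, 3, 4, 5]].mean(axis=0)
        np.testing.assert_allclose(ev.data, oracle)
        assert ev.n_trials == 5

    def test_empty_cell_raises(self, epochs_factory):
        ep = epochs_factory(np.zeros((2, 128, 1200)))
        with pytest.raises(ValueError, match="RVF"):
            make_evoked(ep, "RVF")


class TestPipeline:
    def test_deterministic_rerun(self):
        cfg = TaskConfig(n_blocks=1, trials_per_block=12, n_practice=0,
                         pair_weights=(0.5, 0.5, 0, 0, 0, 0))
        sched = generate_schedule(cfg, seed=6)
        rec, events, _ = simulate_session(SimulationParams(seed=31), sched,
                                          task_config=cfg)
        ep1, ev1 = preprocess_session(rec)
        ep2, ev2 = preprocess_session(rec)
        np.testing.assert_array_equal(ep1.data, ep2.data)
        assert ep1.trial_status == ep2.trial_status
        for vf in ev1:
            np.testing.assert_array_equal(ev1[vf].data, ev2[vf].data)

    def test_noiseless_chain_preserves_transfer_difference(self, montage):
        from ihtt.scoring import score_session

        cfg = TaskConfig(n_blocks=1, trials_per_block=20, n_practice=0,
                         pair_weights=(0.5, 0.5, 0, 0, 0, 0))
        sched = generate_schedule(cfg, seed=7)
        p = SimulationParams(noise_rms_uv=0.0, blink_rate_hz=0.0,
                             accuracy_p=1.0, seed=32)
        rec, events, truth = simulate_session(p, sched, task_config=cfg)
        epochs, evokeds = preprocess_session(rec)
        res = score_session(epochs, evokeds, events)
        assert res.p1_ihtt_ms == pytest.approx(34.0, abs=1e-9)
        assert res.n1_ihtt_ms == pytest.approx(34.0, abs=1e-9)

    def test_unfiltered_chain_preserves_absolute_latencies(self, montage):
        # without the band-pass (which slightly displaces overlapping
        # bumps), evoked extrema sit exactly at the injected latencies
        from ihtt.scoring import detect_peak

        cfg = TaskConfig(n_blocks=1, trials_per_block=12, n_practice=0,
                         pair_weights=(1, 0, 0, 0, 0, 0))
        sched = generate_schedule(cfg, seed=8)
        p = SimulationParams(noise_rms_uv=0.0, blink_rate_hz=0.0,
                             accuracy_p=1.0, seed=33)
        rec, events, _ = simulate_session(p, sched, task_config=cfg)
        ep = segment(rec)
        ep = reject_trials(ep, TH)
        ep = average_reference(ep)
        ep = baseline_correct(ep)
        ev = make_evoked(ep, "LVF")
        assert detect_peak(ev, "P1", 90).latency_ms == 95.0
        assert detect_peak(ev, "P1", 65).latency_ms == 129.0
        assert detect_peak(ev, "N1", 90).latency_ms == 165.0
        assert detect_peak(ev, "N1", 65).latency_ms == 199.0

    def test_injected_bad_channel_detected_and_interpolated(self, montage):
        cfg = TaskConfig(n_blocks=1, trials_per_block=16, n_practice=0,
                         pair_weights=(0.5, 0.5, 0, 0, 0, 0))
        sched = generate_schedule(cfg, seed=9)
        p = SimulationParams(seed=34, bad_channel_indices=(23,))
        rec, events, truth = simulate_session(p, sched, task_config=cfg)
        epochs, _ = preprocess_session(rec)
        assert epochs.channel_status[montage.row(23)] == "interpolated"
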