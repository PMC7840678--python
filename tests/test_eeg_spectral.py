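"""EEG preprocessing, mirror padding and Morlet decomposition."""

import numpy as np
import pytest

from tonecloud import eeg_spectral as es


def _sine_epochs(freq, sfreq=1024.0, amp=1.0, n_trials=2, n_ch=3,
                 tmin=-1.1, tmax=1.3, phase=0.0):
    t = tmin + np.arange(int((tmax - tmin) * sfreq)) / sfreq
    x = amp * np.cos(2 * np.pi * freq * t + phase)
    data = np.tile(x, (n_trials, n_ch, 1))
    return es.EpochedEEG(data=data, times=t, sfreq=sfreq)


class TestPreprocess:
    def test_passband_and_stopband_gains(self):
        eeg50 = _sine_epochs(50.0)
        eeg100 = _sine_epochs(100.0)
        out50 = es.preprocess(eeg50, resample_to=300.0)
        out100 = es.preprocess(eeg100, resample_to=300.0)
        mid = slice(200, -200)      # avoid filter edge transients
        g50 = out50.data[0, 0, mid].std() / eeg50.data[0, 0, mid].std()
        g100 = out100.data[0, 0, mid].std() / eeg100.data[0, 0, mid].std()
        assert 0.7 < g50 <= 1.0
        # 3rd-order zero-phase Butterworth: |H(100 Hz)|^2 ~ 0.11
        assert g100 < 0.15

    def test_amplitude_rejection_on_central_channels(self):
        eeg = _sine_epochs(10.0, amp=10.0, n_trials=5, n_ch=4)
        # sustained 300 ms, 300 uV artifacts whose filtered amplitude still
        # exceeds the 175 uV bound (a 1-sample spike would be removed by
        # the 0.6-70 Hz band-pass before thresholding)
        eeg.data[2, 1, 500:800] += 300.0              # on a central channel
        eeg.data[3, 3, 500:800] += 300.0              # on a peripheral one
        out = es.preprocess(eeg, central_channels=[0, 1])
        assert out.rejected_trials == [2]
        assert out.n_trials == 4

    def test_all_rejected_raises(self):
        eeg = _sine_epochs(10.0, amp=500.0)
        with pytest.raises(ValueError, match="all trials rejected"):
            es.preprocess(eeg)

    def test_sample_rate_guard(self):
        eeg = _sine_epochs(10.0, sfreq=100.0)
        with pytest.raises(ValueError, match="too low"):
            es.preprocess(eeg)

    def test_near_idempotent_on_conforming_data(self):
        eeg = es.preprocess(_sine_epochs(8.0), resample_to=150.0)
        again = es.preprocess(eeg, resample_to=150.0)
        a = eeg.data[0, 0, 30:-30]
        b = again.data[0, 0, 30:len(a) + 30][:a.size]
        assert np.corrcoef(a[:b.size], b)[0, 1] > 0.97


class TestTimeMirror:
    def test_prestimulus_segment_untouched(self):
        eeg = _sine_epochs(4.0)
        out = es.time_mirror_pad(eeg)
        n_pre = int((eeg.times < 0).sum())
        assert np.array_equal(out.data[:, :, n_pre:2 * n_pre],
                              eeg.data[:, :, :n_pre])
        assert out.data.shape[2] >= eeg.data.shape[2]

    def test_left_pad_is_mirror_image(self):
        eeg = _sine_epochs(4.0)
        out = es.time_mirror_pad(eeg)
        n_pre = int((eeg.times < 0).sum())
        assert np.array_equal(out.data[:, :, :n_pre],
                              eeg.data[:, :, :n_pre][:, :, ::-1])

    def test_phase_preserved_for_pure_prestimulus_rhythm(self):
        eeg = _sine_epochs(4.0, sfreq=512.0, phase=0.7)
        tf_raw = es.morlet_tf(eeg, freqs=[4.0])
        tf_mir = es.morlet_tf(es.time_mirror_pad(eeg), freqs=[4.0])
        ti_r = tf_raw.time_index(-0.32)
        ti_m = tf_mir.time_index(-0.32)
        d = tf_raw.phase[0, 0, 0, ti_r] - tf_mir.phase[0, 0, 0, ti_m]
        assert abs(np.angle(np.exp(1j * d))) < 0.05

    def test_post_onset_step_leakage_controlled(self):
        # oracle: decomposition with the post-stimulus period zeroed before
        # mirroring; a strong post-onset step must not move pre-stimulus power
        eeg = _sine_epochs(4.0, sfreq=512.0)
        step = eeg.data.copy()
        step[:, :, eeg.times >= 0] += 3.0
        eeg_step = es.EpochedEEG(step, eeg.times, eeg.sfreq)
        zeroed = eeg.data.copy()
        zeroed[:, :, eeg.times >= 0] = 0.0
        eeg_zero = es.EpochedEEG(zeroed, eeg.times, eeg.sfreq)
        p_step = es.morlet_tf(es.time_mirror_pad(eeg_step), freqs=[4.0])
        p_zero = es.morlet_tf(es.time_mirror_pad(eeg_zero), freqs=[4.0])
        ti = p_step.time_index(-0.1)
        a = p_step.power[0, 0, 0, ti]
        b = p_zero.power[0, 0, 0, ti]
        assert abs(a - b) / b < 0.05
        # the optional cross-fade re-admits post-onset signal by design
        p_fade = es.morlet_tf(es.time_mirror_pad(eeg_step, fade_s=0.05),
                              freqs=[4.0])
        assert p_fade.power[0, 0, 0, ti] > a


class TestMorlet:
    def test_power_peaks_at_signal_frequency_with_zero_phase(self):
        # full 2-13 Hz grid needs the mirrored padding for 2 Hz support
        eeg = es.time_mirror_pad(_sine_epochs(5.0, sfreq=512.0))
        tf = es.morlet_tf(eeg, freqs=np.arange(2.0, 14.0))
        ti = tf.time_index(0.0)
        assert tf.freqs[np.argmax(tf.power[0, 0, :, ti])] == 5.0
        assert abs(tf.phase[0, 0, tf.freq_index(5.0), ti]) < 0.05

    def test_amplitude_doubling_quadruples_power(self):
        a = es.morlet_tf(_sine_epochs(6.0, sfreq=512.0), freqs=[6.0])
        b = es.morlet_tf(_sine_epochs(6.0, sfreq=512.0, amp=2.0), freqs=[6.0])
        ti = a.time_index(-0.5)
        assert np.isclose(b.power[0, 0, 0, ti] / a.power[0, 0, 0, ti], 4.0,
                          rtol=1e-6)

    def test_phase_is_scale_invariant(self):
        eeg = _sine_epochs(4.0, sfreq=512.0, phase=1.1)
        big = es.EpochedEEG(eeg.data * 10, eeg.times, eeg.sfreq)
        ta = es.morlet_tf(eeg, freqs=[4.0])
        tb = es.morlet_tf(big, freqs=[4.0])
        assert np.allclose(ta.phase, tb.phase, atol=1e-9)

    def test_white_noise_power_flat_over_time(self):
        rng = np.random.default_rng(0)
        t = -1.1 + np.arange(int(2.4 * 256)) / 256.0
        data = rng.standard_normal((40, 1, t.size))
        tf = es.morlet_tf(es.EpochedEEG(data, t, 256.0), freqs=[8.0])
        mean_p = tf.power[:, 0, 0, :].mean(axis=0)
        sel = (tf.times > -0.8) & (tf.times < 1.0)    # away from edges
        assert mean_p[sel].std() / mean_p[sel].mean() < 0.35

    def test_too_short_epoch_names_frequency(self):
        t = np.arange(int(0.8 * 256)) / 256.0 - 0.4
        eeg = es.EpochedEEG(np.zeros((1, 1, t.size)), t, 256.0)
        with pytest.raises(ValueError, match="2.00 Hz"):
            es.morlet_tf(eeg, freqs=[2.0])


class TestSelection:
    def test_concentrated_significance_selects_that_time(self):
        times = np.linspace(-1, 0, 21)
        p = np.ones((5, 4, 21))
        p[:, :, 13] = 0.01
        t, counts = es.select_timepoint(p, times)
        assert t == pytest.approx(times[13])
        assert counts[13] == 20

    def test_flat_pvalues_tie_break_earliest(self):
        times = np.linspace(-1, 0, 11)
        p = np.full((3, 2, 11), 0.5)
        t, _ = es.select_timepoint(p, times)
        assert t == pytest.approx(times[0])


class TestSpectrum:
    def test_pure_tone_peak(self):
        eeg = _sine_epochs(10.0, sfreq=256.0)
        freqs, amp = es.eeg_spectrum(eeg, nperseg=256)
        sel = freqs > 1
        assert abs(freqs[sel][np.argmax(amp[sel])] - 10.0) < 1.0

    def test_window_restriction(self):
        eeg = _sine_epochs(10.0, sfreq=256.0)
        eeg.data[:, :, eeg.times >= 0] = 0.0
        f_pre, a_pre = es.eeg_spectrum(eeg, window=(-1.0, 0.0), nperseg=128)
        f_post, a_post = es.eeg_spectrum(eeg, window=(0.0, 1.0), nperseg=128)
        assert a_pre.max() > 10 * a_post.max()

    def test_epoch_container_roundtrip(self, tmp_path):
        eeg = _sine_epochs(7.0, sfreq=256.0)
        eeg.rejected_trials = [4, 9]
        path = tmp_path / "epochs.h5"
        es.save_epochs(path, eeg)
        back = es.load_epochs(path)
        assert np.array_equal(back.data, eeg.data)
        assert np.array_equal(back.times, eeg.times)
        assert back.sfreq == eeg.sfreq
        assert back.ch_names == eeg.ch_names
        assert back.rejected_trials == [4, 9]

    def test_rereference_average(self):
        eeg = _sine_epochs(10.0)
        out = es.rereference(eeg)
        assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-12)
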