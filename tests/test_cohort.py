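"""Generative observer, staircases, and synthetic EEG ground truth."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.optimize import brentq
from scipy.stats import norm

from tonecloud import cohort, eeg_spectral
from tonecloud.soundscapes import quantized_evidence


def _noiseless(**kw):
    base = dict(w_offset=1.0, w_linear=0.0, w_uv=0.0, rhythm_amp=0.0,
                decision_noise_sd=1e-9)
    base.update(kw)
    return cohort.ObserverParams(**base)


class TestObserver:
    def test_closed_form_decision_variable(self):
        obs = _noiseless()
        out = cohort.simulate_response(np.full(10, 0.6), obs, noise=0.0)
        assert out["choice"] == +1
        assert np.isclose(out["dv"], 1.0)

    def test_ambiguous_evidence_is_fair_coin(self):
        obs = cohort.ObserverParams()
        rng = np.random.default_rng(0)
        noise = rng.normal(0, obs.decision_noise_sd, 10000)
        ups = sum(cohort.simulate_response(np.full(10, 0.5), obs,
                                           noise=n)["choice"] > 0
                  for n in noise)
        # binomial 99.9% CI around 0.5 at n=10000
        assert abs(ups / 10000 - 0.5) < 3.3 * 0.005

    def test_phase_coupling_shifts_effective_phase_by_pi(self):
        obs = cohort.ObserverParams(phase_coupling_gain=1.0, rhythm_amp=1.0)
        w0 = cohort.observer_weights(obs, eeg_phase=0.0)
        wpi = cohort.observer_weights(obs, eeg_phase=np.pi)
        obs_flipped = replace(obs, rhythm_phase0=obs.rhythm_phase0 + np.pi)
        assert np.allclose(wpi, cohort.observer_weights(obs_flipped, eeg_phase=0.0))
        rhythm0 = w0 - cohort.observer_weights(replace(obs, rhythm_amp=0.0))
        rhythmpi = wpi - cohort.observer_weights(replace(obs, rhythm_amp=0.0))
        assert np.allclose(rhythm0, -rhythmpi, atol=1e-12)

    def test_nonfinite_evidence_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            cohort.simulate_response(np.full(10, np.nan), cohort.ObserverParams())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            cohort.ObserverParams(rhythm_freq_hz=5.0)   # above epoch Nyquist
        with pytest.raises(ValueError):
            cohort.ObserverParams(decision_noise_sd=0.0)


class TestStaircase:
    def test_step_function_observer_bisects_threshold(self):
        # oracle: the observer is correct iff coherence >= 0.3, so the
        # staircase must settle at 0.3 within one step
        rng = np.random.default_rng(0)
        thr = cohort.run_staircases(cohort.ObserverParams(), seed=rng,
                                    respond=lambda c, r: c >= 0.3)
        assert abs(thr - 0.3) <= 0.1

    def test_tracks_the_70_7_percent_point(self):
        # oracle: exact P(correct | coherence) of the probit observer by
        # the closed-form normal integral; root at 1/sqrt(2)
        obs = cohort.ObserverParams()
        w = cohort.observer_weights(obs)

        def p_correct(c):
            e = quantized_evidence(+1, np.full(10, c))
            return norm.cdf(w @ (e - 0.5) / obs.decision_noise_sd)

        c_star = brentq(lambda c: p_correct(c) - 1 / np.sqrt(2), 0.05, 0.9)
        rng = np.random.default_rng(1)
        thrs = [cohort.run_staircases(obs, seed=rng) for _ in range(20)]
        assert abs(np.mean(thrs) - c_star) < 0.05

    def test_cohort_thresholds_near_paper_range(self, default_cohort):
        # calibration check (not a hard design assert): mean near 0.32
        assert 0.25 < default_cohort.thresholds.mean() < 0.40

    def test_unreachable_reversals_raise(self):
        cfg = replace(cohort.StaircaseConfig(), max_trials=5)
        with pytest.raises(RuntimeError, match="reversals"):
            cohort.run_staircase(cohort.ObserverParams(), 0.4, cfg,
                                 np.random.default_rng(0))


class TestSyntheticEEG:
    def test_phase_ground_truth_without_noise(self):
        params = cohort.SyntheticEEGParams(n_channels=2, sample_rate_hz=512,
                                           noise_amp=0.0, topography=(1.0, 0.5))
        for true_phase in (0.0, 1.2, -2.5):
            raw = cohort.simulate_eeg_epoch(params, {"eeg_phase": true_phase})
            eeg = eeg_spectral.EpochedEEG(raw[None], params.times(), 512)
            tf = eeg_spectral.morlet_tf(eeg_spectral.time_mirror_pad(eeg),
                                        freqs=[4.0])
            est = tf.phase[0, 0, 0, tf.time_index(-0.32)]
            assert abs(np.angle(np.exp(1j * (est - true_phase)))) < 0.1

    def test_phase_difference_pi_recovered(self):
        params = cohort.SyntheticEEGParams(n_channels=1, sample_rate_hz=512,
                                           noise_amp=0.0, topography=(1.0,))
        ests = []
        for ph in (0.0, np.pi):
            raw = cohort.simulate_eeg_epoch(params, {"eeg_phase": ph})
            eeg = eeg_spectral.EpochedEEG(raw[None], params.times(), 512)
            tf = eeg_spectral.morlet_tf(eeg_spectral.time_mirror_pad(eeg),
                                        freqs=[4.0])
            ests.append(tf.phase[0, 0, 0, tf.time_index(-0.32)])
        assert abs(abs(np.angle(np.exp(1j * (ests[0] - ests[1])))) - np.pi) < 0.1

    def test_one_over_f_background_slope(self):
        params = cohort.SyntheticEEGParams(n_channels=8, sample_rate_hz=256,
                                           osc_amp=0.0, noise_exponent=1.0)
        rng = np.random.default_rng(0)
        raw = np.stack([cohort.simulate_eeg_epoch(params, {}, rng)
                        for _ in range(20)])
        eeg = eeg_spectral.EpochedEEG(raw, params.times(), 256)
        freqs, amp = eeg_spectral.eeg_spectrum(eeg, nperseg=512)
        sel = (freqs >= 1) & (freqs <= 40)
        slope = np.polyfit(np.log(freqs[sel]), np.log(amp[sel] ** 2), 1)[0]
        assert abs(slope + params.noise_exponent) < 0.3

    def test_log_power_scales_oscillation(self):
        params = cohort.SyntheticEEGParams(n_channels=1, sample_rate_hz=256,
                                           noise_amp=0.0, topography=(1.0,))
        a = cohort.simulate_eeg_epoch(params, {"eeg_phase": 0.0, "eeg_log_power": 0.0})
        b = cohort.simulate_eeg_epoch(params, {"eeg_phase": 0.0, "eeg_log_power": 2.0})
        assert np.allclose(b, np.e * a)


class TestCohortSimulation:
    def test_ledger_roundtrip_bit_identical(self, default_cohort):
        led = default_cohort.ledger["participants"][3]
        obs = cohort.ObserverParams(**led["observer"])
        seed = np.random.SeedSequence(entropy=led["trial_seed"],
                                      spawn_key=tuple(led["spawn_key"]))
        df = cohort.simulate_participant_trials(obs, led["threshold"],
                                                default_cohort.ledger["n_trials"],
                                                seed)
        old = default_cohort.participant_trials(3).drop(columns="participant")
        assert df.equals(old.reset_index(drop=True))

    def test_same_seed_same_cohort(self):
        a = cohort.simulate_cohort(2, 100, seed=5)
        b = cohort.simulate_cohort(2, 100, seed=5)
        assert a.trials.equals(b.trials)

    def test_directions_balanced_and_coherence_in_range(self, default_cohort):
        tp = default_cohort.participant_trials(0)
        assert abs(tp["direction"].sum()) <= 1
        c = tp[[f"c{i}" for i in range(1, 11)]].to_numpy()
        assert np.all((c >= -1e-9) & (c <= 1 + 1e-9))

    def test_coherence_mean_matches_truncated_normal_oracle(self):
        # closed-form truncated-normal mean as the independent oracle
        for thr in (0.25, 0.32, 0.40):
            rng = np.random.default_rng(int(thr * 100))
            x = cohort._truncated_normal(rng, thr, 0.2, 0.0, 1.0, 200000)
            a, b = (0 - thr) / 0.2, (1 - thr) / 0.2
            expected = thr + 0.2 * (norm.pdf(a) - norm.pdf(b)) / \
                (norm.cdf(b) - norm.cdf(a))
            assert abs(x.mean() - expected) < 0.003
            # resampling truncation biases the mean upward by < 0.045
            # for thresholds in the staircase range
            assert abs(expected - thr) < 0.045

    def test_eeg_states_recorded_in_ledger(self, default_cohort):
        led = default_cohort.ledger["participants"][0]
        tp = default_cohort.participant_trials(0)
        assert np.allclose(led["eeg_phase"], tp["eeg_phase"])
        assert np.allclose(led["eeg_log_power"], tp["eeg_log_power"])
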