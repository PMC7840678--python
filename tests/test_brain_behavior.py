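"""SDT measures, state binning, POS, and between-bin weight contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize

from tonecloud import brain_behavior as bb
from tonecloud import cohort
from tonecloud.eeg_spectral import TFDecomposition
from tonecloud.weight_models import DesignSpec, fit_weight_model


def _trials_from_rates(h, fa, n=1000):
    """Deterministic trial table realizing exact hit/false-alarm counts."""
    n_up = n_down = n // 2
    direction = np.repeat([1, -1], n // 2)
    resp = np.concatenate([
        np.where(np.arange(n_up) < round(h * n_up), 1, -1),
        np.where(np.arange(n_down) < round(fa * n_down), 1, -1)])
    return pd.DataFrame({"direction": direction, "response": resp})


def _z_oracle(p):
    """Inverse-normal via quadrature + root finding (independent of ppf)."""
    def cdf(x):
        val, _ = integrate.quad(lambda u: np.exp(-u * u / 2) / np.sqrt(2 * np.pi),
                                -30, x)
        return val
    return optimize.brentq(lambda x: cdf(x) - p, -8, 8, xtol=1e-13)


class TestSDT:
    def test_identities_match_quadrature_oracle(self):
        rng = np.random.default_rng(0)
        for h, fa in zip(rng.uniform(0.55, 0.97, 10), rng.uniform(0.03, 0.45, 10)):
            n = 2000
            h_r = round(h * n / 2) / (n / 2)
            fa_r = round(fa * n / 2) / (n / 2)
            m = bb.sdt_measures(_trials_from_rates(h_r, fa_r, n))
            zh, zfa = _z_oracle(h_r), _z_oracle(fa_r)
            assert abs(m.dprime - (zh - zfa)) < 1e-10
            assert abs(m.criterion - (-(zh + zfa) / 2)) < 1e-10

    def test_reference_values(self):
        m = bb.sdt_measures(_trials_from_rates(0.716, 0.284, 2000))
        assert m.dprime == pytest.approx(1.142, abs=5e-3)
        assert m.criterion == pytest.approx(0.0, abs=1e-9)
        m2 = bb.sdt_measures(_trials_from_rates(0.976, 0.5, 2000))
        assert m2.criterion == pytest.approx(-0.989, abs=5e-3)

    def test_equal_rates_zero_dprime(self):
        m = bb.sdt_measures(_trials_from_rates(0.6, 0.6, 1000))
        assert m.dprime == pytest.approx(0.0, abs=1e-12)

    def test_rate_clamping_keeps_finite(self):
        m = bb.sdt_measures(_trials_from_rates(1.0, 0.0, 100))
        assert np.isfinite(m.dprime)
        assert m.hit_rate == 1 - 1 / 100

    def test_single_direction_raises(self):
        df = pd.DataFrame({"direction": np.ones(50), "response": np.ones(50)})
        with pytest.raises(ValueError, match="directions"):
            bb.sdt_measures(df)


def _tf_with(power=None, phase=None, freqs=(4.0,), times=(-0.32,)):
    """Minimal TF container: trial x 1 channel x freq x time."""
    n = len(power) if power is not None else len(phase)
    shape = (n, 1, len(freqs), len(times))
    pw = np.ones(shape) if power is None else \
        np.asarray(power)[:, None, None, None] * np.ones(shape)
    ph = np.zeros(shape) if phase is None else \
        np.asarray(phase)[:, None, None, None] * np.ones(shape)
    return TFDecomposition(power=pw, phase=ph, freqs=np.asarray(freqs),
                           times=np.asarray(times))


class TestBinning:
    def test_median_split_is_even(self):
        rng = np.random.default_rng(1)
        tf = _tf_with(power=rng.uniform(1, 2, 100), times=(-0.3, -0.2, -0.1))
        bins = bb.split_by_power(tf, 0, 4.0)
        assert bins.labels.sum() == 50

    def test_quartiles_equipopulated(self):
        rng = np.random.default_rng(2)
        tf = _tf_with(power=rng.uniform(1, 2, 1000), times=(-0.3, -0.2, -0.1))
        bins = bb.split_by_power(tf, 0, 4.0, n_bins=4)
        assert [int((bins.labels == b).sum()) for b in range(4)] == [250] * 4

    def test_labels_match_implanted_log_power(self):
        rng = np.random.default_rng(3)
        lp = rng.normal(0, 1, 400)
        noisy = np.exp(lp) * np.exp(rng.normal(0, 0.1, 400))
        tf = _tf_with(power=noisy, times=(-0.3, -0.2, -0.1))
        bins = bb.split_by_power(tf, 0, 4.0)
        truth = (np.argsort(np.argsort(lp)) >= 200).astype(int)
        assert (bins.labels == truth).mean() >= 0.95

    def test_constant_power_degenerate(self):
        tf = _tf_with(power=np.ones(100), times=(-0.3, -0.2, -0.1))
        with pytest.raises(ValueError, match="degenerate"):
            bb.split_by_power(tf, 0, 4.0)

    def test_phase_division_separates_opposite_phases(self):
        tf = _tf_with(phase=np.array([0.1, 3.0]))
        bins = bb.split_by_phase(tf, 0, 4.0, division_index=0)
        assert bins.labels[0] != bins.labels[1]

    def test_phase_rotation_by_pi_swaps_labels(self):
        rng = np.random.default_rng(4)
        ph = rng.uniform(-np.pi, np.pi, 200)
        ph = ph[np.abs(np.mod(ph, np.pi / 4)) > 1e-3]  # stay off the boundaries
        for k in range(4):
            a = bb.split_by_phase(_tf_with(phase=ph), 0, 4.0, division_index=k)
            b = bb.split_by_phase(_tf_with(phase=bb.wrap_angle(ph + np.pi)),
                                  0, 4.0, division_index=k)
            assert np.array_equal(a.labels, 1 - b.labels)

    def test_uniform_phases_balanced_bins(self):
        rng = np.random.default_rng(5)
        ph = rng.uniform(-np.pi, np.pi, 2000)
        bins = bb.split_by_phase(_tf_with(phase=ph), 0, 4.0, division_index=1)
        assert abs(bins.labels.mean() - 0.5) < 3.3 * 0.011


class TestPOS:
    def test_null_classes_give_small_pos_and_uniform_p(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(20):
            ph = rng.uniform(-np.pi, np.pi, 200)
            mask = rng.random(200) < 0.5
            obs, p = bb.pos_perm_p(ph, mask, n_perm=200, seed=rng)
            ps.append(p)
        assert np.mean(ps) > 0.2          # not systematically significant
        assert (np.asarray(ps) < 0.05).mean() < 0.25

    def test_opposing_von_mises_detected(self):
        rng = np.random.default_rng(7)
        a = rng.vonmises(0.0, 8.0, 150)
        b = rng.vonmises(np.pi, 8.0, 150)
        obs = bb.pos(a, b)
        assert obs > 1.0                   # ITCs ~1, ITC_all ~0
        _, p = bb.pos_perm_p(np.concatenate([a, b]),
                             np.arange(300) < 150, n_perm=500, seed=0)
        assert p < 0.01

    def test_pos_bounded_by_two_and_rotation_invariant(self):
        rng = np.random.default_rng(8)
        a = rng.vonmises(1.0, 4.0, 100)
        b = rng.vonmises(1.0, 4.0, 100)
        assert bb.pos(a, b) <= 2.0
        assert np.isclose(bb.pos(a + 0.7, b + 0.7), bb.pos(a, b))

    def test_small_class_excluded(self):
        with pytest.raises(ValueError, match="too small"):
            bb.pos_perm_p(np.zeros(30), np.arange(30) < 5, n_perm=10)

    def test_group_stouffer_combination(self):
        rng = np.random.default_rng(9)
        per_part = []
        for _ in range(6):
            a = rng.vonmises(0.0, 5.0, 100)
            b = rng.vonmises(np.pi, 5.0, 100)
            per_part.append((np.concatenate([a, b]), np.arange(200) < 100))
        gp, ps, excl = bb.pos_group(per_part, n_perm=200, seed=1)
        assert gp < 0.001 and not excl


class TestContrasts:
    def _fit(self, phase, amp=2.0):
        design = DesignSpec(rhythm_freq_hz=2.2)
        t = np.asarray(design.epoch_centers_s)
        return fit_weight_model(amp * np.cos(2 * np.pi * 2.2 * t - phase), design)

    @pytest.mark.parametrize("p1,p2,expected", [
        (0.3, 0.3, 0.0), (0.0, np.pi, 180.0), (0.0, 3 * np.pi / 2, 90.0)])
    def test_absolute_circular_phase_difference(self, p1, p2, expected):
        # small tolerance: sin/cos columns are not exactly orthogonal to
        # the trivial regressors at 10 samples
        c = bb.phase_contrast(self._fit(p1), self._fit(p2))
        assert c.abs_phase_diff_deg == pytest.approx(expected, abs=2.0)

    def test_amplitude_diffs_signed_vs_absolute(self):
        c_signed = bb.phase_contrast(self._fit(0.0, 1.0), self._fit(0.0, 2.0))
        c_abs = bb.phase_contrast(self._fit(0.0, 1.0), self._fit(0.0, 2.0),
                                  signed_amp=False)
        assert c_signed.component_amp_diffs["rhythm_rms"] < 0
        assert c_abs.component_amp_diffs["rhythm_rms"] > 0

    def test_best_division_argmax(self):
        cons = [bb.phase_contrast(self._fit(0.0), self._fit(d), division_index=k)
                for k, d in enumerate([0.1, 2.0, 0.5, 1.0])]
        assert bb.best_division(cons).selected_division == 1

    def test_group_shift_degenerate_and_null_baseline(self):
        out = bb.group_phase_shift([90.0] * 8)
        assert out["mean_deg"] == 90.0 and out["ci"] == (90.0, 90.0)
        # null baseline: |wrapped difference of uniform phases| averages 90 deg
        rng = np.random.default_rng(10)
        d = np.abs(bb.wrap_angle(rng.uniform(-np.pi, np.pi, 4000)
                                 - rng.uniform(-np.pi, np.pi, 4000)))
        mean = np.rad2deg(d).mean()
        assert abs(mean - 90.0) < 3 * np.rad2deg(d.std()) / np.sqrt(4000)


class TestBinnedWeights:
    def test_no_coupling_gives_small_contrasts_and_dropped_bins_flagged(self):
        data = cohort.simulate_cohort(
            1, 600, seed=12,
            obs_sampler=cohort.default_observer_sampler(
                rhythm_amp=cohort.STRONG_RHYTHM_AMP))
        tp = data.participant_trials(0)
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 600)     # EEG-irrelevant random bins
        bins = bb.BinAssignment(kind="power_median", labels=labels, n_bins=2)
        out = bb.binned_weights(tp, bins, n_perm=500, seed=1)
        assert set(out) == {0, 1, "dropped"} and out["dropped"] == []
        c = bb.phase_contrast(out[0][1], out[1][1])
        assert c.abs_phase_diff_deg < 45.0   # no implanted between-bin shift
        # a bin below the minimum trial count is dropped, not fitted
        labels_bad = np.zeros(600, dtype=int)
        labels_bad[:20] = 1
        bins_bad = bb.BinAssignment(kind="power_median", labels=labels_bad,
                                    n_bins=2)
        out_bad = bb.binned_weights(tp, bins_bad, n_perm=200, seed=2)
        assert out_bad["dropped"] == [1] and 0 in out_bad
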