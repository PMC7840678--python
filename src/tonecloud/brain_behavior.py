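"""Linking single-trial pre-stimulus EEG state to behavior and weights.

Trials are binned by pre-stimulus oscillatory state — a median (or
quartile) split of power in a window around -200 ms, or a half-circle
split of phase at -320 ms with four possible division boundaries rotated
in steps of pi/4.  Behavior is summarized by signal-detection measures
(d', criterion) and by the phase opposition sum (POS) between correct and
incorrect trials; the perceptual weights and their model components are
re-estimated within each bin, and the between-bin change of the rhythmic
component's phase is the headline contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import revcorr, weight_models
from .revcorr import WeightProfile
from .weight_models import DesignSpec, WeightModelFit

__all__ = [
    "SDTMeasures",
    "BinAssignment",
    "PhaseContrast",
    "sdt_measures",
    "split_by_power",
    "split_by_phase",
    "pos",
    "pos_perm_p",
    "pos_group",
    "binned_weights",
    "phase_contrast",
    "best_division",
    "group_phase_shift",
    "wrap_angle",
    "itc",
]


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)


def itc(phases, axis=0):
    """Inter-trial coherence: length of the mean unit phase vector."""
    return np.abs(np.mean(np.exp(1j * np.asarray(phases)), axis=axis))


@dataclass(frozen=True)
class SDTMeasures:
    """Signal-detection summary of direction judgments."""

    hit_rate: float          # P(respond up | up trial)
    fa_rate: float           # P(respond up | down trial)
    dprime: float            # z(H) - z(FA)
    criterion: float         # -(z(H) + z(FA)) / 2
    fraction_correct: float


def _clamp_rate(k: int, n: int, method: str) -> float:
    if method == "half":
        r = k / n
        return float(np.clip(r, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))
    if method == "loglinear":
        return (k + 0.5) / (n + 1.0)
    raise ValueError(f"unknown clamping method {method!r}")


def sdt_measures(trials: pd.DataFrame, clamp: str = "half") -> SDTMeasures:
    """d' and criterion from a trial table, split by true sweep direction.

    Rates are clamped away from {0, 1} (default to 1/(2N)) so the inverse
    normal transform stays finite; ``clamp="loglinear"`` applies the
    standard log-linear correction instead.
    """
    up = trials["direction"].to_numpy() > 0
    resp_up = trials["response"].to_numpy() > 0
    n_up, n_down = int(up.sum()), int((~up).sum())
    if n_up == 0 or n_down == 0:
        raise ValueError("both sweep directions must be present")
    h = _clamp_rate(int(resp_up[up].sum()), n_up, clamp)
    fa = _clamp_rate(int(resp_up[~up].sum()), n_down, clamp)
    zh, zfa = norm.ppf(h), norm.ppf(fa)
    fc = float((resp_up == up).mean())
    return SDTMeasures(hit_rate=h, fa_rate=fa, dprime=float(zh - zfa),
                       criterion=float(-(zh + zfa) / 2.0), fraction_correct=fc)


@dataclass
class BinAssignment:
    """Per-trial bin labels from a power split or a phase division."""

    kind: str                        # power_median | power_quartile | phase_division
    labels: np.ndarray               # int per trial, 0-based
    n_bins: int
    extraction: dict = field(default_factory=dict)   # channel/freq/time used
    division_index: int | None = None

    def mask(self, b: int) -> np.ndarray:
        return self.labels == b


def split_by_power(tf, channel, freq_hz: float, window=(-0.3, -0.1),
                   n_bins: int = 2) -> BinAssignment:
    """Median split (or equi-populated quartiles) of windowed pre-stimulus power.

    Power is averaged over ``window`` (default -200 +- 100 ms, the
    pre-stimulus window the linking analyses use) at one channel and
    frequency; ties are broken by stable trial
    order so bins are equal size +-1.
    """
    if n_bins not in (2, 4):
        raise ValueError("n_bins must be 2 (median) or 4 (quartiles)")
    ci, fi = tf.channel_index(channel), tf.freq_index(freq_hz)
    sel = (tf.times >= window[0]) & (tf.times <= window[1])
    if not np.any(sel):
        raise ValueError(f"window {window} outside the epoch")
    p = tf.power[:, ci, fi, sel].mean(axis=1)
    if np.ptp(p) == 0:
        raise ValueError("degenerate split: power is constant across trials")
    order = np.argsort(p, kind="stable")
    labels = np.empty(p.size, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        labels[chunk] = b
    kind = "power_median" if n_bins == 2 else "power_quartile"
    return BinAssignment(kind=kind, labels=labels, n_bins=n_bins,
                         extraction={"channel": channel, "freq_hz": freq_hz,
                                     "window_s": tuple(window)})


def split_by_phase(tf, channel, freq_hz: float, time_s: float = -0.32,
                   division_index: int = 0) -> BinAssignment:
    """Half-circle split of the phase at one pre-stimulus time point.

    Division ``k`` groups trials into two opposing half-circles centred
    on the angles k*pi/4 and k*pi/4 + pi (label 0 covers phases within
    +-pi/2 of k*pi/4); the four divisions rotate the split in steps of
    pi/4, covering all distinct binary phase groupings at this
    resolution.
    """
    if division_index not in (0, 1, 2, 3):
        raise ValueError("division_index must be 0..3")
    ci, fi, ti = tf.channel_index(channel), tf.freq_index(freq_hz), \
        tf.time_index(time_s)
    ph = tf.phase[:, ci, fi, ti]
    rel = np.mod(ph - division_index * np.pi / 4.0 + np.pi / 2.0, 2 * np.pi)
    labels = (rel >= np.pi).astype(int)
    return BinAssignment(kind="phase_division", labels=labels, n_bins=2,
                         division_index=division_index,
                         extraction={"channel": channel, "freq_hz": freq_hz,
                                     "time_s": time_s})


def pos(phases_a, phases_b, axis=0) -> np.ndarray | float:
    """Phase opposition sum: ITC_a + ITC_b - 2 * ITC_all.

    Elevated when the two trial classes cluster at opposing phases;
    bounded above by 2.  Arrays may carry extra trailing dimensions
    (channel, frequency, time); trials run along ``axis``.
    """
    a, b = np.asarray(phases_a), np.asarray(phases_b)
    va = np.mean(np.exp(1j * a), axis=axis) * a.shape[axis]
    vb = np.mean(np.exp(1j * b), axis=axis) * b.shape[axis]
    n = a.shape[axis] + b.shape[axis]
    itc_all = np.abs(va + vb) / n
    out = itc(a, axis) + itc(b, axis) - 2 * itc_all
    return float(out) if np.ndim(out) == 0 else out


def pos_perm_p(phases, correct_mask, n_perm: int = 1000, seed=None,
               min_class: int = 10):
    """Permutation p-value of the POS between correct and incorrect trials.

    ``phases`` is (trials, ...); the correct/incorrect labels are shuffled
    ``n_perm`` times.  Returns ``(pos_observed, p)`` with arrays matching
    the trailing dimensions.  Raises when a class has < ``min_class``
    trials.
    """
    phases = np.asarray(phases)
    mask = np.asarray(correct_mask, dtype=bool)
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if min(n1, n0) < min_class:
        raise ValueError(f"class too small for POS ({n1} correct / {n0} incorrect)")
    obs = pos(phases[mask], phases[~mask])
    rng = np.random.default_rng(seed)
    count = np.zeros(np.shape(obs))
    for _ in range(n_perm):
        pm = rng.permutation(mask)
        count += pos(phases[pm], phases[~pm]) >= obs
    p = (1.0 + count) / (1.0 + n_perm)
    return obs, p


def pos_group(per_participant, n_perm: int = 1000, seed=None,
              min_class: int = 10):
    """Group-level POS p-values, Stouffer-combined across participants.

    ``per_participant`` is a sequence of ``(phases, correct_mask)`` pairs;
    phases may be (trials, channel, freq, time).  Participants with a
    class smaller than ``min_class`` are excluded with a warning entry.
    Returns ``(group_p, per_participant_p, excluded)``.
    """
    rng = np.random.default_rng(seed)
    ps, excluded = [], []
    for i, (phases, mask) in enumerate(per_participant):
        try:
            _, p = pos_perm_p(phases, mask, n_perm=n_perm, seed=rng,
                              min_class=min_class)
        except ValueError:
            excluded.append(i)
            continue
        ps.append(p)
    if not ps:
        raise ValueError("no participant had enough trials in both classes")
    z = norm.isf(np.asarray(ps))                   # one-sided: large POS -> small p
    group_p = norm.sf(z.sum(axis=0) / np.sqrt(len(ps)))
    return group_p, ps, excluded


def binned_weights(trials: pd.DataFrame, bins: BinAssignment,
                   rhythm_freq_hz: float = 2.2, n_perm: int = 4000,
                   seed=None, min_trials: int = revcorr.MIN_TRIALS_DEFAULT,
                   perm_cache: dict | None = None) -> dict:
    """Re-estimate weights and model components within each trial bin.

    Runs the reverse-correlation + model-fit pipeline separately for the
    trials of every bin; bins below ``min_trials`` are dropped and
    reported under ``"dropped"``.  Returns ``{bin: (WeightProfile,
    WeightModelFit)}`` plus the dropped-bin list.
    """
    if len(trials) != bins.labels.size:
        raise ValueError("bin labels do not match the trial table")
    design = DesignSpec(rhythm_freq_hz=rhythm_freq_hz)
    rng = np.random.default_rng(seed)
    out, dropped = {}, []
    for b in range(bins.n_bins):
        mask = bins.mask(b)
        if mask.sum() < min_trials:
            dropped.append(b)
            continue
        prof = revcorr.perceptual_weights(trials, n_perm=n_perm, seed=rng,
                                          bin_mask=mask, min_trials=min_trials,
                                          bin_label=f"{bins.kind}:{b}",
                                          perm_cache=perm_cache)
        out[b] = (prof, weight_models.fit_weight_model(prof, design))
    out["dropped"] = dropped
    return out


@dataclass
class PhaseContrast:
    """Between-bin contrast of the rhythmic phase and component amplitudes."""

    abs_phase_diff_deg: float                  # circular, in [0, 180]
    component_amp_diffs: dict                  # per component, bin1 - bin2
    selected_division: int | None = None


def phase_contrast(fit_bin1: WeightModelFit, fit_bin2: WeightModelFit,
                   signed_amp: bool = True,
                   division_index: int | None = None) -> PhaseContrast:
    """Contrast two within-bin model fits.

    The phase difference is the absolute circular difference of the
    rhythmic phases (<= 180 deg).  Amplitude differences are signed
    (bin1 - bin2) for power bins and absolute for phase bins
    (``signed_amp=False``), matching the two statistical procedures.
    """
    dphi = wrap_angle(fit_bin1.rhythm_phase - fit_bin2.rhythm_phase)
    amp_diffs = {}
    for name in ("offset", "linear", "uv"):
        d = fit_bin1.betas[name] - fit_bin2.betas[name]
        amp_diffs[name] = float(d if signed_amp else abs(d))
    d = fit_bin1.rhythm_rms - fit_bin2.rhythm_rms
    amp_diffs["rhythm_rms"] = float(d if signed_amp else abs(d))
    return PhaseContrast(abs_phase_diff_deg=float(abs(dphi) * 180.0 / np.pi),
                         component_amp_diffs=amp_diffs,
                         selected_division=division_index)


def best_division(contrasts, key: str = "phase") -> PhaseContrast:
    """Of the four phase divisions, the one with the largest effect.

    ``key`` selects the effect: "phase" (the absolute rhythmic phase
    shift) or a component name in ``component_amp_diffs``.
    """
    contrasts = list(contrasts)
    if not contrasts:
        raise ValueError("no contrasts given")
    if key == "phase":
        vals = [c.abs_phase_diff_deg for c in contrasts]
    else:
        vals = [abs(c.component_amp_diffs[key]) for c in contrasts]
    return contrasts[int(np.argmax(vals))]


def group_phase_shift(abs_diffs_deg, ci: float = 0.95, method: str = "t",
                      n_boot: int = 10000, seed=None) -> dict:
    """Cohort mean of absolute phase shifts with a confidence interval.

    Default is the t-interval on the arithmetic mean of the absolute
    circular differences; ``method="bootstrap"`` uses a percentile
    bootstrap instead.  Under null coupling the expectation is 90 deg
    (mean absolute difference of wrapped uniform phases).
    """
    x = np.asarray(abs_diffs_deg, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 participants")
    mean = float(x.mean())
    if method == "t":
        from scipy.stats import t as t_dist
        se = x.std(ddof=1) / np.sqrt(x.size)
        q = t_dist.ppf(0.5 + ci / 2.0, df=x.size - 1)
        lo, hi = mean - q * se, mean + q * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = x[rng.integers(0, x.size, (n_boot, x.size))].mean(axis=1)
        lo, hi = np.percentile(boots, [50 * (1 - ci), 50 * (1 + ci)])
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"mean_deg": mean, "ci": (float(lo), float(hi))}
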