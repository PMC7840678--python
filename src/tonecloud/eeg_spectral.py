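"""Epoched-EEG preprocessing and single-trial time-frequency analysis.

The preprocessing chain mirrors standard practice for pre-stimulus state
analyses: zero-phase Butterworth band-pass (0.6-70 Hz, 3rd order),
anti-aliased resampling to 150 Hz, and rejection of trials whose amplitude
on designated central channels exceeds +-175 uV.  Zero-phase (forward-
backward) filtering is used so pre-stimulus phase estimates are not
lag-shifted.

To keep wavelet estimates at t < 0 uncontaminated by post-stimulus
activity, epochs are time-mirrored: the pre-stimulus segment is reflected
to the left (for wavelet support) and the stimulus period is faded out
with a half-Hanning window and replaced by mirrored pre-stimulus data.
Time-frequency decomposition uses Morlet wavelets (4 cycles) on an
integer 2-13 Hz grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal
from mne.time_frequency import tfr_array_morlet

__all__ = [
    "EpochedEEG",
    "TFDecomposition",
    "preprocess",
    "time_mirror_pad",
    "morlet_tf",
    "select_timepoint",
    "eeg_spectrum",
    "rereference",
    "default_tf_freqs",
    "save_epochs",
    "load_epochs",
]


def default_tf_freqs() -> np.ndarray:
    """Integer 2-13 Hz wavelet grid (12 bins)."""
    return np.arange(2.0, 14.0)


@dataclass
class EpochedEEG:
    """Trial x channel x time container with an onset-at-zero time axis."""

    data: np.ndarray                 # (n_trials, n_channels, n_times), uV
    times: np.ndarray                # s relative to stimulus onset
    sfreq: float
    ch_names: list = field(default_factory=list)
    rejected_trials: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != self.times.size:
            raise ValueError("data must be (trials, channels, times) matching times")
        dt = np.diff(self.times)
        if self.times.size > 1 and (np.any(dt <= 0) or
                                    not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("times must be strictly increasing and uniform")
        if not self.ch_names:
            self.ch_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, ch) -> int:
        return ch if isinstance(ch, (int, np.integer)) else self.ch_names.index(ch)

    def time_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))


@dataclass
class TFDecomposition:
    """Morlet power and phase, trial x channel x frequency x time."""

    power: np.ndarray
    phase: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    ch_names: list = field(default_factory=list)

    def freq_index(self, f: float) -> int:
        return int(np.argmin(np.abs(self.freqs - f)))

    def time_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))

    def channel_index(self, ch) -> int:
        return ch if isinstance(ch, (int, np.integer)) else self.ch_names.index(ch)


def preprocess(eeg: EpochedEEG, band=(0.6, 70.0), order: int = 3,
               resample_to: float = 150.0, reject_uv: float = 175.0,
               central_channels=None) -> EpochedEEG:
    """Band-pass, resample, and reject high-amplitude trials.

    ``central_channels`` names/indices the channels screened for the
    +-``reject_uv`` rejection (default: all).  Raises if every trial is
    rejected or the sampling rate cannot support the band.
    """
    if eeg.sfreq < 2 * band[1]:
        raise ValueError(f"sample rate {eeg.sfreq} Hz too low for band {band}")
    sos = signal.butter(order, band, btype="bandpass", fs=eeg.sfreq, output="sos")
    filt = signal.sosfiltfilt(sos, eeg.data, axis=-1)

    frac = Fraction(resample_to / eeg.sfreq).limit_denominator(1000)
    data = signal.resample_poly(filt, frac.numerator, frac.denominator, axis=-1)
    n_new = data.shape[-1]
    times = eeg.times[0] + np.arange(n_new) / resample_to

    if central_channels is None:
        idx = np.arange(data.shape[1])
    else:
        idx = np.array([eeg.channel_index(c) for c in central_channels])
    peak = np.max(np.abs(data[:, idx, :]), axis=(1, 2))
    rejected = np.flatnonzero(peak > reject_uv)
    keep = np.setdiff1d(np.arange(data.shape[0]), rejected)
    if keep.size == 0:
        raise ValueError("all trials rejected by the amplitude criterion")
    return EpochedEEG(data=data[keep], times=times, sfreq=resample_to,
                      ch_names=list(eeg.ch_names),
                      rejected_trials=list(map(int, rejected)))


def time_mirror_pad(eeg: EpochedEEG, fade: str = "hanning",
                    fade_s: float = 0.0) -> EpochedEEG:
    """Mirror the pre-stimulus segment over the stimulus period and the left edge.

    Post-onset samples are replaced by time-mirrored pre-stimulus data so
    wavelet estimates at t < 0 are uncontaminated by post-stimulus
    activity (the mirror is value-continuous at onset).  With
    ``fade_s`` > 0 a half-Hanning window cross-fades the original
    stimulus-period signal into the mirror instead of discarding it
    outright; this re-admits a controlled amount of post-onset signal and
    is off by default.  The pre-stimulus segment itself is untouched, and
    the epoch is additionally extended to the left with its mirror image
    so low-frequency wavelets have support at early pre-stimulus times.
    """
    pre_sel = eeg.times < 0
    n_pre = int(pre_sel.sum())
    if n_pre < 2:
        raise ValueError("epoch must cover a pre-stimulus period")
    pre = eeg.data[:, :, :n_pre]
    n_post = eeg.data.shape[2] - n_pre
    mirror = pre[:, :, ::-1]

    out_post = mirror[:, :, :n_post].copy()
    if n_post > mirror.shape[2]:
        # epoch longer than the pre-stimulus segment: keep reflecting
        reps = int(np.ceil(n_post / n_pre)) + 1
        tiled = np.concatenate([mirror, pre] * reps, axis=2)
        out_post = tiled[:, :, :n_post].copy()
    if fade == "hanning" and n_post > 0 and fade_s > 0:
        m = min(int(round(fade_s * eeg.sfreq)), n_post)
        if m > 1:
            w = 0.5 * (1 + np.cos(np.pi * np.arange(m) / (m - 1)))  # 1 -> 0
            out_post[:, :, :m] = (w * eeg.data[:, :, n_pre:n_pre + m]
                                  + (1 - w) * out_post[:, :, :m])
    elif fade not in ("hanning", None, "none"):
        raise ValueError(f"unknown fade {fade!r}")

    data = np.concatenate([mirror, pre, out_post], axis=2)
    t0 = eeg.times[0] - n_pre / eeg.sfreq
    times = t0 + np.arange(data.shape[2]) / eeg.sfreq
    return EpochedEEG(data=data, times=times, sfreq=eeg.sfreq,
                      ch_names=list(eeg.ch_names),
                      rejected_trials=list(eeg.rejected_trials))


def morlet_tf(eeg: EpochedEEG, freqs=None, n_cycles: float = 4.0,
              decim: int = 1) -> TFDecomposition:
    """Morlet wavelet decomposition (energy-normalized, 4 cycles default).

    Raises when the epoch is shorter than the wavelet support at the
    lowest frequency; ``decim`` thins the output time axis.
    """
    freqs = default_tf_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    duration = eeg.times[-1] - eeg.times[0]
    for f in freqs:
        # full wavelet support is 10 sigma_t = 10 * n_cycles / (2 pi f)
        need = 10.0 * n_cycles / (2 * np.pi * f)
        if duration < need:
            raise ValueError(f"epoch of {duration:.2f} s too short for "
                             f"{n_cycles} cycles at {f:.2f} Hz "
                             f"(need {need:.2f} s; mirror-pad the epoch)")
    out = tfr_array_morlet(eeg.data, sfreq=eeg.sfreq, freqs=freqs,
                           n_cycles=n_cycles, output="complex", decim=decim)
    return TFDecomposition(power=np.abs(out) ** 2, phase=np.angle(out),
                           freqs=freqs, times=eeg.times[::decim],
                           ch_names=list(eeg.ch_names))


def select_timepoint(pvals: np.ndarray, times: np.ndarray,
                     alpha: float = 0.05):
    """Pre-stimulus time with the most significant channels across frequencies.

    ``pvals`` is (channel, freq, time); returns ``(time_s, counts)`` where
    counts is the per-time number of sub-threshold (channel, freq) cells.
    Ties resolve to the earliest (most negative) time.
    """
    pvals = np.asarray(pvals)
    if pvals.ndim != 3 or pvals.shape[2] != len(times):
        raise ValueError("pvals must be (channel, freq, time) matching times")
    counts = (pvals < alpha).sum(axis=(0, 1))
    best = int(np.argmax(counts))     # argmax returns the first (earliest) tie
    return float(times[best]), counts


def eeg_spectrum(eeg: EpochedEEG, window=None, channels=None,
                 nperseg: int | None = None):
    """Trial- and channel-averaged amplitude spectrum (Welch).

    ``window`` restricts the time range (e.g. the stimulus period);
    returns ``(freqs, amplitude)``.
    """
    data = eeg.data
    if channels is not None:
        idx = [eeg.channel_index(c) for c in channels]
        data = data[:, idx, :]
    if window is not None:
        sel = (eeg.times >= window[0]) & (eeg.times <= window[1])
        data = data[:, :, sel]
    n = data.shape[-1]
    nperseg = min(n, 512) if nperseg is None else min(n, nperseg)
    freqs, psd = signal.welch(data, fs=eeg.sfreq, nperseg=nperseg, axis=-1)
    return freqs, np.sqrt(psd.mean(axis=(0, 1)))


def save_epochs(path, eeg: EpochedEEG) -> None:
    """Write an epoch container to HDF5 (data, times, sfreq, names)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=eeg.data)
        f.create_dataset("times", data=eeg.times)
        f.attrs["sfreq"] = eeg.sfreq
        f.create_dataset("ch_names", data=np.array(eeg.ch_names, dtype="S"))
        f.create_dataset("rejected_trials",
                         data=np.asarray(eeg.rejected_trials, dtype=int))


def load_epochs(path) -> EpochedEEG:
    """Read an epoch container written by :func:`save_epochs`."""
    import h5py

    with h5py.File(path, "r") as f:
        return EpochedEEG(
            data=f["data"][()], times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            ch_names=[n.decode() for n in f["ch_names"][()]],
            rejected_trials=[int(i) for i in f["rejected_trials"][()]])


def rereference(eeg: EpochedEEG, reference="average") -> EpochedEEG:
    """Re-reference to the channel average or to named channels (plumbing)."""
    if reference == "average":
        ref = eeg.data.mean(axis=1, keepdims=True)
    else:
        idx = [eeg.channel_index(c) for c in np.atleast_1d(reference)]
        ref = eeg.data[:, idx, :].mean(axis=1, keepdims=True)
    return EpochedEEG(data=eeg.data - ref, times=eeg.times, sfreq=eeg.sfreq,
                      ch_names=list(eeg.ch_names),
                      rejected_trials=list(eeg.rejected_trials))
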