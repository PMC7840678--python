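"""Parametric tone-cloud soundscapes.

A soundscape is a 1.2 s acoustic scene composed of 30 simultaneously
presented sequences of four 30 ms pure tones.  Each sequence sweeps up or
down in frequency in 20-cent steps; the fraction of sequences sweeping in
the trial's nominal direction ("coherence") is set independently for each
of ten 120 ms epochs.  The per-epoch sensory evidence is the fraction of
upward sequences, i.e. ``e = 0.5 + direction * coherence / 2``: 0.5 is
ambiguous, 1 a fully coherent upward sweep, 0 a fully coherent downward
sweep.

The module generates such stimuli, reports their realized (count-quantized)
evidence traces, renders audio, and computes band-limited envelope
modulation spectra used to verify that the stimulus itself carries no
rhythm at the 1-4 Hz analysis time scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

__all__ = [
    "Tone",
    "Sequence",
    "SoundscapeSpec",
    "generate_soundscape",
    "evidence_trace",
    "realized_coherences",
    "synthesize_waveform",
    "modulation_spectrum",
    "modulation_peak_ratio",
    "quantized_evidence",
    "write_wav",
]

#: duration of one tone (s)
TONE_DURATION_S = 0.030
#: duration of one evidence epoch (s); 4 tone slots
EPOCH_S = 0.120
#: number of evidence epochs per stimulus
N_EPOCHS = 10
#: nominal stimulus duration (s)
STIM_DURATION_S = N_EPOCHS * EPOCH_S
#: tones per sequence
TONES_PER_SEQ = 4
#: default number of simultaneous sequences
N_SEQUENCES = 30
#: frequency step between consecutive tones of a sequence (cents)
STEP_CENTS = 20.0
#: range from which sequence start frequencies are drawn (Hz)
START_FREQ_RANGE_HZ = (128.0, 16384.0)

_N_SLOTS = N_EPOCHS * TONES_PER_SEQ  # 30 ms tone slots per stimulus


@dataclass(frozen=True)
class Tone:
    """A single pure tone: frequency, onset and (fixed) duration."""

    freq_hz: float
    onset_s: float
    duration_s: float = TONE_DURATION_S

    def __post_init__(self):
        if self.freq_hz <= 0:
            raise ValueError(f"tone frequency must be positive, got {self.freq_hz}")
        if self.onset_s < 0:
            raise ValueError(f"tone onset must be >= 0, got {self.onset_s}")


@dataclass(frozen=True)
class Sequence:
    """One four-tone sweep: direction label, epoch assignment and tones."""

    direction: int           # +1 up-sweep, -1 down-sweep
    epoch: int               # epoch containing the nominal (un-jittered) onset
    start_freq_hz: float
    onset_slot: int          # 30 ms slot of the nominal onset (may be < 0)
    tones: tuple[Tone, ...]


@dataclass
class SoundscapeSpec:
    """Full parametric description of one trial's stimulus."""

    direction: int
    coherences: np.ndarray            # requested, length 10, in [0, 1]
    sequences: list[Sequence]
    n_up: np.ndarray                  # per-epoch count of up-sweeping sequences
    n_active: np.ndarray              # per-epoch count of sequences assigned
    seed: int | None = None

    def to_json(self) -> str:
        d = asdict(self)
        d["coherences"] = list(map(float, self.coherences))
        d["n_up"] = list(map(int, self.n_up))
        d["n_active"] = list(map(int, self.n_active))
        return json.dumps(d)


def quantized_evidence(direction: int, coherences: np.ndarray,
                       n_sequences: int = N_SEQUENCES) -> np.ndarray:
    """Evidence trace after quantizing coherence to sequence counts.

    The number of direction-congruent sequences out of ``n_sequences`` is
    ``round(n * (1 + c) / 2)``; evidence is the resulting fraction of
    upward sequences.  This is the count-level idealization used when
    simulating behavior without rendering tones.
    """
    coherences = np.asarray(coherences, dtype=float)
    n_congruent = np.round(n_sequences * (1.0 + coherences) / 2.0).astype(int)
    n_up = n_congruent if direction > 0 else n_sequences - n_congruent
    return n_up / n_sequences


def generate_soundscape(direction: int, coherences, *, seed=None,
                        n_sequences: int = N_SEQUENCES,
                        clip_policy: str = "error",
                        start_freq_dist: str = "log",
                        replace_finished: bool = True,
                        jitter_s: float = 0.030) -> SoundscapeSpec:
    """Generate one tone-cloud stimulus.

    Parameters
    ----------
    direction : {+1, -1}
        Nominal sweep direction of the trial.
    coherences : array-like of 10 floats in [0, 1]
        Requested per-epoch coherence.
    seed : int, optional
        Seed for the stimulus RNG; fixing it makes the spec reproducible.
    clip_policy : {"error", "clip"}
        Whether out-of-range coherences raise or are clipped into [0, 1].
    start_freq_dist : {"log", "linear"}
        Distribution of sequence start frequencies over 128-16384 Hz.
        Log-uniform (default) is perceptually uniform.
    replace_finished : bool
        If True (default) a sequence ending mid-stimulus is immediately
        replaced by a new random sequence, keeping ``n_sequences`` active
        throughout.  If False, lanes fall silent after their first
        sequence.
    jitter_s : float
        Maximal random delay of individual tone onsets (s).
    """
    if direction not in (+1, -1):
        raise ValueError(f"direction must be +1 or -1, got {direction}")
    if n_sequences < 2:
        raise ValueError(f"need at least 2 sequences, got {n_sequences}")
    coherences = np.asarray(coherences, dtype=float)
    if coherences.shape != (N_EPOCHS,):
        raise ValueError(f"expected {N_EPOCHS} coherence values, got shape {coherences.shape}")
    if np.any((coherences < 0) | (coherences > 1)):
        if clip_policy == "clip":
            coherences = np.clip(coherences, 0.0, 1.0)
        else:
            bad = coherences[(coherences < 0) | (coherences > 1)]
            raise ValueError(f"coherence values outside [0, 1]: {bad}; "
                             "pass clip_policy='clip' to clip instead")

    rng = np.random.default_rng(seed)

    # Each of the n_sequences "lanes" plays back-to-back four-tone sequences.
    # The starting position (1-4) of the initial sequence is random, so lane
    # onsets are staggered: a lane starting at position p has sequence onsets
    # at slots -(p-1), -(p-1)+4, ...  A sequence is assigned to the epoch
    # containing its nominal onset (clamped to epoch 0 for the initial
    # partial sequences), which keeps the evidence exactly 10-dimensional.
    start_pos = rng.integers(1, TONES_PER_SEQ + 1, size=n_sequences)
    onset_slots: list[list[int]] = []
    for p in start_pos:
        first = -(int(p) - 1)
        slots = list(range(first, _N_SLOTS, TONES_PER_SEQ))
        if not replace_finished:
            slots = slots[:1]
        onset_slots.append(slots)

    # bucket sequence onsets by epoch
    epoch_members: list[list[tuple[int, int]]] = [[] for _ in range(N_EPOCHS)]
    for lane, slots in enumerate(onset_slots):
        for s in slots:
            ep = max(s, 0) // TONES_PER_SEQ
            epoch_members[ep].append((lane, s))

    sequences: list[Sequence] = []
    n_up = np.zeros(N_EPOCHS, dtype=int)
    n_active = np.zeros(N_EPOCHS, dtype=int)
    lo, hi = START_FREQ_RANGE_HZ
    step = 2.0 ** (STEP_CENTS / 1200.0)

    for ep in range(N_EPOCHS):
        members = epoch_members[ep]
        n = len(members)
        n_active[ep] = n
        if n == 0:
            continue
        n_congruent = int(round(n * (1.0 + coherences[ep]) / 2.0))
        n_up_ep = n_congruent if direction > 0 else n - n_congruent
        n_up[ep] = n_up_ep
        dirs = np.full(n, -1, dtype=int)
        dirs[rng.permutation(n)[:n_up_ep]] = +1
        for (lane, s0), d in zip(members, dirs):
            if start_freq_dist == "log":
                f0 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            elif start_freq_dist == "linear":
                f0 = float(rng.uniform(lo, hi))
            else:
                raise ValueError(f"unknown start_freq_dist {start_freq_dist!r}")
            tones = []
            for k in range(TONES_PER_SEQ):
                slot = s0 + k
                if slot < 0 or slot >= _N_SLOTS:
                    continue  # tone falls outside the stimulus
                onset = slot * TONE_DURATION_S + rng.uniform(0.0, jitter_s)
                tones.append(Tone(freq_hz=f0 * step ** (d * k), onset_s=onset))
            sequences.append(Sequence(direction=int(d), epoch=ep,
                                      start_freq_hz=f0, onset_slot=int(s0),
                                      tones=tuple(tones)))

    return SoundscapeSpec(direction=direction, coherences=coherences,
                          sequences=sequences, n_up=n_up, n_active=n_active,
                          seed=seed)


def evidence_trace(spec: SoundscapeSpec) -> np.ndarray:
    """Per-epoch realized evidence: fraction of up-sweeping sequences.

    Evidence follows ``e = 0.5 + direction * coherence / 2`` with the
    realized (count-quantized) coherence; epochs with no active sequence
    (only possible with ``replace_finished=False``) are ambiguous (0.5).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        e = spec.n_up / spec.n_active
    return np.where(spec.n_active > 0, e, 0.5)


def realized_coherences(spec: SoundscapeSpec) -> np.ndarray:
    """Realized per-epoch coherence implied by the sequence counts."""
    e = evidence_trace(spec)
    return spec.direction * (2.0 * e - 1.0)


def synthesize_waveform(spec: SoundscapeSpec, sample_rate_hz: float = 48000.0,
                        ramp_s: float = 0.005) -> np.ndarray:
    """Render a spec as a mono waveform (equal-amplitude windowed tones).

    Tones get raised-cosine on/off ramps of ``ramp_s``.  Raises if any tone
    frequency exceeds Nyquist.
    """
    tones = [t for seq in spec.sequences for t in seq.tones]
    fmax = max((t.freq_hz for t in tones), default=0.0)
    if fmax > sample_rate_hz / 2.0:
        raise ValueError(f"tone at {fmax:.1f} Hz exceeds Nyquist "
                         f"({sample_rate_hz / 2:.1f} Hz); raise sample_rate_hz")
    total_s = STIM_DURATION_S + 2 * TONE_DURATION_S  # jitter tail allowance
    n = int(np.ceil(total_s * sample_rate_hz))
    wav = np.zeros(n)
    for t in tones:
        i0 = int(round(t.onset_s * sample_rate_hz))
        m = int(round(t.duration_s * sample_rate_hz))
        tt = np.arange(m) / sample_rate_hz
        x = np.sin(2 * np.pi * t.freq_hz * tt)
        nr = max(int(round(ramp_s * sample_rate_hz)), 1)
        if 2 * nr > m:
            nr = m // 2
        if nr > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
            x[:nr] *= ramp
            x[m - nr:] *= ramp[::-1]
        wav[i0:i0 + m] += x[: max(0, n - i0)]
    return wav


def write_wav(path, waveform: np.ndarray, sample_rate_hz: float) -> None:
    """Write a waveform as 16-bit PCM WAV, peak-normalized to -1 dBFS."""
    from scipy.io import wavfile

    w = np.asarray(waveform, dtype=float)
    peak = np.max(np.abs(w))
    if peak > 0:
        w = w / peak * (10 ** (-1 / 20))
    wavfile.write(path, int(sample_rate_hz), (w * 32767).astype(np.int16))


def modulation_spectrum(waveforms, sample_rate_hz: float, n_bands: int = 10,
                        band_lo: float = 100.0, band_hi: float = 12000.0):
    """Average temporal modulation spectra in log-spaced carrier bands.

    For each of ``n_bands`` logarithmically spaced bands between
    ``band_lo`` and ``band_hi`` Hz the waveform is band-pass filtered, the
    Hilbert envelope taken, and the Fourier amplitude spectrum of the
    envelope computed; spectra are averaged across waveforms.

    Returns
    -------
    mod_freqs : (n_freq,) array of modulation frequencies (Hz)
    amplitudes : (n_bands, n_freq) array of average envelope amplitude spectra
    """
    waveforms = [np.asarray(w, dtype=float) for w in waveforms]
    if len(waveforms) == 0:
        raise ValueError("need at least one waveform")
    n = min(len(w) for w in waveforms)
    if n < int(0.1 * sample_rate_hz):
        raise ValueError("waveform too short for band-pass filtering")
    edges = np.logspace(np.log10(band_lo), np.log10(band_hi), n_bands + 1)
    sos = [signal.butter(4, [edges[b], edges[b + 1]], btype="bandpass",
                         fs=sample_rate_hz, output="sos")
           for b in range(n_bands)]
    mod_freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    amps = np.zeros((n_bands, mod_freqs.size))
    for w in waveforms:
        w = w[:n]
        for b in range(n_bands):
            env = np.abs(signal.hilbert(signal.sosfiltfilt(sos[b], w)))
            amps[b] += np.abs(np.fft.rfft(env)) / n
    amps /= len(waveforms)
    return mod_freqs, amps


def modulation_peak_ratio(mod_freqs: np.ndarray, amplitudes: np.ndarray,
                          lo: float = 1.0, hi: float = 4.0,
                          kernel: int = 7) -> float:
    """Largest local-peak-to-trend ratio of the modulation spectrum in [lo, hi] Hz.

    The trend is a running-median smooth of each band's spectrum (excluding
    DC).  A stimulus free of built-in rhythm at the analysis time scales
    has no ratio above ~1.2 in the 1-4 Hz range.
    """
    from scipy.ndimage import median_filter

    sel = (mod_freqs >= lo) & (mod_freqs <= hi)
    if not np.any(sel):
        raise ValueError(f"no modulation frequencies in [{lo}, {hi}] Hz")
    ratios = [1.0]
    for band in np.atleast_2d(amplitudes):
        x = band[1:]  # drop DC, which dominates any median trend
        trend = median_filter(x, size=kernel, mode="nearest")
        trend = np.maximum(trend, np.finfo(float).tiny)
        r = np.ones_like(band)
        r[1:] = x / trend
        # a smoothly decaying spectrum has no local maximum; only genuine
        # local peaks count against the no-rhythm criterion
        peak = np.zeros(band.size, dtype=bool)
        peak[1:-1] = (band[1:-1] > band[:-2]) & (band[1:-1] > band[2:])
        use = sel & peak
        if np.any(use):
            ratios.append(np.max(r[use]))
    return float(np.max(ratios))
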