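"""Synthetic ground-truth cohort: probit observers, staircases, EEG.

The generative observer mirrors the descriptive weight model used in the
analysis: its temporal weights over the ten 120 ms stimulus epochs are the
sum of an offset, a zero-mean linear ramp, a u/v-shaped component (one
cosine cycle over the stimulus) and a rhythmic component at
``rhythm_freq_hz`` (default 2.2 Hz).  The decision variable is the
weighted sum of the momentary evidence (relative to the ambiguous point
0.5) plus Gaussian noise; the response is its sign (a probit observer, the
simplest model under which the reverse-correlation estimator is unbiased).

Trial-wise coupling to brain state enters through the phase of the
rhythmic component: the phase (and/or log-power) of a pre-stimulus EEG
oscillation shifts the observer's rhythmic weighting phase by
``phase_coupling_gain * eeg_phase + power_coupling_gain * eeg_log_power``.
Synthetic EEG epochs contain that oscillation (ground-truth phase
referenced to t = -0.32 s) on top of 1/f background noise, so the
downstream phase/power-binned analyses can be validated against an exact
ledger of implanted parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .soundscapes import EPOCH_S, N_EPOCHS, STIM_DURATION_S, quantized_evidence

__all__ = [
    "ObserverParams",
    "StaircaseConfig",
    "SyntheticEEGParams",
    "CohortData",
    "epoch_centers",
    "observer_weights",
    "simulate_response",
    "run_staircase",
    "run_staircases",
    "simulate_eeg_epoch",
    "simulate_participant_trials",
    "simulate_cohort",
    "evidence_matrix",
]


def epoch_centers() -> np.ndarray:
    """Centers of the ten 120 ms epochs (s from stimulus onset)."""
    return (np.arange(N_EPOCHS) + 0.5) * EPOCH_S


#: rhythmic amplitude (weight units) used for the "strong implant" cohorts
#: in recovery and model-selection demonstrations: large relative to the
#: decision noise, so the rhythmic component dominates the z-scored weight
#: profiles the way it must for frequency recovery to be well posed.
STRONG_RHYTHM_AMP = 4.5


@dataclass(frozen=True)
class ObserverParams:
    """Generative temporal-weighting observer.

    Default weight ratios follow the shape of group-level human weight
    profiles in this paradigm (dominant positive offset, mild downward
    linear trend, negligible u/v component, rhythmic component at 2.2 Hz
    with RMS amplitude about 0.18 of the offset); ``decision_noise_sd``
    is set so that 2-down-1-up staircases converge near coherence 0.32.
    """

    w_offset: float = 1.0
    w_linear: float = -0.23
    w_uv: float = 0.006
    rhythm_amp: float = 0.26
    rhythm_freq_hz: float = 2.2
    rhythm_phase0: float = 0.5
    decision_noise_sd: float = 2.94
    phase_coupling_gain: float = 0.0
    power_coupling_gain: float = 0.0

    def __post_init__(self):
        vals = [self.w_offset, self.w_linear, self.w_uv, self.rhythm_amp]
        if not np.all(np.isfinite(vals)):
            raise ValueError("observer weights must be finite")
        if self.rhythm_amp < 0:
            raise ValueError("rhythm_amp must be >= 0")
        nyquist = 1.0 / (2 * EPOCH_S)  # 120 ms epoch sampling
        if not 0 < self.rhythm_freq_hz <= nyquist + 1e-12:
            raise ValueError(f"rhythm_freq_hz must be in (0, {nyquist:.3f}] Hz")
        if self.decision_noise_sd <= 0:
            raise ValueError("decision_noise_sd must be > 0")


def observer_weights(obs: ObserverParams, eeg_phase: float = 0.0,
                     eeg_log_power: float = 0.0) -> np.ndarray:
    """Trial-specific temporal weights at the ten epoch centers."""
    t = epoch_centers()
    lin = 2.0 * (t - t.mean()) / STIM_DURATION_S        # zero-mean ramp in [-~1, 1]
    uv = np.cos(2 * np.pi * t / STIM_DURATION_S)        # one cycle over the stimulus
    phase = (obs.rhythm_phase0
             + obs.phase_coupling_gain * eeg_phase
             + obs.power_coupling_gain * eeg_log_power)
    rhythm = obs.rhythm_amp * np.cos(2 * np.pi * obs.rhythm_freq_hz * t - phase)
    return obs.w_offset + obs.w_linear * lin + obs.w_uv * uv + rhythm


def simulate_response(evidence, obs: ObserverParams, trial_state=None,
                      rng=None, noise: float | None = None):
    """Binary direction judgment of the probit observer for one trial.

    ``trial_state`` maps ``{"eeg_phase": rad, "eeg_log_power": float}``;
    missing keys default to 0.  Returns ``{"choice": +-1, "dv": float}``
    where choice +1 means "up".
    """
    evidence = np.asarray(evidence, dtype=float)
    if not np.all(np.isfinite(evidence)):
        raise ValueError("evidence contains non-finite values")
    state = trial_state or {}
    w = observer_weights(obs, state.get("eeg_phase", 0.0),
                         state.get("eeg_log_power", 0.0))
    if noise is None:
        rng = np.random.default_rng(rng)
        noise = rng.normal(0.0, obs.decision_noise_sd)
    dv = float(w @ (evidence - 0.5) + noise)
    return {"choice": +1 if dv > 0 else -1, "dv": dv}


@dataclass(frozen=True)
class StaircaseConfig:
    """2-down-1-up staircase settings (three interleaved runs).

    The default keeps the 0.1 coherence step constant throughout
    (``n_step_halvings=0``): with the mean-of-late-reversals estimator,
    per-reversal halving freezes tracks started far from threshold (the
    0.8 start stalls near coherence 0.5) and biases thresholds upward.
    A halving schedule remains available via ``n_step_halvings``.
    """

    starts: tuple[float, ...] = (0.15, 0.4, 0.8)
    initial_step: float = 0.1
    n_reversals_used: int = 6
    n_reversals_discarded: int = 4
    n_step_halvings: int = 0     # halve step at each of the first k reversals
    max_trials: int = 400


def _staircase_trial_correct(obs, coherence, rng) -> bool:
    direction = +1 if rng.random() < 0.5 else -1
    ev = quantized_evidence(direction, np.full(N_EPOCHS, coherence))
    out = simulate_response(ev, obs, rng=rng)
    return out["choice"] == direction


def run_staircase(obs: ObserverParams, start: float, config: StaircaseConfig,
                  rng, respond=None) -> float:
    """One 2-down-1-up track; returns the mean of the late reversals.

    Coherence decreases after two consecutive correct responses and
    increases after every error; the step halves at each of the first
    ``n_step_halvings`` reversals and is fixed thereafter.  ``respond``
    may override the observer with a callable ``(coherence, rng) -> bool``.
    """
    if respond is None:
        respond = lambda c, r: _staircase_trial_correct(obs, c, r)
    n_total = config.n_reversals_discarded + config.n_reversals_used
    coherence = float(start)
    step = config.initial_step
    n_correct = 0
    last_move = 0       # -1 down, +1 up
    reversals: list[float] = []
    for _ in range(config.max_trials):
        correct = respond(coherence, rng)
        move = 0
        if correct:
            n_correct += 1
            if n_correct >= 2:
                move, n_correct = -1, 0
        else:
            move, n_correct = +1, 0
        if move != 0:
            if last_move != 0 and move != last_move:
                reversals.append(coherence)
                if len(reversals) <= config.n_step_halvings:
                    step /= 2.0
                if len(reversals) >= n_total:
                    return float(np.mean(reversals[config.n_reversals_discarded:]))
            last_move = move
            coherence = float(np.clip(coherence + move * step, 0.0, 1.0))
    raise RuntimeError(f"staircase did not reach {n_total} reversals "
                       f"within {config.max_trials} trials")


def run_staircases(obs: ObserverParams, config: StaircaseConfig | None = None,
                   seed=None, respond=None) -> float:
    """Average threshold over the three interleaved staircases."""
    config = config or StaircaseConfig()
    rng = np.random.default_rng(seed)
    return float(np.mean([run_staircase(obs, s, config, rng, respond=respond)
                          for s in config.starts]))


@dataclass(frozen=True)
class SyntheticEEGParams:
    """Parameters of the synthetic pre-stimulus EEG generator.

    One oscillator at ``osc_freq_hz`` with a per-channel topography gain
    rides on 1/f^noise_exponent Gaussian noise.  The oscillation's trial
    phase is referenced to ``t_ref`` (the pre-stimulus time point used by
    the phase analyses), and its amplitude scales with the trial's
    log-power offset, so both are exact ground truth for recovery tests.
    """

    n_channels: int = 64
    sample_rate_hz: float = 1024.0
    osc_freq_hz: float = 4.0
    osc_amp: float = 1.0
    topography: tuple[float, ...] | None = None   # None -> smooth default bump
    noise_exponent: float = 1.0
    noise_amp: float = 1.0
    evoked_amp: float = 0.0
    tmin: float = -1.1
    tmax: float = 1.3
    t_ref: float = -0.32

    def __post_init__(self):
        if not 2.0 <= self.osc_freq_hz <= 13.0:
            raise ValueError("osc_freq_hz must lie in the analyzed 2-13 Hz range")
        if self.topography is not None:
            if len(self.topography) != self.n_channels:
                raise ValueError("topography length must equal n_channels")
            if not np.all(np.isfinite(self.topography)):
                raise ValueError("topography gains must be finite")

    def gains(self) -> np.ndarray:
        if self.topography is not None:
            return np.asarray(self.topography, dtype=float)
        # smooth bump centred on the middle of the channel list
        i = np.arange(self.n_channels)
        return np.exp(-0.5 * ((i - (self.n_channels - 1) / 2)
                              / (self.n_channels / 6)) ** 2)

    def times(self) -> np.ndarray:
        n = int(round((self.tmax - self.tmin) * self.sample_rate_hz))
        return self.tmin + np.arange(n) / self.sample_rate_hz


def _one_over_f_noise(rng, n_channels, n_times, exponent, sample_rate_hz):
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit variance."""
    white = rng.standard_normal((n_channels, n_times))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_times, d=1.0 / sample_rate_hz)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n_times, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_eeg_epoch(params: SyntheticEEGParams, trial_state, rng=None) -> np.ndarray:
    """One trial's raw EEG epoch, channels x time over [tmin, tmax).

    ``trial_state`` carries ``eeg_phase`` (rad, ground-truth oscillation
    phase at ``t_ref``) and ``eeg_log_power`` (log-power offset of the
    oscillation; amplitude scales by exp(log_power / 2)).
    """
    rng = np.random.default_rng(rng)
    t = params.times()
    phase = trial_state.get("eeg_phase", 0.0)
    log_power = trial_state.get("eeg_log_power", 0.0)
    amp = params.osc_amp * np.exp(log_power / 2.0)
    osc = amp * np.cos(2 * np.pi * params.osc_freq_hz * (t - params.t_ref) + phase)
    data = params.gains()[:, None] * osc[None, :]
    if params.noise_amp > 0:
        data = data + params.noise_amp * _one_over_f_noise(
            rng, params.n_channels, t.size, params.noise_exponent,
            params.sample_rate_hz)
    if params.evoked_amp != 0:
        evoked = params.evoked_amp * np.exp(-0.5 * ((t - 0.15) / 0.05) ** 2)
        data = data + params.gains()[:, None] * evoked[None, :]
    return data


def evidence_matrix(trials: pd.DataFrame) -> np.ndarray:
    """(n_trials, 10) evidence from a trial table's coherence columns."""
    cols = [f"c{i}" for i in range(1, N_EPOCHS + 1)]
    c = trials[cols].to_numpy(dtype=float)
    d = trials["direction"].to_numpy(dtype=float)[:, None]
    return 0.5 + d * c / 2.0


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (preserves shape away from bounds)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_participant_trials(obs: ObserverParams, threshold: float,
                                n_trials: int, seed,
                                coherence_sd: float = 0.2,
                                eeg_log_power_sd: float = 0.5) -> pd.DataFrame:
    """Simulate one participant's main-experiment trials.

    Per-epoch coherences are drawn from N(threshold, coherence_sd)
    truncated to [0, 1] by resampling; directions are balanced; the
    stored c1..c10 are the *realized* (count-quantized) coherences so the
    evidence reconstructs exactly.  EEG trial states (phase uniform,
    log-power Gaussian) are drawn here and drive the observer's coupling.
    """
    rng = np.random.default_rng(seed)
    directions = np.repeat([+1, -1], [n_trials - n_trials // 2, n_trials // 2])
    directions = rng.permutation(directions)
    coh = _truncated_normal(rng, threshold, coherence_sd, 0.0, 1.0,
                            (n_trials, N_EPOCHS))
    phases = rng.uniform(-np.pi, np.pi, n_trials)
    log_powers = rng.normal(0.0, eeg_log_power_sd, n_trials)
    noise = rng.normal(0.0, obs.decision_noise_sd, n_trials)

    ev = np.empty((n_trials, N_EPOCHS))
    responses = np.empty(n_trials, dtype=int)
    for i in range(n_trials):
        e = quantized_evidence(int(directions[i]), coh[i])
        ev[i] = e
        out = simulate_response(e, obs,
                                {"eeg_phase": phases[i],
                                 "eeg_log_power": log_powers[i]},
                                noise=noise[i])
        responses[i] = out["choice"]

    realized_coh = directions[:, None] * (2.0 * ev - 1.0)
    df = pd.DataFrame({"trial": np.arange(n_trials), "direction": directions})
    for j in range(N_EPOCHS):
        df[f"c{j + 1}"] = realized_coh[:, j]
    df["response"] = responses
    df["correct"] = (responses == directions).astype(int)
    df["eeg_phase"] = phases
    df["eeg_log_power"] = log_powers
    return df


@dataclass
class CohortData:
    """Output of :func:`simulate_cohort`: trials, thresholds, ground truth."""

    trials: pd.DataFrame                   # all participants, 'participant' column
    thresholds: np.ndarray                 # per participant
    ledger: dict                           # every implanted parameter, JSON-able
    eeg: dict | None = None                # participant -> (trial, ch, time) array
    eeg_params: SyntheticEEGParams | None = None

    def participant_trials(self, p: int) -> pd.DataFrame:
        return self.trials[self.trials["participant"] == p].reset_index(drop=True)

    def ledger_json(self) -> str:
        return json.dumps(self.ledger)


def simulate_cohort(n_participants: int = 20, n_trials: int = 1000,
                    obs_sampler=None, eeg_params: SyntheticEEGParams | None = None,
                    seed=None, staircase_config: StaircaseConfig | None = None,
                    generate_eeg: bool = False) -> CohortData:
    """Simulate a full cohort with per-participant staircase calibration.

    ``obs_sampler(rng) -> ObserverParams`` draws each participant's
    observer (default: mild Gaussian jitter of the default parameters).
    EEG epochs are only rendered when ``generate_eeg`` is True (they are
    large); the trial states that drive the coupling are always drawn and
    recorded in the ledger.
    """
    master = np.random.SeedSequence(seed)
    p_seeds = master.spawn(n_participants)
    if obs_sampler is None:
        obs_sampler = default_observer_sampler()

    frames, thresholds, ledger_parts = [], [], []
    eeg_store = {} if generate_eeg else None
    for p, ss in enumerate(p_seeds):
        s_obs, s_stair, s_trials, s_eeg = ss.spawn(4)
        obs = obs_sampler(np.random.default_rng(s_obs))
        threshold = run_staircases(obs, staircase_config,
                                   seed=np.random.default_rng(s_stair))
        df = simulate_participant_trials(obs, threshold, n_trials, s_trials)
        df.insert(0, "participant", p)
        frames.append(df)
        thresholds.append(threshold)
        ledger_parts.append({
            "participant": p,
            "observer": asdict(obs),
            "threshold": threshold,
            "trial_seed": s_trials.entropy if isinstance(s_trials.entropy, int)
                          else list(s_trials.entropy),
            "spawn_key": list(s_trials.spawn_key),
            "eeg_phase": df["eeg_phase"].tolist(),
            "eeg_log_power": df["eeg_log_power"].tolist(),
        })
        if generate_eeg:
            if eeg_params is None:
                raise ValueError("generate_eeg=True requires eeg_params")
            rng = np.random.default_rng(s_eeg)
            epochs = np.stack([
                simulate_eeg_epoch(eeg_params,
                                   {"eeg_phase": df["eeg_phase"].iloc[i],
                                    "eeg_log_power": df["eeg_log_power"].iloc[i]},
                                   rng)
                for i in range(n_trials)])
            eeg_store[p] = epochs

    ledger = {"seed": seed, "n_participants": n_participants,
              "n_trials": n_trials, "participants": ledger_parts}
    return CohortData(trials=pd.concat(frames, ignore_index=True),
                      thresholds=np.asarray(thresholds), ledger=ledger,
                      eeg=eeg_store, eeg_params=eeg_params)


def default_observer_sampler(rhythm_amp: float = 0.26,
                             rhythm_freq_hz: float = 2.2,
                             phase_coupling_gain: float = 0.0,
                             power_coupling_gain: float = 0.0,
                             between_subject_sd: float = 0.05,
                             phase0_sd: float = 0.3):
    """Sampler of per-participant observers around the default parameters.

    Weight components jitter by ``between_subject_sd`` (absolute, weight
    units) and the preferred rhythmic phase by ``phase0_sd`` around a
    cohort-common phase, emulating the between-participant consistency of
    human rhythmic components.
    """
    base = ObserverParams()

    def sample(rng) -> ObserverParams:
        return replace(
            base,
            w_offset=base.w_offset + between_subject_sd * rng.standard_normal(),
            w_linear=base.w_linear + between_subject_sd * rng.standard_normal(),
            w_uv=base.w_uv + between_subject_sd * rng.standard_normal(),
            rhythm_amp=max(rhythm_amp + between_subject_sd * rng.standard_normal(), 0.0),
            rhythm_freq_hz=rhythm_freq_hz,
            rhythm_phase0=base.rhythm_phase0 + phase0_sd * rng.standard_normal(),
            phase_coupling_gain=phase_coupling_gain,
            power_coupling_gain=power_coupling_gain,
        )

    return sample
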