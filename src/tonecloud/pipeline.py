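"""End-to-end orchestration of the synthetic-cohort analysis.

``run_full`` executes simulate -> weights -> modelcompare -> eeglink ->
stats -> report on one :class:`RunConfig`, writing every intermediate to
a run directory (trial tables and weights as TSV, comparisons and cluster
reports as JSON, a manifest with the config and all seeds).  Each stage
is also callable on its own, and the CLI subcommands compose to the same
outputs.

The EEG-linking stage re-estimates the perceptual weights for every
channel x frequency x bin combination.  Because these maps are recomputed
hundreds of times inside the permutation null, the per-bin profiles are
z-scored analytically: per-epoch evidence is i.i.d. across trials, so the
shuffle-null standard deviation of a bin's response contrast is the
within-direction evidence SD scaled by the bin's class counts.  The
global (unbinned) profiles use the full 4000-shuffle permutation
z-scoring; tests verify the analytic scaling matches the permutation
z-scores.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import brain_behavior, cohort, eeg_spectral, inference, revcorr, weight_models
from .cohort import SyntheticEEGParams, evidence_matrix
from .inference import grid_graph
from .soundscapes import N_EPOCHS

__all__ = ["RunConfig", "run_full", "stage_simulate", "stage_weights",
           "stage_modelcompare", "stage_eeglink", "stage_stats", "stage_report",
           "binned_profile_maps", "ConfigError", "DataError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or malformed input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """All tunable constants of the pipeline, schema-validated."""

    # cohort
    n_participants: int = 20
    n_trials: int = 1000
    seed: int = 0
    rhythm_amp: float = 0.26
    rhythm_freq_hz: float = 2.2
    phase_coupling_gain: float = 0.0
    power_coupling_gain: float = 0.0
    between_subject_sd: float = 0.05
    phase0_sd: float = 0.3
    # synthetic EEG (grid montage rows x cols)
    generate_eeg: bool = False
    eeg_rows: int = 8
    eeg_cols: int = 8
    eeg_sfreq: float = 1024.0
    osc_freq_hz: float = 4.0
    osc_amp: float = 1.0
    noise_amp: float = 1.0
    noise_exponent: float = 1.0
    resample_to: float = 150.0
    reject_uv: float = 175.0
    # time-frequency
    tf_freq_lo: float = 2.0
    tf_freq_hi: float = 13.0
    n_cycles: float = 4.0
    tf_decim: int = 3
    # linking
    power_window: tuple = (-0.3, -0.1)
    phase_time_s: float = -0.32
    rhythm_link_freq_hz: float = 2.2
    n_perm_link_null: int = 1000
    min_bin_trials: int = 50
    eeg_chunk: int = 200
    # weights / model comparison
    n_perm_revcorr: int = 4000
    grid_lo: float = 1.1
    grid_hi: float = 4.0
    grid_step: float = 0.1
    n_boot: int = 10000
    # group statistics
    n_perm_cluster: int = 2000
    cluster_t_p: float = 0.05
    min_cluster_size: int = 2
    fdr_q: float = 0.01

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "power_window" in d:
            d = {**d, "power_window": tuple(d["power_window"])}
        try:
            cfg = cls(**d)
        except TypeError as e:
            raise ConfigError(str(e)) from e
        if cfg.n_participants < 1 or cfg.n_trials < 1:
            raise ConfigError("n_participants and n_trials must be positive")
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["power_window"] = list(d["power_window"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @property
    def n_channels(self) -> int:
        return self.eeg_rows * self.eeg_cols

    def tf_freqs(self) -> np.ndarray:
        return np.arange(self.tf_freq_lo, self.tf_freq_hi + 0.5)

    def frequency_grid(self) -> np.ndarray:
        return weight_models.default_frequency_grid(self.grid_lo, self.grid_hi,
                                                    self.grid_step)

    def eeg_params(self) -> SyntheticEEGParams:
        gains = _grid_topography(self.eeg_rows, self.eeg_cols)
        return SyntheticEEGParams(n_channels=self.n_channels,
                                  sample_rate_hz=self.eeg_sfreq,
                                  osc_freq_hz=self.osc_freq_hz,
                                  osc_amp=self.osc_amp,
                                  topography=tuple(gains),
                                  noise_exponent=self.noise_exponent,
                                  noise_amp=self.noise_amp)


def _grid_topography(rows: int, cols: int) -> np.ndarray:
    """Smooth Gaussian gain bump centred on the montage grid."""
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = ((r - (rows - 1) / 2) / max(rows / 4, 1)) ** 2 + \
         ((c - (cols - 1) / 2) / max(cols / 4, 1)) ** 2
    return np.exp(-0.5 * d2).ravel()


# ---------------------------------------------------------------- stages

def stage_simulate(config: RunConfig, out_dir=None) -> cohort.CohortData:
    """Simulate the cohort (behavior + ground-truth ledger; EEG is lazy)."""
    sampler = cohort.default_observer_sampler(
        rhythm_amp=config.rhythm_amp, rhythm_freq_hz=config.rhythm_freq_hz,
        phase_coupling_gain=config.phase_coupling_gain,
        power_coupling_gain=config.power_coupling_gain,
        between_subject_sd=config.between_subject_sd,
        phase0_sd=config.phase0_sd)
    data = cohort.simulate_cohort(config.n_participants, config.n_trials,
                                  obs_sampler=sampler, seed=config.seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        data.trials.to_csv(out / "trials.tsv", sep="\t", index=False)
        (out / "ledger.json").write_text(data.ledger_json())
    return data


def stage_weights(config: RunConfig, trials: pd.DataFrame,
                  out_dir=None) -> list:
    """Global reverse-correlation weight profile per participant."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    cache: dict = {}
    profiles = []
    for p, df in trials.groupby("participant"):
        profiles.append(revcorr.perceptual_weights(
            df, n_perm=config.n_perm_revcorr, seed=rng, participant_id=int(p),
            perm_cache=cache))
    if out_dir is not None:
        revcorr.weights_to_frame(profiles).to_csv(
            Path(out_dir) / "weights.tsv", sep="\t", index=False)
    return profiles


def stage_modelcompare(config: RunConfig, profiles, out_dir=None) -> dict:
    """Frequency scan + trivial-vs-rhythmic group comparison."""
    scan = weight_models.scan_frequencies(profiles, config.frequency_grid())
    comp = weight_models.group_comparison(
        scan, n_boot=config.n_boot,
        seed=np.random.SeedSequence([config.seed, 202]).generate_state(1)[0])
    result = {"best_freq_hz": comp.best_freq_hz,
              "delta_neg_log_ev": comp.delta_neg_log_ev,
              "exceedance_prob": comp.exceedance_prob,
              "model_frequency": comp.model_frequency,
              "grid_hz": scan.grid_hz.tolist(),
              "group_logev": scan.group_logev.tolist(),
              "group_logev_trivial": float(scan.logev_trivial.sum()),
              "participant_best_freqs": scan.participant_best_freqs.tolist()}
    if out_dir is not None:
        (Path(out_dir) / "modelcompare.json").write_text(json.dumps(result, indent=1))
    return result


def participant_eeg_extracts(config: RunConfig, trials_p: pd.DataFrame,
                             participant: int):
    """Simulate, preprocess and decompose one participant's EEG.

    Returns per-trial ``phase`` and ``power`` arrays of shape
    (n_trials, n_channels, n_freqs): phase at ``phase_time_s``, power
    averaged over ``power_window``.  EEG epochs are generated and
    processed in chunks and never kept whole.
    """
    params = config.eeg_params()
    freqs = config.tf_freqs()
    n = len(trials_p)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 303, int(participant)]))
    phases_out = np.empty((n, config.n_channels, freqs.size), dtype=np.float32)
    powers_out = np.empty_like(phases_out)
    for start in range(0, n, config.eeg_chunk):
        stop = min(start + config.eeg_chunk, n)
        raw = np.stack([
            cohort.simulate_eeg_epoch(
                params,
                {"eeg_phase": trials_p["eeg_phase"].iloc[i],
                 "eeg_log_power": trials_p["eeg_log_power"].iloc[i]}, rng)
            for i in range(start, stop)])
        eeg = eeg_spectral.EpochedEEG(data=raw, times=params.times(),
                                      sfreq=params.sample_rate_hz)
        eeg = eeg_spectral.preprocess(eeg, resample_to=config.resample_to,
                                      reject_uv=config.reject_uv)
        if eeg.rejected_trials:
            raise DataError("synthetic EEG rejected trials; raise reject_uv")
        eeg = eeg_spectral.time_mirror_pad(eeg)
        tf = eeg_spectral.morlet_tf(eeg, freqs=freqs, n_cycles=config.n_cycles,
                                    decim=config.tf_decim)
        ti = tf.time_index(config.phase_time_s)
        sel = (tf.times >= config.power_window[0]) & \
              (tf.times <= config.power_window[1])
        phases_out[start:stop] = tf.phase[:, :, :, ti]
        powers_out[start:stop] = tf.power[:, :, :, sel].mean(axis=3)
    return phases_out, powers_out


# ------------------------------------------------- vectorized linking maps

def _design_solver(rhythm_freq_hz: float):
    """Precompute the ridge solve so thousands of fits become one matmul."""
    design = weight_models.DesignSpec(rhythm_freq_hz=rhythm_freq_hz)
    _, X_std, scales = design.matrix()
    p = X_std.shape[1]
    prec = design.ridge_lambda * np.eye(p) + X_std.T @ X_std
    solver = np.linalg.solve(prec, X_std.T).T       # (10, p): betas_std = y @ solver
    return solver, scales, design


def binned_profile_maps(E: np.ndarray, responses: np.ndarray,
                        directions: np.ndarray, masks: np.ndarray,
                        solver, scales, min_count: int = 5):
    """Weight profiles + model fits for many trial bins at once.

    ``masks`` is (n_bins, n_trials) boolean.  The per-bin contrast
    (mean evidence | up) - (mean evidence | down), averaged over the two
    direction subsets, is z-scored analytically against the response-
    shuffle null (evidence is i.i.d. across trials, so the null SD is the
    within-direction evidence SD scaled by the class counts) and fitted
    with the precomputed ridge ``solver``.

    Returns ``(betas, phase, rms, valid)`` with betas (n_bins, p) in the
    raw regressor basis.
    """
    masks = np.asarray(masks, dtype=bool)
    m, n = masks.shape
    raw = np.zeros((m, N_EPOCHS))
    var = np.zeros((m, N_EPOCHS))
    valid = np.ones(m, dtype=bool)
    for s in (+1, -1):
        ds = directions == s
        up = (ds & (responses > 0)).astype(float)
        down = (ds & (responses < 0)).astype(float)
        cu = masks @ up
        cd = masks @ down
        ok = (cu >= min_count) & (cd >= min_count)
        valid &= ok
        cu = np.maximum(cu, 1.0)
        cd = np.maximum(cd, 1.0)
        W = (masks * up) / (2 * cu[:, None]) - (masks * down) / (2 * cd[:, None])
        raw += W @ E
        v_s = E[ds].var(axis=0, ddof=1) if ds.sum() > 1 else np.ones(N_EPOCHS)
        var += 0.25 * v_s[None, :] * (1.0 / cu + 1.0 / cd)[:, None]
    z = raw / np.sqrt(var)
    betas_std = z @ solver                         # (m, p)
    betas = betas_std / scales[None, :]
    phase = np.arctan2(betas[:, 3], betas[:, 4])
    rms = np.hypot(betas[:, 3], betas[:, 4]) / np.sqrt(2.0)
    return betas, phase, rms, valid


_COMPONENTS = ("offset", "linear", "uv", "rhythm_rms")


def _participant_bin_masks(power_ext, phase_ext) -> np.ndarray:
    """All bin masks of one participant, (n_masks, n_trials) boolean.

    Mask order: per (channel, freq) cell the power median split (low,
    high), then per cell the 4 phase divisions x 2 bins.  Precomputing
    these lets the permuted-alignment null reuse them: permuting the
    EEG-trial pairing is just a column permutation of the masks.
    """
    n = power_ext.shape[0]
    flat_pow = power_ext.reshape(n, -1)
    rank = np.argsort(np.argsort(flat_pow, axis=0, kind="stable"), axis=0)
    high = (rank >= (n // 2)).T                       # (cells, n) high-power bin
    masks_pow = np.concatenate([~high[:, None, :], high[:, None, :]], axis=1)
    masks_pow = masks_pow.reshape(-1, n)              # cell-major: low, high

    flat_ph = phase_ext.reshape(n, -1).T              # (cells, n)
    masks_phase = []
    for k in range(4):
        # same convention as brain_behavior.split_by_phase: half-circles
        # centred on k*pi/4 and k*pi/4 + pi
        rel = np.mod(flat_ph - k * np.pi / 4.0 + np.pi / 2.0, 2 * np.pi)
        b1 = rel >= np.pi
        masks_phase.append(np.stack([~b1, b1], axis=1))
    masks_phase = np.stack(masks_phase, axis=1).reshape(-1, n)  # cell,div,bin
    return np.concatenate([masks_pow, masks_phase], axis=0)


def _participant_link_effects(E, responses, directions, masks, n_ch, n_freq,
                              solver, scales, order=None, min_count=5):
    """One participant's linking-effect maps from precomputed bin masks.

    ``order`` optionally permutes the EEG-trial alignment (the null).
    Returns dict with "power" (signed bin diffs, component -> (ch, freq)),
    "power_absphi" (ch, freq), "phase" (component -> (ch, freq, 4) absolute
    diffs) and "phase_absphi" (ch, freq, 4).
    """
    if order is not None:
        masks = masks[:, order]
    betas, phase, rms, valid = binned_profile_maps(
        E, responses, directions, masks, solver, scales, min_count=min_count)
    comp = np.column_stack([betas[:, 0], betas[:, 1], betas[:, 2], rms])
    comp[~valid] = 0.0
    phase = np.where(valid, phase, 0.0)

    n_cells = n_ch * n_freq
    cp = comp[:2 * n_cells].reshape(n_cells, 2, 4)
    php = phase[:2 * n_cells].reshape(n_cells, 2)
    power_eff = {name: (cp[:, 1, i] - cp[:, 0, i]).reshape(n_ch, n_freq)
                 for i, name in enumerate(_COMPONENTS)}
    dphi = brain_behavior.wrap_angle(php[:, 1] - php[:, 0])
    power_absphi = np.abs(dphi).reshape(n_ch, n_freq) * 180.0 / np.pi

    cq = comp[2 * n_cells:].reshape(n_cells, 4, 2, 4)
    phq = phase[2 * n_cells:].reshape(n_cells, 4, 2)
    phase_eff = {name: np.abs(cq[:, :, 1, i] - cq[:, :, 0, i])
                 .reshape(n_ch, n_freq, 4) for i, name in enumerate(_COMPONENTS)}
    dphi_q = brain_behavior.wrap_angle(phq[:, :, 1] - phq[:, :, 0])
    phase_absphi = np.abs(dphi_q).reshape(n_ch, n_freq, 4) * 180.0 / np.pi
    return {"power": power_eff, "power_absphi": power_absphi,
            "phase": phase_eff, "phase_absphi": phase_absphi}


def stage_eeglink(config: RunConfig, data: cohort.CohortData,
                  out_dir=None) -> dict:
    """EEG simulation + TF extraction + linking-effect maps with nulls.

    Returns observed per-participant effect maps and the permuted-
    alignment null group maps (shared across effect families), ready for
    :func:`stage_stats`.
    """
    solver, scales, _ = _design_solver(config.rhythm_link_freq_hz)
    n_ch, n_freq = config.n_channels, config.tf_freqs().size
    min_count = max(config.min_bin_trials // 8, 5)
    per_part = []
    observed = []
    for p in range(config.n_participants):
        tp = data.participant_trials(p)
        phase_ext, power_ext = participant_eeg_extracts(config, tp, p)
        E = evidence_matrix(tp)
        r = tp["response"].to_numpy()
        d = tp["direction"].to_numpy()
        masks = _participant_bin_masks(power_ext, phase_ext)
        per_part.append((E, r, d, masks))
        observed.append(_participant_link_effects(
            E, r, d, masks, n_ch, n_freq, solver, scales,
            min_count=min_count))

    # permuted trial<->EEG alignment null, one pass shared by all families
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    n_perm = config.n_perm_link_null
    null_maps = {f"phase_{c}": np.empty((n_perm, n_ch, n_freq))
                 for c in _COMPONENTS}
    null_maps["phase_absphi"] = np.empty((n_perm, n_ch, n_freq))
    null_maps["power_absphi"] = np.empty((n_perm, n_ch, n_freq))
    for i in range(n_perm):
        acc = {k: np.zeros((n_ch, n_freq)) for k in null_maps}
        for (E, r, d, masks) in per_part:
            order = rng.permutation(E.shape[0])
            eff = _participant_link_effects(E, r, d, masks, n_ch, n_freq,
                                            solver, scales, order=order,
                                            min_count=min_count)
            for c in _COMPONENTS:
                acc[f"phase_{c}"] += eff["phase"][c].max(axis=-1)
            acc["phase_absphi"] += eff["phase_absphi"].max(axis=-1)
            acc["power_absphi"] += eff["power_absphi"]
        for k in null_maps:
            null_maps[k][i] = acc[k] / len(per_part)

    result = {"observed": observed, "null_maps": null_maps}
    if out_dir is not None:
        np.savez_compressed(Path(out_dir) / "linkmaps.npz",
                            **{f"null_{k}": v for k, v in null_maps.items()})
    return result


def stage_stats(config: RunConfig, link: dict, out_dir=None) -> dict:
    """Group statistics over the linking maps, FDR-corrected across families."""
    observed = link["observed"]
    null_maps = link["null_maps"]
    graph = grid_graph(config.eeg_rows, config.eeg_cols)
    seed_stats = np.random.SeedSequence([config.seed, 505])
    rngs = iter(seed_stats.generate_state(20))

    families: dict = {}
    # signed power-bin differences: sign-flip cluster test per component
    for c in _COMPONENTS:
        eff = np.stack([o["power"][c] for o in observed])
        res = inference.cluster_perm_test(
            eff, graph, n_perm=config.n_perm_cluster,
            t_thresh_p=config.cluster_t_p, min_size=config.min_cluster_size,
            seed=next(rngs))
        families[f"power_{c}"] = res
    # non-negative contrasts: shared permuted-alignment null
    eff = np.stack([o["power_absphi"] for o in observed])[..., None]
    families["power_absphi"] = inference.max_division_from_null(
        eff, null_maps["power_absphi"], graph, min_size=config.min_cluster_size)
    for c in _COMPONENTS:
        eff = np.stack([o["phase"][c] for o in observed])
        families[f"phase_{c}"] = inference.max_division_from_null(
            eff, null_maps[f"phase_{c}"], graph,
            min_size=config.min_cluster_size)
    eff = np.stack([o["phase_absphi"] for o in observed])
    families["phase_absphi"] = inference.max_division_from_null(
        eff, null_maps["phase_absphi"], graph,
        min_size=config.min_cluster_size)

    min_ps = {k: (min((c["p"] for c in v.clusters), default=1.0))
              for k, v in families.items()}
    keys = sorted(min_ps)
    flags = inference.fdr_bh(np.array([min_ps[k] for k in keys]), q=config.fdr_q)
    fdr = dict(zip(keys, map(bool, flags)))

    report = {"families": {}, "fdr_significant": fdr, "fdr_q": config.fdr_q}
    for k, v in families.items():
        report["families"][k] = {
            "clusters": [{kk: c[kk] for kk in
                          ("channels", "freq_indices", "mass", "size", "p")}
                         for c in v.clusters],
            "min_p": min_ps[k]}

    # headline phase-shift summaries at the strongest group cell
    freqs = config.tf_freqs()
    for key in ("power_absphi", "phase_absphi"):
        eff = np.stack([o[key] for o in observed])
        if eff.ndim == 3:
            eff = eff[..., None]
        grp = inference.reduce_max_division(eff)
        ch, fi = np.unravel_index(np.argmax(grp), grp.shape)
        shifts = eff.max(axis=-1)[:, ch, fi]
        report[f"{key}_summary"] = {
            "channel": int(ch), "freq_hz": float(freqs[fi]),
            **brain_behavior.group_phase_shift(shifts)}

    if out_dir is not None:
        (Path(out_dir) / "clusters.json").write_text(json.dumps(report, indent=1))
    return report


def stage_report(config: RunConfig, out_dir, profiles=None, modelcomp=None,
                 stats=None) -> dict:
    """Figures and a run summary, regenerated from serialized intermediates."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    made = []
    if profiles is None and (out / "weights.tsv").exists():
        wf = pd.read_csv(out / "weights.tsv", sep="\t")
        wf = wf[wf["bin"].isna()] if wf["bin"].notna().any() else wf
        prof_mat = wf.pivot_table(index="participant", columns="epoch",
                                  values="z").to_numpy()
    elif profiles is not None:
        prof_mat = np.stack([p.z_weights for p in profiles])
    else:
        prof_mat = None
    if prof_mat is not None:
        fig, ax = plt.subplots()
        t = cohort.epoch_centers()
        ax.plot(t, prof_mat.T, color="0.8", lw=0.8)
        ax.plot(t, prof_mat.mean(axis=0), color="k", lw=2)
        ax.set(xlabel="time in stimulus (s)", ylabel="perceptual weight (z)")
        fig.savefig(out / "weights.png", dpi=120)
        plt.close(fig)
        made.append("weights.png")
    if modelcomp is None and (out / "modelcompare.json").exists():
        modelcomp = json.loads((out / "modelcompare.json").read_text())
    if modelcomp is not None:
        fig, ax = plt.subplots()
        ax.plot(modelcomp["grid_hz"], -np.asarray(modelcomp["group_logev"]),
                label="trivial + rhythmic")
        ax.axhline(-modelcomp["group_logev_trivial"], color="k", ls="--",
                   label="trivial")
        ax.set(xlabel="rhythm frequency (Hz)", ylabel="group negLogEv (nats)")
        ax.legend()
        fig.savefig(out / "modelcompare.png", dpi=120)
        plt.close(fig)
        made.append("modelcompare.png")
    summary = {"figures": made, "config": config.to_dict()}
    if stats is not None:
        summary["fdr_significant"] = stats.get("fdr_significant")
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_full(config: RunConfig, out_dir) -> dict:
    """Execute the complete pipeline into ``out_dir``; returns all results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "simulate"
    try:
        data = stage_simulate(config, out)
        results["thresholds"] = data.thresholds.tolist()
        results["sdt"] = [dataclasses.asdict(
            brain_behavior.sdt_measures(data.participant_trials(p)))
            for p in range(config.n_participants)]
        stage = "weights"
        profiles = stage_weights(config, data.trials, out)
        stage = "modelcompare"
        results["modelcompare"] = stage_modelcompare(config, profiles, out)
        stats = None
        if config.generate_eeg:
            stage = "eeglink"
            link = stage_eeglink(config, data, out)
            stage = "stats"
            stats = stage_stats(config, link, out)
            results["stats"] = stats
        stage = "report"
        results["report"] = stage_report(config, out, profiles,
                                         results["modelcompare"], stats)
    except Exception:
        (out / "manifest.json").write_text(json.dumps(
            {"status": "failed", "stage": stage, "config": config.to_dict()},
            indent=1))
        raise
    (out / "manifest.json").write_text(json.dumps(
        {"status": "ok", "config": config.to_dict(),
         "config_digest": config.digest(), "seed": config.seed}, indent=1))
    return results
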