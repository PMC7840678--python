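# tonecloud

Analysis toolkit for a psychophysics + EEG paradigm probing **rhythmic
perceptual sampling**: listeners judge the overall direction (up vs down)
of frequency sweeps in 1.2 s "tone cloud" soundscapes — 30 simultaneous
four-tone sequences whose per-epoch sweep coherence is randomized — while
64-channel EEG is recorded.  The package implements the full analysis
chain and a synthetic observer + EEG cohort with exact ground truth, so
every stage can be validated end to end:

* **Stimuli** (`tonecloud.soundscapes`): parametric tone-cloud generation,
  per-epoch sensory evidence `e_t = 0.5 + d·c_t/2` (0.5 ambiguous, 1 fully
  coherent upward), audio rendering, and band-limited envelope modulation
  spectra (to verify the stimulus has no built-in 1–4 Hz rhythm).
* **Synthetic cohort** (`tonecloud.cohort`): probit observers whose
  temporal weights `w_t = w0 + w1·ℓ(t) + w2·cos(2πt/T) + A·cos(2πf t − φ)`
  drive choices via `sign(Σ_t w_t (e_t − 0.5) + ε)`; 2-down-1-up staircase
  calibration (starts 0.15/0.4/0.8); synthetic pre-stimulus EEG whose 4 Hz
  oscillation phase/power can shift the observer's rhythmic weighting
  phase trial by trial.
* **Reverse correlation** (`tonecloud.revcorr`): per-epoch perceptual
  weights as response-conditioned evidence differences, z-scored against
  4000 stimulus–response shuffles.
* **Weight models** (`tonecloud.weight_models`): Bayesian linear
  regression of weight profiles on trivial (offset, linear, u/v) and
  rhythmic (sin/cos, 1.1–4 Hz scan) components; closed-form model
  evidence, bootstrap exceedance probabilities, model frequencies, and a
  Gibbs-sampled WAIC.  The rhythmic component is summarized by
  `rms = sqrt((β_sin² + β_cos²)/2)` and `phase = atan2(β_sin, β_cos)`.
* **EEG spectral analysis** (`tonecloud.eeg_spectral`): zero-phase 0.6–70
  Hz Butterworth filtering, resampling to 150 Hz, ±175 µV rejection,
  time-mirror padding of the stimulus period, Morlet wavelets (4 cycles,
  2–13 Hz) for single-trial pre-stimulus power and phase.
* **Brain–behavior linking** (`tonecloud.brain_behavior`): d′/criterion,
  phase opposition sum (POS) with Stouffer group combination, median/
  quartile power splits and four-way phase divisions, per-bin weight
  re-estimation and between-bin phase contrasts.
* **Group inference** (`tonecloud.inference`): sign-flip cluster-based
  permutation tests over channel × frequency maps (max-sum statistic,
  minimum cluster size 2), selection-aware permutation nulls for
  max-over-division contrasts, Benjamini–Hochberg FDR across contrast
  families.
* **Pipeline + CLI** (`tonecloud.pipeline`, `tonecloud` command):
  configuration, orchestration, artifacts, figures.

## Worked example

Simulate a 20-observer cohort (1000 trials each, per-epoch coherences
drawn around each observer's staircase threshold with SD 0.2), estimate
perceptual weights, and scan rhythm frequencies:

```python
import numpy as np
from tonecloud import cohort, revcorr, weight_models as wm, brain_behavior

sampler = cohort.default_observer_sampler(rhythm_amp=cohort.STRONG_RHYTHM_AMP)
data = cohort.simulate_cohort(20, 1000, obs_sampler=sampler, seed=1)

sdt = [brain_behavior.sdt_measures(data.participant_trials(p)) for p in range(20)]
print(np.median([m.fraction_correct for m in sdt]))   # 0.7075

rng, cache = np.random.default_rng(0), {}
profiles = [revcorr.perceptual_weights(data.participant_trials(p),
                                       n_perm=4000, seed=rng, perm_cache=cache)
            for p in range(20)]
scan = wm.scan_frequencies(profiles)
print(scan.best_freq_hz)                              # 2.2
comp = wm.group_comparison(scan, seed=0)
print(comp.exceedance_prob, comp.model_frequency)     # 1.0 {'rhythmic': 1.0, ...}
```

The cohort median fraction correct sits near 0.71–0.73 — the value forced by
the 2-down-1-up calibration (70.7 % convergence plus the small accuracy
gain from epoch-wise coherence variability) — and the evidence scan
recovers the implanted 2.2 Hz sampling rhythm with a bootstrap exceedance
probability of 1.

The full EEG linking analysis (synthetic oscillation phase shifting the
observer's sampling phase, phase-binned weight re-fits, cluster
statistics) runs via

```sh
tonecloud run --config myconfig.json --out runs/demo
```

with `generate_eeg: true` in the config; see `tonecloud.pipeline.RunConfig`
for every constant.

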