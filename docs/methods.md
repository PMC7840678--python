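# Methods

## The paradigm and its observables

Each trial presents a 1.2 s tone cloud: 30 simultaneous sequences of four
30 ms pure tones stepping ±20 cents, start frequencies log-uniform over
128–16384 Hz, tone onsets jittered up to 30 ms.  The stimulus is divided
into ten 120 ms epochs; per epoch, the fraction of sequences sweeping in
the trial's nominal direction ("coherence" c_t) is drawn independently.
The per-epoch sensory evidence is e_t = 0.5 + d·c_t/2 with d = ±1 the
nominal direction, so 0.5 is ambiguous and 0/1 fully coherent down/up.
Coherence is realized by counting sequences (n_up = round(n·(1+c)/2) out
of the sequences assigned to that epoch), which quantizes evidence to
steps of 1/30.  Sequences are assigned to the epoch containing their
nominal onset; each lane immediately starts a new random sequence when
one ends, so 30 sequences are always active (finished-sequence
replacement is not observable in the evidence bookkeeping and is
config-exposed).

The analysis estimates, per participant, the *perceptual weight* of each
epoch — the influence of e_t on the binary report — and asks (i) whether
the weight profile carries a rhythmic component in the 1.1–4 Hz range and
(ii) whether the phase of that rhythmic sampling depends on the phase or
power of pre-stimulus EEG oscillations.

## Generative observer

The synthetic observer is a probit ideal-observer variant: temporal
weights

    w_t = w_offset + w_linear·ℓ(t) + w_uv·cos(2π t / T) + A·cos(2π f t − φ_trial)

with ℓ a zero-mean linear ramp, T = 1.2 s, and
φ_trial = φ0 + g_phase·θ_EEG + g_power·log-power.  The decision variable
is D = Σ_t w_t (e_t − 0.5) + ε with ε ~ N(0, σ); the response is
sign(D).  This is the simplest generative model under which the
difference-of-conditional-means reverse-correlation estimator is
(to first order) proportional to the implanted weights.

Default parameters mirror the component *ratios* of group-level human
weight profiles in this paradigm: w_offset = 1, w_linear = −0.23,
w_uv = 0.006, A = 0.26 (rhythm/offset RMS ratio ≈ 0.18), f = 2.2 Hz, and
σ = 2.94, chosen so that the 2-down-1-up staircases converge near
coherence 0.32.  A probit observer at its staircase threshold has a fixed
stimulus–response scale: at 1000 trials the z-scored weights are about
0.7 z per unit generative weight, regardless of σ.  Recovery and
model-selection demonstrations that require the rhythmic component to
dominate the z-profiles therefore use `STRONG_RHYTHM_AMP = 4.5`
(realized z-amplitude ≈ 3), a deliberate stress amplitude rather than a
human-matched one.

### Staircase calibration

Three interleaved 2-down-1-up tracks (starts 0.15/0.4/0.8, step 0.1,
threshold = mean of six reversals after discarding four) converge to the
70.7 %-correct coherence.  The step is kept *constant*: with the
mean-of-late-reversals estimator, halving the step at early reversals
freezes tracks that start far above threshold (the 0.8 start stalls near
coherence 0.5) and biases thresholds upward by ~0.06.  With the constant
step, simulated cohorts give thresholds ≈ 0.33 against a true
70.7 %-point of 0.32, and the main-experiment accuracy follows as
≈ 0.72–0.73: the staircase sets 70.7 %, truncated-Gaussian coherence
sampling (resampling into [0, 1] raises the mean by up to 0.04) adds a
little evidence, and epoch-wise coherence variability subtracts a little.
Median d′ ≈ 1.2 and criterion ≈ 0 follow analytically from the symmetric
design.

## Reverse correlation

raw_t = mean(e_t | "up") − mean(e_t | "down"), computed within each true
direction subset and averaged (removing the direction-induced offset; a
pooled variant exists for noiseless observers, which are otherwise
perfectly correct within subsets).  The null distribution shuffles
responses against stimuli within subsets (4000 permutations, shared
permutation index matrices across a cohort for speed); z_t is the
raw contrast standardized by that null.  Because evidence is i.i.d.
across trials and epochs, the null SD is analytically
0.5·sqrt(Σ_s v_s(t)(1/n_up,s + 1/n_down,s)); the EEG-linking maps use
this closed form (verified against the permutation z to a few percent)
so the selection-aware permutation nulls stay computable; the global
profiles always use the full permutation z-scoring.

## Weight models and comparison

Profiles are fit by Bayesian linear regression with a Gaussian ridge
prior (λ = 1, unit-information on unit-RMS standardized regressors; the
sin/cos pair shares one scale factor so the phase convention survives
standardization) and the noise variance marginalized under a weak
inverse-gamma prior (a0 = b0 = 0.01), giving a closed-form marginal
likelihood verified against 2-D adaptive quadrature.  Group comparison
sums log evidence over participants; the rhythm frequency is scanned over
1.1–4 Hz in 0.1 Hz steps (the resolution of the per-participant best
frequencies); the scan argmax is invariant to rescaling the profiles and
to λ ∈ [0.1, 10].  Exceedance probabilities bootstrap participants
(10,000 draws); model frequency counts per-participant winners.  WAIC is
computed from a two-block Gibbs sampler on the conjugate model (split
R-hat guard at 1.1).  Two caveats are inherent and tested as such: with a
proper evidence, pure-noise data *favor the simpler model on average*
(Occam), so null exceedance probabilities sit below 0.5 rather than at
it; and per-profile WAIC differences are ~3× noisier than evidence
differences, so WAIC-vs-evidence ranking agreement is asserted on
decisively structured cohorts and, for the null direction, on the mean.

## Synthetic EEG and spectral analysis

Each trial's epoch (−1.1 … +1.3 s, 1024 Hz default; reduced rates in
tests) is one oscillator at 4 Hz with a smooth topography-gain bump plus
1/f Gaussian noise; the oscillation's phase is referenced to t = −0.32 s
(the pre-stimulus time the phase analyses use), and its amplitude scales
with exp(log-power/2), so both are exact ground truth.  Preprocessing is
a zero-phase 3rd-order 0.6–70 Hz Butterworth (zero-phase so pre-stimulus
phase is not lag-shifted), polyphase resampling to 150 Hz, and ±175 µV
rejection on designated channels.  Before wavelet analysis the stimulus
period is *replaced* by time-mirrored pre-stimulus data (and the epoch
extended leftward by its mirror): full replacement keeps pre-stimulus
estimates exactly uncontaminated by post-onset activity; a half-Hanning
cross-fade is available but off by default because any retained original
signal re-admits measurable leakage.  Morlet decomposition (4 cycles,
integer 2–13 Hz) is energy-normalized; all downstream analyses
(median splits, phase bins) are scale-free, which is asserted by a
scale-invariance test.

## Linking brain state to sampling

Power analyses average power in (−0.3, −0.1) s and median-split (or
quartile-split) trials per channel × frequency; phase analyses take the
phase at −0.32 s and split the circle along four divisions: division k
groups trials into opposing half-circles centred on k·π/4 and k·π/4 + π.
Weights and model components are re-estimated per bin; between-bin
contrasts are signed for power bins (paired t + sign-flip cluster
permutation: per-cell t thresholded at two-sided p < 0.05, clusters over
channel adjacency and neighboring frequencies, max-sum mass, minimum
size 2, 2000 sign flips) and absolute for phase bins (max over the four
divisions, compared to a null that re-runs the *entire* selection
pipeline on permuted trial↔EEG alignments, so the selection bias is in
the null; cells above the cell-wise 95th percentile are clustered and the
cluster mass compared to the null maximum).  Cluster p-values from all
contrast families (each component's amplitude and the rhythmic phase, for
power and phase conditioning) enter one Benjamini–Hochberg step across
families at q = 0.01.  The default synthetic montage is a grid with
4-neighbor adjacency.

### The phase-coupling implant and what "recovery" means

The mechanism demonstration implants g_phase = 0.5 rad/rad at a 4 Hz
oscillation: opposing phase half-circles then differ in implanted
sampling phase by exactly g·π = 90°.  Two properties of this implant are
worth recording.  First, with a *linear* gain on a wrapped uniform phase,
the division whose bins straddle ±π has zero implanted contrast, and
large gains (≳1 rad/rad) wrap the weight phase across each bin, crushing
the within-bin resultant; the 0.5 rad/rad implant keeps the resultant at
0.90 and the contrast clean at the {0, π}-boundary division.  Second,
binarized-response reverse correlation *attenuates* between-bin phase
contrasts: the response-conditioned contrast is not a plain average of
the per-trial weights, and simulations with ground-truth bins and no EEG
noise recover ~85° of an implanted 90° at the amplitudes used (and far
less at mismatched divisions).  Recovery is therefore asserted on the
implant-defined division at the strongest-topography channel, with a
±20° band that absorbs both the attenuation and single-trial EEG phase
noise.  The same attenuation applies, unquantifiably, to human data —
measured between-bin phase shifts should be read as lower bounds.

## Problem sizes

Cohort-level behavioral checks run at the design scale (20 observers ×
1000 trials; 100 replicates for frequency recovery).  The EEG mechanism
demonstration runs at 12 participants × 800 trials on an 8-channel
(2 × 4) montage at 512 Hz with 1200 alignment-permutation nulls, and the
permutation-calibration studies use 100–200 replicates at n_perm = 200 on
a 3 × 3 montage; these sizes were chosen to keep the full validation
suite comfortably re-runnable on a single CPU while leaving every
statistical margin intact (e.g. 1/1201 < the BH threshold the mechanism
cluster must clear).

## Known limitations

* The synthetic EEG has no artifacts, no evoked structure by default, no
  volume conduction or realistic topographies; ICA, bad-channel
  interpolation and re-referencing realism are out of scope (a
  re-referencing helper exists as plumbing).  Passing tests show the
  *analysis chain* is correct and calibrated, not that real EEG meets its
  assumptions.
* The generative observer is a linear-integration probit; real listeners
  may integrate nonlinearly, and the reverse-correlation attenuation
  described above would then differ.
* Evidence quantization to 1/30 steps and coherence truncation at [0, 1]
  are faithful to the stimulus design but make the "requested vs
  realized" coherence distinction load-bearing; all simulation code
  stores realized values.
* WAIC at 10 data points per profile is noisy by nature; it is a
  cross-check on the evidence-based comparison, not a replacement.
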