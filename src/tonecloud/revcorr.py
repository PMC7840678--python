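"""Psychophysical reverse correlation: temporal perceptual weights.

The weight of epoch t is the difference in mean sensory evidence between
trials answered "up" and trials answered "down".  The contrast is computed
within each true sweep-direction subset and averaged across the two
subsets, which removes the direction-induced evidence offset; a pooled
variant is available.  Weights are converted to within-participant
z-scores against a null distribution obtained by shuffling the alignment
of responses and stimuli (within direction subsets), so a weight of zero
means no influence of that epoch on the choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import evidence_matrix
from .soundscapes import N_EPOCHS

__all__ = ["WeightProfile", "perceptual_weights", "weights_to_frame"]

#: bins with fewer trials than this are refused rather than silently fitted
MIN_TRIALS_DEFAULT = 50


@dataclass
class WeightProfile:
    """Per-epoch perceptual weights for one participant (or one trial bin)."""

    z_weights: np.ndarray          # length 10, z-units
    raw_diff: np.ndarray           # length 10, evidence units
    n_trials_used: int
    participant_id: int | str | None = None
    bin_label: str | None = None
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None

    def __post_init__(self):
        self.z_weights = np.asarray(self.z_weights, dtype=float)
        self.raw_diff = np.asarray(self.raw_diff, dtype=float)
        if self.z_weights.shape != (N_EPOCHS,):
            raise ValueError("weight profile must have 10 epochs")
        if not np.all(np.isfinite(self.z_weights)):
            raise ValueError("z-weights must be finite")


def _permutation_indices(n: int, n_perm: int, rng, cache=None) -> np.ndarray:
    """(n_perm, n) row permutations; cached by n so cohorts can share them."""
    if cache is not None and n in cache:
        return cache[n]
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    if cache is not None:
        cache[n] = idx
    return idx


def _contrast_vector(responses: np.ndarray) -> np.ndarray:
    """Weights realizing mean(E | up) - mean(E | down) as a dot product."""
    up = responses > 0
    n_up, n_down = int(up.sum()), int((~up).sum())
    if n_up == 0 or n_down == 0:
        raise ValueError("degenerate responses: only one response class present")
    w = np.where(up, 1.0 / n_up, -1.0 / n_down)
    return w


def perceptual_weights(trials: pd.DataFrame, n_perm: int = 4000, seed=None,
                       bin_mask=None, min_trials: int = MIN_TRIALS_DEFAULT,
                       pooled: bool = False, zscore_mode: str = "averaged",
                       participant_id=None, bin_label: str | None = None,
                       perm_cache: dict | None = None) -> WeightProfile:
    """Estimate the 10-epoch perceptual weight profile of one trial set.

    Parameters
    ----------
    trials : trial table with columns direction, c1..c10, response.
    n_perm : number of stimulus-response shuffles for the null z-scoring.
    bin_mask : optional boolean mask restricting the trials (condition bins).
    pooled : ignore the direction split and contrast responses over all trials.
    zscore_mode : "averaged" z-scores the direction-averaged contrast
        (default); "per_direction" z-scores within each direction subset
        first and averages the two z-profiles.
    perm_cache : optional dict; permutation index matrices are cached per
        subset size, letting a cohort loop reuse them.
    """
    if zscore_mode not in ("averaged", "per_direction"):
        raise ValueError(f"unknown zscore_mode {zscore_mode!r}")
    if bin_mask is not None:
        trials = trials[np.asarray(bin_mask, dtype=bool)]
    n = len(trials)
    if n < min_trials:
        raise ValueError(f"only {n} trials available, need >= {min_trials}")
    E = evidence_matrix(trials)
    responses = trials["response"].to_numpy()
    directions = trials["direction"].to_numpy()

    rng = np.random.default_rng(seed)
    subsets = [np.ones(n, dtype=bool)] if pooled else \
        [directions == +1, directions == -1]

    raws, nulls = [], []
    for sel in subsets:
        if not np.any(sel):
            raise ValueError("a direction subset is empty")
        w = _contrast_vector(responses[sel])
        Es = E[sel]
        raws.append(w @ Es)
        idx = _permutation_indices(int(sel.sum()), n_perm, rng, perm_cache)
        nulls.append(w[idx] @ Es)            # (n_perm, 10)

    if zscore_mode == "per_direction":
        zs = [(r - nl.mean(axis=0)) / nl.std(axis=0, ddof=1)
              for r, nl in zip(raws, nulls)]
        z = np.mean(zs, axis=0)
        raw = np.mean(raws, axis=0)
        null_mean = np.mean([nl.mean(axis=0) for nl in nulls], axis=0)
        null_sd = np.mean([nl.std(axis=0, ddof=1) for nl in nulls], axis=0)
    else:
        raw = np.mean(raws, axis=0)
        null = np.mean(nulls, axis=0)        # pairs independent shuffles
        null_mean = null.mean(axis=0)
        null_sd = null.std(axis=0, ddof=1)
        z = (raw - null_mean) / null_sd

    return WeightProfile(z_weights=z, raw_diff=raw, n_trials_used=n,
                         participant_id=participant_id, bin_label=bin_label,
                         null_mean=null_mean, null_sd=null_sd)


def weights_to_frame(profiles) -> pd.DataFrame:
    """Long-format TSV-ready table (participant, bin, epoch, raw, z)."""
    rows = []
    for p in profiles:
        for t in range(N_EPOCHS):
            rows.append({"participant": p.participant_id, "bin": p.bin_label,
                         "epoch": t + 1, "raw": p.raw_diff[t],
                         "z": p.z_weights[t]})
    return pd.DataFrame(rows)
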