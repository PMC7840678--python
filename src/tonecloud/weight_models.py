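"""Regression models of perceptual weight profiles and their comparison.

A weight profile (10 z-scored weights at the epoch centers) is described
by three "trivial" regressors — offset, zero-mean linear ramp, and a
u/v-shaped component cos(2*pi*t*fexp) with fexp = 1/stimulus duration —
optionally augmented by a rhythmic sin/cos pair at a frequency scanned
over 1.1-4 Hz.  Models are fit by Bayesian linear regression with a
Gaussian ridge prior on standardized regressors and the noise variance
marginalized under an inverse-gamma prior, giving a closed-form marginal
likelihood (model evidence).  Group-level comparison sums log evidence
over participants; bootstrap exceedance probabilities, per-participant
model frequencies, and a Gibbs-sampled WAIC provide complementary views.

The rhythmic component is summarized by its RMS amplitude
sqrt((b_sin^2 + b_cos^2)/2) and its phase atan2(b_sin, b_cos), so the
fitted component is proportional to cos(2*pi*f*t - phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .cohort import epoch_centers
from .soundscapes import N_EPOCHS, STIM_DURATION_S

__all__ = [
    "DesignSpec",
    "WeightModelFit",
    "GroupComparison",
    "FrequencyScan",
    "default_frequency_grid",
    "fit_weight_model",
    "rhythm_phase_of",
    "scan_frequencies",
    "exceedance_and_frequency",
    "waic_fit",
]

#: default ridge scale on standardized regressors (unit-information)
RIDGE_LAMBDA = 1.0
#: inverse-gamma prior on the noise variance (weak, Jeffreys-type)
NOISE_PRIOR_A = 0.01
NOISE_PRIOR_B = 0.01


def default_frequency_grid(lo: float = 1.1, hi: float = 4.0,
                           step: float = 0.1) -> np.ndarray:
    """Scanned rhythm frequencies, 1.1-4 Hz in 0.1 Hz steps."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class DesignSpec:
    """Regressor specification evaluated at the ten epoch centers."""

    rhythm_freq_hz: float | None = None
    epoch_centers_s: tuple[float, ...] = tuple(epoch_centers())
    fexp_hz: float = 1.0 / STIM_DURATION_S
    ridge_lambda: float = RIDGE_LAMBDA

    def __post_init__(self):
        if self.rhythm_freq_hz is not None and not (
                1.0 < self.rhythm_freq_hz <= 1.0 / (2 * 0.12) + 1e-9):
            raise ValueError("rhythm frequency outside the resolvable 1.1-4.17 Hz range")

    @property
    def names(self) -> tuple[str, ...]:
        base = ("offset", "linear", "uv")
        return base + (("sin", "cos") if self.rhythm_freq_hz is not None else ())

    def matrix(self):
        """(X_raw, X_std, scales): raw columns and unit-RMS standardized ones.

        The sin and cos columns share a common scale factor so the phase
        atan2(b_sin, b_cos) is identical in both bases.
        """
        t = np.asarray(self.epoch_centers_s)
        n = t.size
        cols = [np.ones(n),
                2.0 * (t - t.mean()) / STIM_DURATION_S,
                np.cos(2 * np.pi * t * self.fexp_hz)]
        if self.rhythm_freq_hz is not None:
            cols += [np.sin(2 * np.pi * t * self.rhythm_freq_hz),
                     np.cos(2 * np.pi * t * self.rhythm_freq_hz)]
        X = np.column_stack(cols)
        scales = np.sqrt(np.mean(X ** 2, axis=0))
        if self.rhythm_freq_hz is not None:
            common = np.sqrt(np.mean(scales[3:5] ** 2))
            scales[3:5] = common
        if np.any(scales < 1e-12):
            raise ValueError("degenerate regressor (zero column)")
        X_std = X / scales
        if np.linalg.matrix_rank(X_std) < X.shape[1]:
            raise ValueError("rank-deficient design matrix at "
                             f"rhythm_freq_hz={self.rhythm_freq_hz}")
        return X, X_std, scales


@dataclass
class WeightModelFit:
    """Posterior summary of one Bayesian linear fit of a weight profile."""

    betas: dict                      # raw-basis posterior means, z-units
    log_evidence: float              # closed-form marginal log likelihood, nats
    design: DesignSpec
    sigma2_mean: float
    waic: float | None = None

    @property
    def rhythm_norm(self) -> float:
        """sqrt(b_sin^2 + b_cos^2): peak amplitude of the rhythmic component."""
        return float(np.hypot(self.betas.get("sin", 0.0), self.betas.get("cos", 0.0)))

    @property
    def rhythm_rms(self) -> float:
        """Root-mean-squared amplitude of the combined sin and cos components."""
        return self.rhythm_norm / np.sqrt(2.0)

    @property
    def rhythm_phase(self) -> float:
        return rhythm_phase_of(self)


def _posterior(y, X_std, lam, a0=NOISE_PRIOR_A, b0=NOISE_PRIOR_B):
    n, p = X_std.shape
    prec = lam * np.eye(p) + X_std.T @ X_std
    mu = np.linalg.solve(prec, X_std.T @ y)
    a_n = a0 + n / 2.0
    b_n = b0 + 0.5 * (y @ y - mu @ prec @ mu)
    return prec, mu, a_n, b_n


def _log_evidence(y, X_std, lam, a0=NOISE_PRIOR_A, b0=NOISE_PRIOR_B):
    n, p = X_std.shape
    prec, mu, a_n, b_n = _posterior(y, X_std, lam, a0, b0)
    sign, logdet = np.linalg.slogdet(prec)
    return (-0.5 * n * np.log(2 * np.pi)
            + 0.5 * (p * np.log(lam) - logdet)
            + a0 * np.log(b0) - a_n * np.log(b_n)
            + gammaln(a_n) - gammaln(a0))


def fit_weight_model(profile, design: DesignSpec) -> WeightModelFit:
    """Fit the trivial (+ optional rhythmic) model to one weight profile.

    ``profile`` may be a :class:`~tonecloud.revcorr.WeightProfile` (its
    z-weights are used) or a plain length-10 array.  Betas are reported in
    the raw regressor basis so that, e.g., a pure cosine of amplitude A at
    the rhythm frequency yields b_cos ~ A (up to ridge shrinkage).
    """
    y = np.asarray(getattr(profile, "z_weights", profile), dtype=float)
    if y.shape != (N_EPOCHS,):
        raise ValueError(f"expected a length-{N_EPOCHS} profile, got {y.shape}")
    X, X_std, scales = design.matrix()
    prec, mu_std, a_n, b_n = _posterior(y, X_std, design.ridge_lambda)
    log_ev = _log_evidence(y, X_std, design.ridge_lambda)
    betas = dict(zip(design.names, mu_std / scales))
    sigma2_mean = b_n / (a_n - 1.0) if a_n > 1 else float("nan")
    return WeightModelFit(betas=betas, log_evidence=float(log_ev),
                          design=design, sigma2_mean=float(sigma2_mean))


def rhythm_phase_of(fit: WeightModelFit) -> float:
    """Phase (rad, (-pi, pi]) such that the component is cos(2*pi*f*t - phase)."""
    if "sin" not in fit.betas or "cos" not in fit.betas:
        raise ValueError("fit has no rhythmic component")
    if fit.rhythm_norm < 1e-10:
        raise ValueError("phase undefined: rhythmic amplitude below numerical floor")
    phase = float(np.arctan2(fit.betas["sin"], fit.betas["cos"]))
    if phase <= -np.pi:
        phase += 2 * np.pi
    return phase


@dataclass
class GroupComparison:
    """Group-level trivial vs trivial+rhythmic comparison at one frequency."""

    best_freq_hz: float
    delta_neg_log_ev: float          # negLogEv(trivial) - negLogEv(rhythmic)
    exceedance_prob: float
    model_frequency: dict            # {"trivial": f, "rhythmic": f}, sums to 1


@dataclass
class FrequencyScan:
    """Evidence scan over the rhythm-frequency grid."""

    grid_hz: np.ndarray
    logev_trivial: np.ndarray        # per participant
    logev_rhythmic: np.ndarray       # (n_participants, n_freqs)
    participant_ids: list = field(default_factory=list)

    @property
    def group_logev(self) -> np.ndarray:
        return self.logev_rhythmic.sum(axis=0)

    @property
    def best_freq_hz(self) -> float:
        return float(self.grid_hz[int(np.argmax(self.group_logev))])

    @property
    def participant_best_freqs(self) -> np.ndarray:
        return self.grid_hz[np.argmax(self.logev_rhythmic, axis=1)]

    def logev_at(self, freq_hz: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.grid_hz - freq_hz)))
        return self.logev_rhythmic[:, i]


def scan_frequencies(profiles, grid_hz=None,
                     ridge_lambda: float = RIDGE_LAMBDA) -> FrequencyScan:
    """Scan the rhythm-frequency grid, summing evidence over participants.

    ``profiles`` is a sequence of WeightProfile (or arrays), one per
    participant; at least two are required for a group-level scan.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("group-level scan needs at least 2 participants")
    grid_hz = default_frequency_grid() if grid_hz is None else np.asarray(grid_hz)
    ys = [np.asarray(getattr(p, "z_weights", p), dtype=float) for p in profiles]
    ids = [getattr(p, "participant_id", i) for i, p in enumerate(profiles)]

    triv = DesignSpec(rhythm_freq_hz=None, ridge_lambda=ridge_lambda)
    _, Xt_std, _ = triv.matrix()
    logev_t = np.array([_log_evidence(y, Xt_std, ridge_lambda) for y in ys])

    logev_r = np.empty((len(ys), grid_hz.size))
    for j, f in enumerate(grid_hz):
        d = DesignSpec(rhythm_freq_hz=float(f), ridge_lambda=ridge_lambda)
        _, X_std, _ = d.matrix()
        logev_r[:, j] = [_log_evidence(y, X_std, ridge_lambda) for y in ys]

    return FrequencyScan(grid_hz=grid_hz, logev_trivial=logev_t,
                         logev_rhythmic=logev_r, participant_ids=ids)


def exceedance_and_frequency(logev_trivial, logev_rhythmic,
                             n_boot: int = 10000, seed=None) -> dict:
    """Bootstrap exceedance probability and per-participant model frequency.

    Participants are resampled with replacement; the exceedance
    probability is the fraction of bootstrap draws in which the summed log
    evidence favors the rhythmic model.  Model frequency is the fraction
    of participants individually favoring each model.
    """
    lt = np.asarray(logev_trivial, dtype=float)
    lr = np.asarray(logev_rhythmic, dtype=float)
    if lt.shape != lr.shape or lt.ndim != 1:
        raise ValueError("need matched per-participant log evidences")
    n = lt.size
    if n < 3:
        raise ValueError(f"need at least 3 participants, got {n}")
    rng = np.random.default_rng(seed)
    diffs = lr - lt
    idx = rng.integers(0, n, size=(n_boot, n))
    exceedance = float(np.mean(diffs[idx].sum(axis=1) > 0))
    f_rhythm = float(np.mean(diffs > 0))
    return {"exceedance_prob": exceedance,
            "model_frequency": {"rhythmic": f_rhythm, "trivial": 1.0 - f_rhythm}}


def group_comparison(scan: FrequencyScan, n_boot: int = 10000,
                     seed=None) -> GroupComparison:
    """Trivial vs rhythmic comparison at the scan's best group frequency."""
    lr = scan.logev_at(scan.best_freq_hz)
    boot = exceedance_and_frequency(scan.logev_trivial, lr, n_boot, seed)
    delta = float(lr.sum() - scan.logev_trivial.sum())
    return GroupComparison(best_freq_hz=scan.best_freq_hz,
                           delta_neg_log_ev=delta,
                           exceedance_prob=boot["exceedance_prob"],
                           model_frequency=boot["model_frequency"])


def _split_rhat(chains: np.ndarray) -> float:
    """Split-half R-hat over (n_chains, n_samples) draws of one scalar."""
    half = chains.shape[1] // 2
    segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, s = segs.shape
    means = segs.mean(axis=1)
    w = segs.var(axis=1, ddof=1).mean()
    b = s * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (s - 1) / s * w + b / s
    return float(np.sqrt(var_plus / w))


def waic_fit(profile, design: DesignSpec, n_samples: int = 10000,
             n_burnin: int = 10000, thinning: int = 5, seed=None,
             n_chains: int = 2, rhat_tol: float = 1.1) -> dict:
    """WAIC of one model via Gibbs sampling of the conjugate linear model.

    Alternates beta | sigma^2, y (Gaussian, with posterior location fixed
    by conjugacy) and sigma^2 | beta, y (inverse gamma).  WAIC is
    -2 * (lppd - p_waic) with the variance-based penalty.  Raises if the
    split R-hat of any beta exceeds ``rhat_tol``.
    """
    y = np.asarray(getattr(profile, "z_weights", profile), dtype=float)
    X, X_std, scales = design.matrix()
    n, p = X_std.shape
    lam = design.ridge_lambda
    prec, mu, _, _ = _posterior(y, X_std, lam)
    L = np.linalg.cholesky(np.linalg.inv(prec))
    rng = np.random.default_rng(seed)

    keep_b = np.empty((n_chains, n_samples, p))
    keep_ll = np.empty((n_chains, n_samples, n))
    for c in range(n_chains):
        sigma2 = float(np.var(y)) or 1.0
        kept = 0
        it = 0
        total = n_burnin + n_samples * thinning
        while kept < n_samples:
            beta = mu + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
            resid = y - X_std @ beta
            shape = NOISE_PRIOR_A + (n + p) / 2.0
            rate = NOISE_PRIOR_B + 0.5 * (resid @ resid + lam * beta @ beta)
            sigma2 = rate / rng.gamma(shape)
            it += 1
            if it > n_burnin and (it - n_burnin) % thinning == 0:
                keep_b[c, kept] = beta
                keep_ll[c, kept] = (-0.5 * np.log(2 * np.pi * sigma2)
                                    - 0.5 * resid ** 2 / sigma2)
                kept += 1
            if it > total + thinning:
                break

    rhats = [_split_rhat(keep_b[:, :, j]) for j in range(p)]
    if max(rhats) > rhat_tol:
        raise RuntimeError(f"Gibbs sampler did not converge: R-hat={max(rhats):.3f} "
                           f"(per-beta: {np.round(rhats, 3).tolist()})")

    ll = keep_ll.reshape(-1, n)
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(ll.shape[0])))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    waic = -2.0 * (lppd - p_waic)
    betas_std = keep_b.reshape(-1, p).mean(axis=0)
    return {"waic": waic, "lppd": lppd, "p_waic": p_waic,
            "betas": dict(zip(design.names, betas_std / scales)),
            "rhat": dict(zip(design.names, rhats))}
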