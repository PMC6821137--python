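"""Prediction scoring and statistical comparison of fitted models.

Prediction accuracy is the Pearson correlation between the predicted rate
and the trial-averaged PSTH, corrected for the finite-trial noise ceiling:
the ceiling is estimated from the mean correlation between PSTHs of random
half-splits of trials, extrapolated to the full trial count by the
Spearman-Brown formula, and the raw correlation is divided by it.

Model comparisons use three pieces of machinery:

* a permutation test against chance (shuffle the *prediction* across time,
  recompute the correlation, optional Bonferroni correction over models);
* a jackknife t-like test between two models (leave-one-subset-out
  correlations over interleaved time partitions; significant when the mean
  difference exceeds the sum of the two jackknife standard errors);
* an exact binomial sign test (optionally Wilcoxon signed-rank) across a
  population of paired per-neuron scores.

Model-property summaries: per-channel filter gain (sum of temporal-filter
coefficients; the largest-gain channel is the excitatory reference, a
negative smallest-gain channel the inhibitory reference) and the synaptic
adaptation index (one minus the ratio of mean output to mean input of the
adapting synapse for a standard test pulse; > 0 depression, < 0
facilitation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import ModelSpec, _render_kernels, stp_gain

__all__ = [
    "SpikeRaster",
    "psth",
    "noise_corrected_r",
    "NoiseCorrectedR",
    "permutation_chance_test",
    "jackknife_ttest",
    "JackknifeComparison",
    "population_sign_test",
    "channel_gains",
    "ChannelGains",
    "adaptation_index",
]


@dataclass
class SpikeRaster:
    """Trial x time spike counts at fixed bins, with optional state labels."""

    counts: np.ndarray
    dt: float = 0.010
    state: np.ndarray | None = None
    stimulus_id: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if self.counts.size == 0:
            raise ValueError("empty raster")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")
        if self.state is not None:
            self.state = np.asarray(self.state)
            if len(self.state) != self.n_trials:
                raise ValueError("one state label per trial required")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def psth(raster: SpikeRaster) -> np.ndarray:
    """Trial-averaged firing rate (spikes/s) per bin; no smoothing."""
    return raster.counts.mean(axis=0) / raster.dt


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class NoiseCorrectedR:
    r: float
    r_raw: float
    ceiling: float
    flag: str | None = None


def noise_corrected_r(pred: np.ndarray, raster: SpikeRaster,
                      n_splits: int = 100, seed: int = 0) -> NoiseCorrectedR:
    """Prediction correlation corrected for trial-to-trial response noise.

    ``ceiling = sqrt(2 * rhh / (1 + rhh))`` where ``rhh`` is the mean
    correlation between PSTHs of random half-splits of trials
    (Spearman-Brown extrapolation of half-set reliability to the full set);
    the corrected score is ``r_raw / ceiling``, clipped at 1.  Rasters with
    fewer than 4 trials return the raw correlation flagged
    ``"single_trial"``; a non-positive ceiling estimate returns NaN flagged
    ``"unpredictable"``.
    """
    target = psth(raster)
    r_raw = _pearson(pred, target)
    if raster.n_trials < 4:
        return NoiseCorrectedR(r=r_raw, r_raw=r_raw, ceiling=np.nan,
                               flag="single_trial")
    rng = np.random.default_rng(seed)
    n = raster.n_trials
    half = n // 2
    rs = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        a = raster.counts[perm[:half]].mean(axis=0)
        b = raster.counts[perm[half: 2 * half]].mean(axis=0)
        r = _pearson(a, b)
        if np.isfinite(r):
            rs.append(r)
    rhh = float(np.mean(rs)) if rs else np.nan
    if not np.isfinite(rhh) or rhh <= 0:
        return NoiseCorrectedR(r=np.nan, r_raw=r_raw, ceiling=np.nan,
                               flag="unpredictable")
    ceiling = float(np.sqrt(2.0 * rhh / (1.0 + rhh)))
    r = float(np.clip(r_raw / ceiling, -1.0, 1.0))
    return NoiseCorrectedR(r=r, r_raw=r_raw, ceiling=ceiling)


def permutation_chance_test(pred: np.ndarray, obs: np.ndarray,
                            n_perm: int = 1000, seed: int = 0,
                            n_models_for_bonferroni: int = 1) -> float:
    """Chance-level test: shuffle the prediction across time bins.

    ``p = (1 + #{shuffled r >= observed r}) / (n_perm + 1)``, multiplied by
    the number of models compared (Bonferroni) and capped at 1.
    """
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError("length mismatch")
    r_obs = _pearson(pred, obs)
    if not np.isfinite(r_obs):
        warnings.warn("constant series: chance test undefined, p = 1")
        return 1.0
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r = _pearson(rng.permutation(pred), obs)
        if np.isfinite(r) and r >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return min(1.0, p * n_models_for_bonferroni)


@dataclass
class JackknifeComparison:
    r_a: float
    r_b: float
    se_a: float
    se_b: float
    significant: bool


def _jackknife_corr(pred: np.ndarray, obs: np.ndarray, n_jack: int):
    T = len(obs)
    idx = np.arange(T) % n_jack
    thetas = []
    for k in range(n_jack):
        keep = idx != k
        if keep.sum() < 3:
            raise ValueError("degenerate jackknife partition")
        thetas.append(_pearson(pred[keep], obs[keep]))
    thetas = np.asarray(thetas)
    if not np.all(np.isfinite(thetas)):
        raise ValueError("degenerate jackknife partition (constant subset)")
    mean = thetas.mean()
    se = np.sqrt((n_jack - 1) / n_jack * np.sum((thetas - mean) ** 2))
    return float(mean), float(se)


def jackknife_ttest(pred_a: np.ndarray, pred_b: np.ndarray, obs: np.ndarray,
                    n_jack: int = 20) -> JackknifeComparison:
    """Jackknifed comparison of two models' prediction correlations.

    Correlations are recomputed on ``n_jack`` leave-one-subset-out
    partitions of time bins (interleaved, so stimulus structure is balanced
    across resamples); the difference is significant when the absolute
    difference of the jackknife means exceeds the sum of the two jackknife
    standard errors (approximately p < 0.05).  Symmetric in (A, B).
    """
    if n_jack < 2:
        raise ValueError("n_jack must be >= 2")
    pred_a = np.asarray(pred_a, float)
    pred_b = np.asarray(pred_b, float)
    obs = np.asarray(obs, float)
    ra, sa = _jackknife_corr(pred_a, obs, n_jack)
    rb, sb = _jackknife_corr(pred_b, obs, n_jack)
    sig = bool(abs(ra - rb) > sa + sb)
    return JackknifeComparison(r_a=ra, r_b=rb, se_a=sa, se_b=sb,
                               significant=sig)


def population_sign_test(scores_a, scores_b, method: str = "sign") -> float:
    """Paired population comparison across neurons.

    ``method='sign'``: exact two-sided binomial sign test on
    ``sign(b - a)`` with ties dropped.  ``method='wilcoxon'``: Wilcoxon
    signed-rank test.  All-tied input returns p = 1 with a warning.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError("paired scores must have equal length")
    diff = b - a
    diff = diff[diff != 0]
    if diff.size == 0:
        warnings.warn("all pairs tied; sign test undefined, p = 1")
        return 1.0
    if method == "sign":
        k = int(np.sum(diff > 0))
        return float(stats.binomtest(k, diff.size, 0.5,
                                     alternative="two-sided").pvalue)
    if method == "wilcoxon":
        return float(stats.wilcoxon(diff).pvalue)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ChannelGains:
    gains: np.ndarray
    excitatory: int
    inhibitory: int | None


def channel_gains(model: ModelSpec) -> ChannelGains:
    """Per-channel temporal-filter gain and E/I reference channels.

    Gain is the sum of the filter coefficients across time lags.  The
    maximum-gain channel is the excitatory reference; the minimum-gain
    channel is the inhibitory reference when its gain is negative.
    """
    kernels = _render_kernels(model)
    gains = kernels.sum(axis=1)
    exc = int(np.argmax(gains))
    imin = int(np.argmin(gains))
    inh = imin if gains[imin] < 0 else None
    return ChannelGains(gains=gains, excitatory=exc, inhibitory=inh)


def adaptation_index(v: float, tau: float, dt: float = 0.010,
                     test_signal: np.ndarray | None = None,
                     mode: str = "canonical") -> float:
    """Adaptation strength of one model synapse.

    One minus the ratio of mean output to mean input of the synapse over the
    driven portion of a standard test signal (default: 0.5 s silence
    followed by a 0.5 s unit-amplitude pulse).  Zero for v = 0, positive for
    depression, negative for facilitation.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if test_signal is None:
        n = int(round(0.5 / dt))
        test_signal = np.concatenate([np.zeros(n), np.ones(n)])
    test_signal = np.asarray(test_signal, float)
    active = test_signal > 0
    if not active.any():
        raise ValueError("test signal has no driven portion")
    d = stp_gain(test_signal, v, tau, dt, mode=mode)
    out = d * test_signal
    return float(1.0 - out[active].mean() / test_signal[active].mean())
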