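"""Encoding-model stages and architectures.

The model family is a cascade of stages applied to a channel x time stimulus
matrix:

    log-compress -> spectral reweighting -> [per-channel STP | per-channel
    rectification | nothing] -> per-channel temporal filtering (damped-
    oscillator FIR) -> [global STP | nothing] -> static output nonlinearity

Four architectures are composed from these stages:

* ``LN``        -- reweight, filter, output nonlinearity.
* ``localSTP``  -- short-term plasticity applied independently per reweighted
                   channel before temporal filtering (spectrally tuned
                   adaptation).
* ``globalSTP`` -- a single STP gain applied to the summed filter output
                   before the output nonlinearity.
* ``localRect`` -- per-channel threshold rectification before temporal
                   filtering (a non-adaptive local nonlinearity control).

The STP stage is a two-parameter synaptic resource model: release
probability ``v`` (v > 0 depression, v < 0 facilitation) and recovery time
constant ``tau`` (seconds).  The canonical per-bin update is

    d[t] = d[t-1] + dt * ((1 - d[t-1]) / tau - v * drive[t-1] * d[t-1])

with d[0] = 1 and the gain clipped to [d_min, d_max]; a ``verbatim`` mode
implements an alternative literal difference form,
``d[t] = d[t-1] + drive[t-1] * (1 - d[t-1]) * v - d[t-1] / tau``, for
comparison (note it relaxes toward 0, not 1, under silence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .stimuli import StimulusMatrix, log_compress

__all__ = [
    "SpectralWeights",
    "DampedOscillatorFilter",
    "STPParams",
    "RectifierParams",
    "OutputNL",
    "ModelSpec",
    "reweight",
    "do_kernel",
    "fir_predict",
    "stp_gain",
    "stp_apply",
    "global_stp",
    "rectify_local",
    "output_nl",
    "predict",
]

ARCHITECTURES = ("LN", "globalSTP", "localSTP", "localRect")


# ---------------------------------------------------------------------------
# stage parameter containers
# ---------------------------------------------------------------------------

@dataclass
class SpectralWeights:
    """Input-channel x output-channel reweighting matrix.

    Either a free matrix ``w`` (n_in x n_out) or a Gaussian parameterization
    over channel index (per-output mean/sd, peak value 1), as used for
    natural-sound spectrograms where channel index ~ log frequency.
    """

    w: np.ndarray | None = None
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    n_in: int | None = None

    def __post_init__(self):
        if self.w is not None:
            self.w = np.atleast_2d(np.asarray(self.w, dtype=float))
            self.n_in = self.w.shape[0]
        elif self.means is not None:
            self.means = np.asarray(self.means, dtype=float)
            self.sds = np.asarray(self.sds, dtype=float)
            if self.n_in is None:
                raise ValueError("gaussian weights need n_in")
            if np.any(self.sds <= 0):
                raise ValueError("gaussian sds must be > 0")
        else:
            raise ValueError("provide either w or (means, sds, n_in)")

    @property
    def is_gaussian(self) -> bool:
        return self.w is None

    @property
    def n_out(self) -> int:
        return len(self.means) if self.is_gaussian else self.w.shape[1]

    def matrix(self) -> np.ndarray:
        """Render to an n_in x n_out array (Gaussian form peaks at 1)."""
        if not self.is_gaussian:
            return self.w
        idx = np.arange(self.n_in)[:, None]
        return np.exp(-((idx - self.means[None, :]) ** 2)
                      / (2.0 * self.sds[None, :] ** 2))


@dataclass
class DampedOscillatorFilter:
    """Parametric temporal kernel: decaying-exponential-weighted sinusoid.

    h(u) = gain * exp(-decay * m(u)) * sin(freq * m(u)),  m(u) = max(u - latency, 0)

    with lag u in seconds; the kernel is zero for lags before ``latency``.
    ``decay`` is in 1/s and ``freq`` in rad/s.  ``n_lags`` bins of width dt
    cover 0..150 ms at the default 10 ms bin.
    """

    gain: float = 1.0
    latency: float = 0.0
    decay: float = 20.0
    freq: float = 30.0
    n_lags: int = 15

    def kernel(self, dt: float) -> np.ndarray:
        return do_kernel(self, dt)


@dataclass
class STPParams:
    """Per-channel short-term plasticity parameters."""

    v: np.ndarray
    tau: np.ndarray
    d_min: float = 0.0
    d_max: float = 5.0
    recursion_mode: str = "canonical"

    def __post_init__(self):
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if self.v.shape != self.tau.shape:
            raise ValueError("v and tau must have matching shapes")
        if np.any(self.tau <= 0):
            raise ValueError("STP recovery time constants must be > 0")
        if self.recursion_mode not in ("canonical", "verbatim"):
            raise ValueError(f"unknown recursion_mode {self.recursion_mode!r}")

    @property
    def n_channels(self) -> int:
        return len(self.v)


@dataclass
class RectifierParams:
    """Per-channel linear-rectification thresholds."""

    s0: np.ndarray

    def __post_init__(self):
        self.s0 = np.atleast_1d(np.asarray(self.s0, dtype=float))
        if not np.all(np.isfinite(self.s0)):
            raise ValueError("rectifier thresholds must be finite")


@dataclass
class OutputNL:
    """Static output nonlinearity.

    kinds: ``linear`` (pass-through), ``relu`` (threshold ``base``, offset
    ``rate_offset``), ``logistic`` (sigmoid), ``dexp`` (double exponential
    sigmoid ``b + A*exp(-exp(kappa*(x - b)))``; increasing for kappa < 0,
    output bounded between b and b + A).
    """

    kind: str = "dexp"
    base: float = 0.0        # b
    amplitude: float = 1.0   # A
    slope: float = -1.0      # kappa
    rate_offset: float = 0.0  # r0 (relu / logistic)

    def __post_init__(self):
        if self.kind not in ("linear", "relu", "logistic", "dexp"):
            raise ValueError(f"unknown output nonlinearity {self.kind!r}")


@dataclass
class ModelSpec:
    """Complete architecture description.

    ``global_stp`` holds a 1-channel :class:`STPParams` for the globalSTP
    architecture (``common_input=True`` selects the variant that averages
    per-channel gains instead).  ``compress`` applies log(1+x) to the raw
    stimulus first.  ``normalize_weights`` rescales each reweighting column
    to unit L2 norm inside :func:`predict` (removing the scale degeneracy
    between weights, filter gain and STP strength during fitting); it never
    alters the stored weights.
    """

    architecture: str
    weights: SpectralWeights
    filters: list
    out_nl: OutputNL
    stp: STPParams | None = None
    rect: RectifierParams | None = None
    global_stp: STPParams | None = None
    common_input: bool = False
    compress: bool = True
    normalize_weights: bool = False
    behavior_split: str = "none"
    dt: float = 0.010

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if len(self.filters) != self.weights.n_out:
            raise ValueError("one temporal filter required per reweighted channel")
        if self.architecture == "localSTP":
            if self.stp is None or self.stp.n_channels != self.rank:
                raise ValueError("localSTP requires one (v, tau) pair per channel")
        if self.architecture == "localRect":
            if self.rect is None or len(self.rect.s0) != self.rank:
                raise ValueError("localRect requires one threshold per channel")
        if self.architecture == "globalSTP" and self.global_stp is None:
            raise ValueError("globalSTP requires global STP parameters")
        if self.behavior_split not in ("none", "NL", "filter+NL", "all"):
            raise ValueError(f"unknown behavior_split {self.behavior_split!r}")

    @property
    def rank(self) -> int:
        return self.weights.n_out

    def copy(self) -> "ModelSpec":
        import copy
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def reweight(stim: StimulusMatrix, weights: SpectralWeights) -> StimulusMatrix:
    """Map the stimulus into a J-dimensional spectral space.

    Output channel j at bin t is ``sum_i w[i, j] * s[i, t]``.
    """
    w = weights.matrix()
    if w.shape[0] != stim.n_channels:
        raise ValueError(
            f"weight input dimension {w.shape[0]} != stimulus channels "
            f"{stim.n_channels}")
    return StimulusMatrix(w.T @ stim.values, dt=stim.dt,
                          channel_labels=[f"rw{j}" for j in range(w.shape[1])])


def do_kernel(filt: DampedOscillatorFilter, dt: float) -> np.ndarray:
    """Evaluate the damped-oscillator kernel at lags 0, dt, ..., (n_lags-1)*dt."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    u = np.arange(filt.n_lags) * dt
    m = np.maximum(u - filt.latency, 0.0)
    return filt.gain * np.exp(-filt.decay * m) * np.sin(filt.freq * m)


@njit(cache=True)
def _fir_loop(values, kernels):  # pragma: no cover - exercised via wrapper
    C, T = values.shape
    L = kernels.shape[1]
    out = np.zeros(T)
    for c in range(C):
        vc = values[c]
        kc = kernels[c]
        warm = min(L - 1, T)
        for t in range(warm):  # bins before one full kernel length
            acc = 0.0
            for u in range(t + 1):
                acc += kc[u] * vc[t - u]
            out[t] += acc
        for t in range(warm, T):
            acc = 0.0
            for u in range(L):
                acc += kc[u] * vc[t - u]
            out[t] += acc
    return out


def fir_predict(stim: StimulusMatrix, kernels) -> np.ndarray:
    """Causal FIR filtering summed over channels.

    ``kernels`` is a (n_channels x n_lags) array (or list of 1-D kernels).
    Bins before stimulus onset are treated as silence (zero padding).
    Returns the linear drive rL(t), length = stim.n_bins.
    """
    kernels = np.atleast_2d(np.asarray(kernels, dtype=float))
    if kernels.shape[0] != stim.n_channels:
        raise ValueError(
            f"kernel count {kernels.shape[0]} != channel count {stim.n_channels}")
    return _fir_loop(np.ascontiguousarray(stim.values),
                     np.ascontiguousarray(kernels))


@njit(cache=True)
def _stp_loop(drive, v, tau, dt, d_min, d_max, canonical):  # pragma: no cover
    T = drive.shape[0]
    d = np.empty(T)
    d[0] = 1.0
    for t in range(1, T):
        prev = d[t - 1]
        if canonical:
            u = drive[t - 1]
            if u < 0.0:
                u = 0.0
            val = prev + dt * ((1.0 - prev) / tau - v * u * prev)
        else:
            val = prev + drive[t - 1] * (1.0 - prev) * v - prev / tau
        if val < d_min:
            val = d_min
        elif val > d_max:
            val = d_max
        d[t] = val
    return d


def stp_gain(drive: np.ndarray, v: float, tau: float, dt: float,
             mode: str = "canonical", d_min: float = 0.0,
             d_max: float = 5.0) -> np.ndarray:
    """Synaptic gain trajectory d(t) for a single channel.

    Canonical mode: recovery toward the baseline gain 1 with rate 1/tau and
    resource depletion proportional to ``v * max(drive, 0) * d``; v > 0
    yields depression (d <= 1), v < 0 facilitation (d >= 1, capped at
    ``d_max``).  Verbatim mode applies the alternative printed recursion
    unchanged.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if mode not in ("canonical", "verbatim"):
        raise ValueError(f"unknown STP mode {mode!r}")
    drive = np.ascontiguousarray(drive, dtype=np.float64)
    return _stp_loop(drive, float(v), float(tau), float(dt),
                     float(d_min), float(d_max), mode == "canonical")


def stp_apply(stim: StimulusMatrix, params: STPParams, dt: float | None = None
              ) -> StimulusMatrix:
    """Apply independent per-channel STP gains to each stimulus channel."""
    if params.n_channels != stim.n_channels:
        raise ValueError(
            f"{params.n_channels} STP channels for {stim.n_channels} stimulus "
            "channels")
    dt = stim.dt if dt is None else dt
    out = np.empty_like(stim.values)
    for i in range(stim.n_channels):
        d = stp_gain(stim.values[i], params.v[i], params.tau[i], dt,
                     mode=params.recursion_mode, d_min=params.d_min,
                     d_max=params.d_max)
        out[i] = d * stim.values[i]
    return StimulusMatrix(out, dt=stim.dt,
                          channel_labels=list(stim.channel_labels))


def global_stp(rL: np.ndarray, v: float, tau: float, dt: float,
               mode: str = "canonical", d_min: float = 0.0,
               d_max: float = 5.0,
               channel_drives: np.ndarray | None = None) -> np.ndarray:
    """Post-integration adaptation of the summed linear drive.

    The depletion drive is the rectified filter output ``max(rL, 0)`` (so
    negative drive cannot release resources); the resulting gain multiplies
    the signed drive itself.  If ``channel_drives`` (n_channels x T) is
    given, the common-input variant is used instead: per-channel gains are
    computed and their mean applied to rL.
    """
    rL = np.asarray(rL, dtype=float)
    if channel_drives is not None:
        gains = np.stack([
            stp_gain(ch, v, tau, dt, mode=mode, d_min=d_min, d_max=d_max)
            for ch in np.atleast_2d(channel_drives)
        ])
        return gains.mean(axis=0) * rL
    d = stp_gain(np.maximum(rL, 0.0), v, tau, dt, mode=mode,
                 d_min=d_min, d_max=d_max)
    return d * rL


def rectify_local(stim: StimulusMatrix, params: RectifierParams
                  ) -> StimulusMatrix:
    """Per-channel threshold rectification ``max(value - s0, 0)``."""
    s0 = params.s0
    if len(s0) != stim.n_channels:
        raise ValueError(
            f"{len(s0)} thresholds for {stim.n_channels} channels")
    return StimulusMatrix(np.maximum(stim.values - s0[:, None], 0.0),
                          dt=stim.dt, channel_labels=list(stim.channel_labels))


def output_nl(rL: np.ndarray, nl: OutputNL) -> np.ndarray:
    """Apply the static output nonlinearity elementwise."""
    rL = np.asarray(rL, dtype=float)
    if nl.kind == "linear":
        return rL.copy()
    if nl.kind == "relu":
        return np.maximum(rL - nl.base, 0.0) + nl.rate_offset
    if nl.kind == "logistic":
        z = np.clip((rL - nl.base) / nl.slope, -500, 500)
        return nl.rate_offset + nl.amplitude / (1.0 + np.exp(-z))
    if nl.kind == "dexp":
        inner = np.clip(nl.slope * (rL - nl.base), -500, 500)
        return nl.base + nl.amplitude * np.exp(-np.exp(inner))
    raise ValueError(f"unknown output nonlinearity {nl.kind!r}")


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _render_kernels(model: ModelSpec) -> np.ndarray:
    rows = []
    for f in model.filters:
        if isinstance(f, DampedOscillatorFilter):
            rows.append(do_kernel(f, model.dt))
        else:
            rows.append(np.asarray(f, dtype=float))
    return np.stack(rows)


def _effective_weights(model: ModelSpec) -> SpectralWeights:
    if not model.normalize_weights:
        return model.weights
    w = model.weights.matrix().copy()
    norms = np.linalg.norm(w, axis=0)
    norms[norms == 0] = 1.0
    return SpectralWeights(w=w / norms)


def predict(model: ModelSpec, stim: StimulusMatrix) -> np.ndarray:
    """Predicted firing rate (spikes/s per bin) for a stimulus.

    Stages are composed in architecture order; the computation is
    deterministic and causal (prediction at bin t depends only on stimulus
    bins <= t).
    """
    if model.weights.n_in != stim.n_channels:
        raise ValueError(
            f"model expects {model.weights.n_in} input channels, stimulus has "
            f"{stim.n_channels}")
    x = log_compress(stim) if model.compress else stim
    x = reweight(x, _effective_weights(model))
    if model.architecture == "localSTP":
        x = stp_apply(x, model.stp, model.dt)
    elif model.architecture == "localRect":
        x = rectify_local(x, model.rect)
    rL = fir_predict(x, _render_kernels(model))
    if model.architecture == "globalSTP":
        g = model.global_stp
        if model.common_input:
            rL = global_stp(rL, g.v[0], g.tau[0], model.dt,
                            mode=g.recursion_mode, d_min=g.d_min,
                            d_max=g.d_max, channel_drives=x.values)
        else:
            rL = global_stp(rL, g.v[0], g.tau[0], model.dt,
                            mode=g.recursion_mode, d_min=g.d_min,
                            d_max=g.d_max)
    return output_nl(rL, model.out_nl)
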