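"""Model estimation: multi-start gradient descent on MSE with shrinkage.

The estimation cost is the mean squared error between predicted and observed
rate, inflated by its own standard error across interleaved jackknife
subsets of time bins ("MSE with shrinkage", a form of early stopping:
improvements smaller than the noise in the error estimate do not lower the
cost).  Models are fit by L-BFGS-B with numerical gradients from several
random initial conditions, and the initial condition with the lowest
estimation cost wins.

Fitting is stage-wise by default: the linear--nonlinear skeleton (weights,
temporal filters, output nonlinearity) is optimized first with the local
nonlinear stage held neutral (STP strength v = 0 / rectifier threshold 0),
then all parameters are refined jointly.  This mirrors sequential fitting
and substantially improves the behaviour of the nonconvex STP stage.

Behavior-state-dependent fits use a nested hierarchy: a pooled
state-independent fit first, then only the designated parameter groups
(e.g. the output nonlinearity) are duplicated per state and refined, with
all remaining parameters frozen at the pooled solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import (DampedOscillatorFilter, ModelSpec, SpectralWeights,
                    predict)
from .stimuli import StimulusMatrix

__all__ = [
    "FitOptions",
    "FitResult",
    "CrossValResult",
    "BehaviorFitResult",
    "shrinkage_cost",
    "initialize",
    "canonicalize_channel_signs",
    "refine",
    "fit_model",
    "crossval_fit",
    "fit_behavior_dependent",
    "ParameterMap",
]

ALL_GROUPS = ("weights", "filter", "stp", "rect", "global", "nl")
LINEAR_GROUPS = ("weights", "filter", "nl")


@dataclass(frozen=True)
class FitOptions:
    n_random_inits: int = 10
    seed: int = 0
    max_iterations: int = 1000
    tol: float = 1e-7
    n_shrinkage_jackknives: int = 10
    cv_folds: int = 10
    stagewise: bool = True
    # stop drawing initial conditions once an init leaves less than this
    # fraction of the response variance unexplained (None: always run all)
    early_stop_frac: float | None = None

    def validate(self):
        if self.n_random_inits < 1:
            raise ValueError("n_random_inits must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_shrinkage_jackknives < 1:
            raise ValueError("n_shrinkage_jackknives must be >= 1")


@dataclass
class FitResult:
    model: ModelSpec
    init_costs: list
    best_init: int
    cost_trace: list
    validation_pred: np.ndarray | None = None


@dataclass
class CrossValResult:
    fold_results: list
    validation_pred: np.ndarray
    folds: np.ndarray

    @property
    def model(self) -> ModelSpec:
        costs = [fr.init_costs[fr.best_init] for fr in self.fold_results]
        return self.fold_results[int(np.argmin(costs))].model


@dataclass
class BehaviorFitResult:
    base_result: FitResult
    state_models: dict
    state_costs: dict
    split_level: str


# ---------------------------------------------------------------------------
# cost
# ---------------------------------------------------------------------------

def shrinkage_cost(pred: np.ndarray, obs: np.ndarray, n_jack: int = 10
                   ) -> float:
    """MSE scaled by its standard error: cost = m * (1 + s/m) = m + s.

    Per-bin squared errors are split into ``n_jack`` interleaved subsets;
    ``m`` is the mean subset MSE and ``s`` the standard error of the subset
    MSEs.  ``n_jack = 1`` gives the plain MSE.
    """
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    err = (pred - obs) ** 2
    if n_jack <= 1:
        return float(err.mean())
    sub = np.array([err[k::n_jack].mean() for k in range(n_jack)])
    m = sub.mean()
    s = sub.std(ddof=1) / np.sqrt(n_jack)
    return float(m + s)


# ---------------------------------------------------------------------------
# parameter vector mapping
# ---------------------------------------------------------------------------

class ParameterMap:
    """Flatten/unflatten the free parameters of a ModelSpec.

    Bound to a specific (mutable) model instance; ``set_vector`` writes the
    values back in place so repeated objective evaluations avoid copies.
    Parameter groups: weights, filter, stp, rect, global, nl.
    """

    def __init__(self, model: ModelSpec, groups=ALL_GROUPS):
        self.model = model
        self.entries = []  # (group, getter, setter, lb, ub, scale)
        g = set(groups)
        m = model
        if "weights" in g:
            if m.weights.is_gaussian:
                n_in = m.weights.n_in
                self._add("weights", lambda: m.weights.means,
                          self._setter_arr(m.weights, "means"),
                          -1.0, float(n_in), scale=2.0)
                self._add("weights", lambda: m.weights.sds,
                          self._setter_arr(m.weights, "sds"),
                          0.1, float(2 * n_in), scale=2.0)
            else:
                self._add("weights", lambda: m.weights.w.ravel(),
                          lambda v: m.weights.w.__setitem__(
                              ..., v.reshape(m.weights.w.shape)),
                          -np.inf, np.inf, scale=1.0)
        if "filter" in g:
            for f in m.filters:
                if not isinstance(f, DampedOscillatorFilter):
                    continue
                self._add_scalar("filter", f, "gain", -np.inf, np.inf,
                                 scale=max(abs(f.gain), 0.1))
                self._add_scalar("filter", f, "latency", 0.0,
                                 (f.n_lags - 1) * m.dt, scale=0.02)
                self._add_scalar("filter", f, "decay", 0.0, 400.0,
                                 scale=20.0)
                self._add_scalar("filter", f, "freq", 0.0, 400.0,
                                 scale=20.0)
        if "stp" in g and m.stp is not None:
            self._add("stp", lambda: m.stp.v, self._setter_arr(m.stp, "v"),
                      -2.0, 2.0, scale=0.2)
            self._add("stp", lambda: m.stp.tau,
                      self._setter_arr(m.stp, "tau"), 1e-3, 2.0, scale=0.05)
        if "rect" in g and m.rect is not None:
            self._add("rect", lambda: m.rect.s0,
                      self._setter_arr(m.rect, "s0"), -np.inf, np.inf,
                      scale=1.0)
        if "global" in g and m.global_stp is not None:
            self._add("global", lambda: m.global_stp.v,
                      self._setter_arr(m.global_stp, "v"), -2.0, 2.0,
                      scale=0.2)
            self._add("global", lambda: m.global_stp.tau,
                      self._setter_arr(m.global_stp, "tau"), 1e-3, 2.0,
                      scale=0.05)
        if "nl" in g:
            nl = m.out_nl
            if nl.kind in ("dexp", "logistic"):
                self._add_scalar("nl", nl, "base", -np.inf, np.inf,
                                 scale=max(abs(nl.base), 1.0))
                self._add_scalar("nl", nl, "amplitude", -np.inf, np.inf,
                                 scale=max(abs(nl.amplitude), 1.0))
                self._add_scalar("nl", nl, "slope", -np.inf, np.inf,
                                 scale=max(abs(nl.slope), 0.1))
                if nl.kind == "logistic":
                    self._add_scalar("nl", nl, "rate_offset", 0.0, np.inf,
                                     scale=1.0)
            elif nl.kind == "relu":
                self._add_scalar("nl", nl, "base", -np.inf, np.inf,
                                 scale=1.0)
                self._add_scalar("nl", nl, "rate_offset", 0.0, np.inf,
                                 scale=1.0)
            # linear: no free parameters

    @staticmethod
    def _setter_arr(obj, attr):
        def setter(v):
            getattr(obj, attr)[...] = v
        return setter

    def _add(self, group, getter, setter, lb, ub, scale=1.0):
        self.entries.append((group, getter, setter, lb, ub, scale))

    def _add_scalar(self, group, obj, attr, lb, ub, scale=1.0):
        self._add(group,
                  lambda o=obj, a=attr: np.atleast_1d(getattr(o, a)),
                  lambda v, o=obj, a=attr: setattr(o, a, float(v[0])),
                  lb, ub, scale)

    def get_vector(self) -> np.ndarray:
        return np.concatenate([np.asarray(g(), float).ravel()
                               for _, g, _, _, _, _ in self.entries]) \
            if self.entries else np.empty(0)

    @property
    def _sizes(self):
        sizes = getattr(self, "_size_cache", None)
        if sizes is None:
            sizes = [np.asarray(g()).size
                     for _, g, _, _, _, _ in self.entries]
            self._size_cache = sizes
        return sizes

    def set_vector(self, theta: np.ndarray) -> None:
        pos = 0
        for (_, _, setter, _, _, _), n in zip(self.entries, self._sizes):
            setter(theta[pos:pos + n])
            pos += n

    def scales(self) -> np.ndarray:
        """Characteristic magnitude per parameter; the optimizer works in
        units of these so finite-difference steps and curvature estimates
        are comparable across parameter kinds."""
        out = []
        for _, getter, _, _, _, scale in self.entries:
            out.extend([scale] * np.asarray(getter()).size)
        return np.asarray(out)

    def bounds(self):
        out = []
        for _, getter, _, lb, ub, _ in self.entries:
            out.extend([(lb, ub)] * np.asarray(getter()).size)
        return out


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize(model: ModelSpec, seed: int,
               resp: np.ndarray | None = None) -> ModelSpec:
    """Draw a random initial condition for every free parameter.

    Deterministic given ``seed``.  Spectral weights start small
    (N(0,1) x 0.01; Gaussian means spread evenly over channels, sd = 2),
    damped-oscillator filters draw gain in +/-[0.1, 1], latency in [0, 30] ms,
    decay in [5, 50]/s and frequency in [10, 100] rad/s, STP strength in
    [0.01, 0.2] (nonzero so recovery-time gradients exist) and tau in
    [0.02, 0.2] s.  Output-nonlinearity scales come from the response
    statistics when a response is supplied.
    """
    rng = np.random.default_rng(seed)
    m = model.copy()
    if m.weights.is_gaussian:
        n_in, n_out = m.weights.n_in, m.weights.n_out
        m.weights.means[...] = np.linspace(0, n_in - 1, n_out + 2)[1:-1] \
            + rng.normal(0, 0.5, n_out)
        m.weights.sds[...] = 2.0
    else:
        m.weights.w[...] = rng.normal(0.0, 1.0, m.weights.w.shape) * 0.01
    for f in m.filters:
        if isinstance(f, DampedOscillatorFilter):
            f.gain = float(rng.choice([-1, 1]) * rng.uniform(0.1, 1.0))
            f.latency = float(rng.uniform(0.0, 0.03))
            f.decay = float(rng.uniform(5.0, 50.0))
            f.freq = float(rng.uniform(10.0, 100.0))
    for stp in (m.stp, m.global_stp):
        if stp is not None:
            stp.v[...] = rng.uniform(0.01, 0.2, stp.v.shape)
            stp.tau[...] = rng.uniform(0.02, 0.2, stp.tau.shape)
    if m.rect is not None:
        m.rect.s0[...] = 0.0
    if resp is not None:
        resp = np.asarray(resp, float)
        mu, sd = float(resp.mean()), float(resp.std())
        scale = sd if sd > 0 else max(abs(mu), 1.0)
        nl = m.out_nl
        if nl.kind == "dexp":
            nl.base, nl.amplitude, nl.slope = mu, 4.0 * scale, -1.0 / scale
        elif nl.kind == "logistic":
            nl.base, nl.amplitude = mu, 4.0 * scale
            nl.slope, nl.rate_offset = scale, max(float(resp.min()), 0.0)
        elif nl.kind == "relu":
            nl.base, nl.rate_offset = 0.0, max(float(resp.min()), 0.0)
    return m


def _neutralize_nonlinear(m: ModelSpec) -> dict:
    """Freeze local nonlinear stages at their neutral (identity) values.

    Returns the saved values so they can be restored for the joint stage.
    """
    saved = {}
    if m.stp is not None:
        saved["stp_v"] = m.stp.v.copy()
        m.stp.v[...] = 0.0
    if m.global_stp is not None:
        saved["global_v"] = m.global_stp.v.copy()
        m.global_stp.v[...] = 0.0
    if m.rect is not None:
        saved["rect_s0"] = m.rect.s0.copy()
        m.rect.s0[...] = 0.0
    return saved


def canonicalize_channel_signs(m: ModelSpec) -> ModelSpec:
    """Flip weight-column/kernel-gain sign pairs so reweighted drives are
    predominantly positive.

    The transformation (w_j, G_j) -> (-w_j, -G_j) leaves every linear
    prediction unchanged, but the local STP and rectification stages act on
    the *signed* reweighted stimulus: a negative-leaning column silences
    the rectified adaptation drive entirely (zero gradient in v).  Fits
    that enable a local nonlinear stage from a linear solution therefore
    flip each channel into the positive-drive convention first.  In place;
    returns the model.
    """
    if m.weights.is_gaussian:
        return m  # gaussian columns are nonnegative by construction
    for j in range(m.weights.n_out):
        if m.weights.w[:, j].sum() < 0:
            m.weights.w[:, j] *= -1.0
            f = m.filters[j]
            if isinstance(f, DampedOscillatorFilter):
                f.gain *= -1.0
            else:
                m.filters[j] = -np.asarray(f, float)
    return m


def _restore_nonlinear(m: ModelSpec, saved: dict) -> None:
    if "stp_v" in saved:
        m.stp.v[...] = saved["stp_v"]
    if "global_v" in saved:
        m.global_stp.v[...] = saved["global_v"]
    if "rect_s0" in saved:
        m.rect.s0[...] = saved["rect_s0"]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _run_descent(working: ModelSpec, groups, stim, resp, mask, opts,
                 trace=None) -> float:
    pmap = ParameterMap(working, groups)
    x0 = pmap.get_vector()
    if x0.size == 0:
        pred = predict(working, stim)
        return shrinkage_cost(pred[mask], resp[mask],
                              opts.n_shrinkage_jackknives)
    scales = pmap.scales()
    resp_masked = resp[mask]

    def objective(theta_scaled):
        pmap.set_vector(theta_scaled * scales)
        pred = predict(working, stim)
        c = shrinkage_cost(pred[mask], resp_masked,
                           opts.n_shrinkage_jackknives)
        if not np.isfinite(c):
            return 1e12
        if trace is not None:
            trace.append(c)
        return c

    bounds = [(lb / s, ub / s) for (lb, ub), s in zip(pmap.bounds(), scales)]
    res = minimize(objective, x0 / scales, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": opts.max_iterations,
                            "ftol": opts.tol, "eps": 1e-6})
    pmap.set_vector(res.x * scales)
    return float(res.fun)


def refine(model: ModelSpec, stim: StimulusMatrix, resp: np.ndarray,
           opts: FitOptions = FitOptions(),
           mask: np.ndarray | None = None,
           groups=ALL_GROUPS) -> FitResult:
    """Single gradient descent from the model's current parameters.

    Useful for warm starts, e.g. refining a local-STP model initialized
    from a fitted LN solution plus a small STP strength (the LN model is a
    parameter slice of the local-STP model, so the refined cost can only
    improve on the LN cost).
    """
    resp = np.asarray(resp, float)
    if mask is None:
        mask = np.ones(stim.n_bins, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    working = model.copy()
    trace = []
    cost = _run_descent(working, groups, stim, resp, mask, opts, trace)
    return FitResult(model=working, init_costs=[cost], best_init=0,
                     cost_trace=trace)


def fit_model(model: ModelSpec, stim: StimulusMatrix, resp: np.ndarray,
              opts: FitOptions = FitOptions(),
              mask: np.ndarray | None = None) -> FitResult:
    """Estimate all model parameters from a stimulus/response pair.

    ``resp`` is a rate series (spikes/s) aligned with the stimulus bins;
    ``mask`` restricts the estimation cost to a boolean subset of bins
    (validation bins are simply excluded -- predictions are still computed
    over the full stimulus, preserving temporal context).  Returns the best
    of ``opts.n_random_inits`` random initial conditions by estimation cost;
    ties break toward the lowest init index.
    """
    opts.validate()
    resp = np.asarray(resp, float)
    if resp.shape != (stim.n_bins,):
        raise ValueError("response length must match stimulus bins")
    if mask is None:
        mask = np.ones(stim.n_bins, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("estimation mask selects no bins")

    seeds = np.random.SeedSequence(opts.seed).generate_state(
        opts.n_random_inits)
    target = None
    if opts.early_stop_frac is not None:
        target = opts.early_stop_frac * float(np.var(resp[mask]))
    best = None
    init_costs = []
    for idx in range(opts.n_random_inits):
        working = initialize(model, int(seeds[idx]), resp)
        trace = []
        try:
            nonlinear = any(g is not None for g in
                            (working.stp, working.rect, working.global_stp))
            if opts.stagewise and nonlinear:
                saved = _neutralize_nonlinear(working)
                _run_descent(working, LINEAR_GROUPS, stim, resp, mask, opts,
                             trace)
                _restore_nonlinear(working, saved)
                if working.stp is not None or working.rect is not None:
                    canonicalize_channel_signs(working)
                cost = _run_descent(working, ALL_GROUPS, stim, resp, mask,
                                    opts, trace)
            else:
                cost = _run_descent(working, ALL_GROUPS, stim, resp, mask,
                                    opts, trace)
        except Exception as exc:  # noqa: BLE001 - init-level robustness
            warnings.warn(f"init {idx} failed: {exc}")
            init_costs.append(np.inf)
            continue
        if not np.isfinite(cost):
            warnings.warn(f"init {idx} produced non-finite cost; discarded")
            init_costs.append(np.inf)
            continue
        init_costs.append(cost)
        if best is None or cost < best[1]:
            best = (idx, cost, working, trace)
        if target is not None and cost <= target:
            break
    if best is None:
        raise RuntimeError("all initial conditions failed")
    idx, cost, working, trace = best
    return FitResult(model=working, init_costs=init_costs, best_init=idx,
                     cost_trace=trace)


def crossval_fit(model: ModelSpec, stim: StimulusMatrix, resp: np.ndarray,
                 opts: FitOptions = FitOptions()) -> CrossValResult:
    """Interleaved k-fold cross-validated fit.

    Bin t belongs to validation fold ``t mod cv_folds``; each fold is fit on
    its 90% complement and predicts its held-out bins, and the concatenation
    of held-out predictions (in original time order) is the validation
    prediction.
    """
    opts.validate()
    resp = np.asarray(resp, float)
    T = stim.n_bins
    folds = np.arange(T) % opts.cv_folds
    val_pred = np.full(T, np.nan)
    fold_results = []
    for k in range(opts.cv_folds):
        est_mask = folds != k
        if not (~est_mask).any() or not est_mask.any():
            raise ValueError(f"fold {k} has no data")
        fr = fit_model(model, stim, resp, opts, mask=est_mask)
        pred = predict(fr.model, stim)
        val_pred[~est_mask] = pred[~est_mask]
        fold_results.append(fr)
    return CrossValResult(fold_results=fold_results,
                          validation_pred=val_pred, folds=folds)


_SPLIT_GROUPS = {
    "NL": ("nl",),
    "filter+NL": ("filter", "nl"),
    "all": ALL_GROUPS,
}


def fit_behavior_dependent(model: ModelSpec, stim: StimulusMatrix,
                           resp_by_state: dict,
                           split_level: str = "NL",
                           opts: FitOptions = FitOptions(),
                           mask: np.ndarray | None = None
                           ) -> BehaviorFitResult:
    """Two-stage behavior-state-dependent fit.

    Stage 1 fits a state-independent model to the pooled (state-averaged)
    response.  Stage 2 duplicates only the parameter groups named by
    ``split_level`` per state and refines each copy against that state's
    response, holding all other parameters frozen at the stage-1 solution.
    ``split_level='none'`` is identical to :func:`fit_model` on the pooled
    response.
    """
    if split_level not in ("none",) and split_level not in _SPLIT_GROUPS:
        raise ValueError(f"unknown split level {split_level!r}")
    if len(resp_by_state) < 2:
        raise ValueError("need responses from at least two behavioral states")
    states = list(resp_by_state)
    pooled = np.mean([np.asarray(resp_by_state[s], float) for s in states],
                     axis=0)
    base = fit_model(model, stim, pooled, opts, mask=mask)
    if mask is None:
        mask = np.ones(stim.n_bins, dtype=bool)
    if split_level == "none":
        return BehaviorFitResult(
            base_result=base,
            state_models={s: base.model for s in states},
            state_costs={s: shrinkage_cost(
                predict(base.model, stim)[mask],
                np.asarray(resp_by_state[s], float)[mask],
                opts.n_shrinkage_jackknives) for s in states},
            split_level=split_level)
    groups = _SPLIT_GROUPS[split_level]
    state_models, state_costs = {}, {}
    for s in states:
        working = base.model.copy()
        resp_s = np.asarray(resp_by_state[s], float)
        cost = _run_descent(working, groups, stim, resp_s, mask, opts)
        state_models[s] = working
        state_costs[s] = cost
    return BehaviorFitResult(base_result=base, state_models=state_models,
                             state_costs=state_costs,
                             split_level=split_level)
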