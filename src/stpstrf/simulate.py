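"""Ground-truth neuron simulation and parameter-recovery harnesses.

Synthetic neurons are built from the same model family the package fits, so
every stage of the pipeline can be verified end to end: generate a
stimulus, pass it through a known model, sample spikes, fit candidate
architectures to the samples, and compare the estimates with the truth.

Default ground-truth neurons have two spectral channels -- a strong
excitatory channel with graded short-term depression and a weaker
inhibitory (negative-gain) channel with weak depression, mirroring the
E/I asymmetry that spectrally tuned adaptation produces in cortex.  Kernel
gains are scaled so evoked rates land in a realistic 20--40 spikes/s
regime; spiking is Poisson per 10 ms bin.  These simulators run on
uncompressed envelope matrices (native sound-level units), where release
probabilities in [0.1, 0.6] span weak to strong adaptation.

Three experiment drivers are provided:

* :func:`recovery_experiment` -- fit LN and local-STP models to simulated
  neurons, score both on held-out data, and report parameter recovery and
  model-selection outcomes.
* :func:`ssa_experiment` -- simulate oddball responses from adapting
  neurons, fit LN / global-STP / local-STP models, and compare actual
  against model-predicted SSA indices.
* :func:`behavior_experiment` -- plant a behavior-state gain change and test
  whether the state-split output nonlinearity recovers it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluate import (SpikeRaster, adaptation_index, channel_gains,
                       jackknife_ttest, noise_corrected_r,
                       population_sign_test, psth)
from .fit import FitOptions, fit_behavior_dependent, fit_model
from .model import (DampedOscillatorFilter, ModelSpec, OutputNL,
                    SpectralWeights, STPParams, predict)
from .ssa import burst_responses, predicted_si, ssa_index
from .stimuli import (EnvelopeParams, OddballParams, StimulusMatrix,
                      natural_envelope, oddball_sequence, vocmod_stimulus)

__all__ = [
    "GroundTruthConfig",
    "RecoveryReport",
    "make_vocmod_stimulus",
    "ground_truth_model",
    "simulate_neuron",
    "recovery_experiment",
    "figure6_analysis",
    "ssa_experiment",
    "behavior_experiment",
]

RECOVERY_OPTS = FitOptions(n_random_inits=2, max_iterations=150, seed=0)


@dataclass(frozen=True)
class GroundTruthConfig:
    """Study conditions for a simulated population."""

    n_neurons: int = 20
    architecture: str = "localSTP"   # ground-truth architecture
    v_range: tuple = (0.1, 0.6)      # excitatory-channel release probability
    tau_range: tuple = (0.03, 0.15)  # recovery time constant, s
    v_inhibitory: float = 0.05       # fixed weak depression on the I channel
    tau_inhibitory: float = 0.08
    n_trials: int = 20
    n_stim_samples: int = 30         # 3-s vocalization-noise samples
    stim_duration: float = 3.0
    noise: str = "poisson"           # or "gaussian"
    gaussian_sigma: float = 5.0      # spikes/s, for gaussian noise
    amplitude: float = 70.0          # peak evoked rate of the output NL
    spont: float = 0.0               # baseline rate
    seed: int = 0

    def validate(self):
        if self.n_neurons < 1 or self.n_trials < 1:
            raise ValueError("n_neurons and n_trials must be >= 1")
        if self.noise not in ("poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.architecture not in ("LN", "localSTP"):
            raise ValueError("ground truth architecture must be LN or localSTP")


@dataclass
class RecoveryReport:
    table: pd.DataFrame
    models: dict = field(default_factory=dict)  # neuron -> fitted localSTP
    config: GroundTruthConfig | None = None

    def summary(self) -> dict:
        t = self.table.dropna(subset=["est_v"])
        out = {"n_neurons": len(self.table),
               "n_significant": int(self.table["stp_significant"].sum())}
        if len(t) >= 3 and t["true_v"].std() > 0:
            from scipy.stats import spearmanr
            out["v_rank_corr"] = float(
                spearmanr(t["true_v"], t["est_v"]).statistic)
        strong = t[t["true_v"] >= 0.2]
        if len(strong):
            ratio = strong["est_tau"] / strong["true_tau"]
            out["tau_within_factor2"] = float(
                np.mean((ratio >= 0.5) & (ratio <= 2.0)))
        return out


# ---------------------------------------------------------------------------
# stimulus and ground-truth construction
# ---------------------------------------------------------------------------

def make_vocmod_stimulus(n_samples: int = 30, duration: float = 3.0,
                         seed: int = 0, dt: float = 0.010,
                         peak_level: float = 65.0) -> StimulusMatrix:
    """Concatenated two-band vocalization-modulated noise samples."""
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_samples)
    base = EnvelopeParams(duration=duration, peak_level=peak_level)
    parts = []
    for k in range(n_samples):
        e1 = natural_envelope(replace(base, seed=int(seeds[2 * k])))
        e2 = natural_envelope(replace(base, seed=int(seeds[2 * k + 1])))
        parts.append(vocmod_stimulus(e1, e2, base.fs_env, dt).values)
    return StimulusMatrix(np.concatenate(parts, axis=1), dt=dt,
                          channel_labels=["band0", "band1"])


def _model_skeleton(architecture: str, rank: int = 2, n_in: int = 2,
                    dt: float = 0.010, compress: bool = False,
                    normalize_weights: bool = True) -> ModelSpec:
    """Fit-ready model spec with placeholder parameters."""
    kw = dict(
        architecture=architecture,
        weights=SpectralWeights(w=np.eye(n_in, rank)),
        filters=[DampedOscillatorFilter() for _ in range(rank)],
        out_nl=OutputNL(kind="dexp", base=1.0, amplitude=20.0, slope=-1.0),
        compress=compress, normalize_weights=normalize_weights, dt=dt)
    if architecture == "localSTP":
        kw["stp"] = STPParams(v=np.full(rank, 0.1), tau=np.full(rank, 0.1))
    elif architecture == "localRect":
        from .model import RectifierParams
        kw["rect"] = RectifierParams(s0=np.zeros(rank))
    elif architecture == "globalSTP":
        kw["global_stp"] = STPParams(v=np.array([0.1]), tau=np.array([0.1]))
    return ModelSpec(**kw)


def ground_truth_model(rng: np.random.Generator, stim: StimulusMatrix,
                       architecture: str = "localSTP",
                       v_exc: float = 0.4, tau_exc: float = 0.08,
                       v_inh: float = 0.05, tau_inh: float = 0.08,
                       spont: float = 0.0, amplitude: float = 70.0,
                       second_gain_range: tuple = (-0.5, -0.25),
                       drive_norm: str = "std") -> ModelSpec:
    """Two-channel ground-truth neuron with E/I channel asymmetry.

    Channel 0 is excitatory (positive-gain filter, depression ``v_exc``);
    channel 1 is inhibitory by default (negative gain drawn from
    ``second_gain_range``, weak depression ``v_inh``); a positive
    ``second_gain_range`` yields a second, weaker excitatory band instead.
    Temporal kernels are single-lobed (slow oscillation relative to the
    150 ms window) so the per-channel gain -- the kernel coefficient sum --
    is robustly signed.  Kernel gains are rescaled so the linear drive has
    unit standard deviation on ``stim``, which puts evoked rates in the
    20--40 spikes/s range for the default output nonlinearity (baseline
    ``spont``, maximum evoked rate ``amplitude``).
    """
    m = _model_skeleton(architecture, rank=2, n_in=stim.n_channels,
                        dt=stim.dt, compress=False, normalize_weights=False)
    m.filters = [
        DampedOscillatorFilter(gain=float(rng.uniform(0.8, 1.2)),
                               latency=float(rng.uniform(0.0, 0.02)),
                               decay=float(rng.uniform(15.0, 35.0)),
                               freq=float(rng.uniform(15.0, 35.0))),
        DampedOscillatorFilter(gain=float(rng.uniform(*second_gain_range)),
                               latency=float(rng.uniform(0.0, 0.02)),
                               decay=float(rng.uniform(15.0, 35.0)),
                               freq=float(rng.uniform(15.0, 35.0))),
    ]
    if architecture == "localSTP":
        m.stp.v[...] = [v_exc, v_inh]
        m.stp.tau[...] = [tau_exc, tau_inh]
    # scale the linear drive so the sigmoid operates mid-range: unit sd for
    # continuous envelopes, peak = 2 for sparse burst trains (where the sd
    # normalization would park burst tops in the saturated tail)
    probe = m.copy()
    probe.out_nl = OutputNL(kind="linear")
    rL = predict(probe, stim)
    scale = rL.std() if drive_norm == "std" else rL.max() / 2.0
    if scale > 0:
        for f in m.filters:
            f.gain /= scale
    m.out_nl = OutputNL(kind="dexp", base=spont, amplitude=amplitude,
                        slope=-2.0)
    return m


def simulate_neuron(model: ModelSpec, stim: StimulusMatrix, n_trials: int,
                    noise: str = "poisson", seed: int = 0,
                    gaussian_sigma: float = 5.0) -> SpikeRaster:
    """Sample a spike raster from a model's predicted rate.

    Rates are clipped at 0; Poisson noise draws independent counts per
    trial and bin with mean ``rate * dt``; Gaussian noise adds
    ``N(0, sigma * dt)`` to the expected count (clipped at 0).
    """
    if stim.dt <= 0:
        raise ValueError("dt must be positive")
    rate = np.maximum(predict(model, stim), 0.0)
    lam = rate * stim.dt
    rng = np.random.default_rng(seed)
    if noise == "poisson":
        counts = rng.poisson(lam, size=(n_trials, len(lam)))
    elif noise == "gaussian":
        counts = np.maximum(
            lam + rng.normal(0.0, gaussian_sigma * stim.dt,
                             size=(n_trials, len(lam))), 0.0)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return SpikeRaster(counts=counts, dt=stim.dt)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def _block_validation_mask(n_bins: int, block: int = 50,
                           n_groups: int = 5) -> np.ndarray:
    """Boolean estimation mask: every n_groups-th 0.5-s block held out."""
    blocks = np.arange(n_bins) // block
    return (blocks % n_groups) != (n_groups - 1)


def recovery_experiment(config: GroundTruthConfig,
                        opts: FitOptions = RECOVERY_OPTS) -> RecoveryReport:
    """Simulate a population, fit LN and local-STP models, score recovery.

    Per neuron: draw ground-truth parameters, sample a Poisson raster,
    fit both architectures on interleaved estimation blocks (80%), score
    noise-corrected prediction correlations on held-out blocks (20%), and
    test LN vs local STP with the jackknife comparison.  Estimated STP
    parameters are read from the fitted model's highest-gain (excitatory)
    channel.  Per-neuron failures are recorded, not fatal.
    """
    config.validate()
    stim = make_vocmod_stimulus(config.n_stim_samples, config.stim_duration,
                                seed=config.seed)
    est_mask = _block_validation_mask(stim.n_bins)
    val = ~est_mask
    ss = np.random.SeedSequence(config.seed + 1).generate_state(
        3 * config.n_neurons)
    rows, models = [], {}
    for n in range(config.n_neurons):
        rng = np.random.default_rng(int(ss[3 * n]))
        true_v = float(rng.uniform(*config.v_range))
        true_tau = float(rng.uniform(*config.tau_range))
        truth = ground_truth_model(
            rng, stim, architecture=config.architecture,
            v_exc=true_v, tau_exc=true_tau,
            v_inh=config.v_inhibitory, tau_inh=config.tau_inhibitory,
            spont=config.spont, amplitude=config.amplitude)
        raster = simulate_neuron(truth, stim, config.n_trials,
                                 noise=config.noise, seed=int(ss[3 * n + 1]),
                                 gaussian_sigma=config.gaussian_sigma)
        resp = psth(raster)
        row = {"neuron": n, "true_v": true_v, "true_tau": true_tau,
               "architecture": config.architecture}
        try:
            from .fit import refine
            fit_opts = replace(opts, seed=int(ss[3 * n + 2]) % (2 ** 31))
            ln = fit_model(_model_skeleton("LN"), stim, resp, fit_opts,
                           mask=est_mask)
            # portfolio: stagewise random inits plus warm starts from the
            # fitted LN solution (STP+NL accommodation, then joint); the
            # lowest estimation cost wins.  The warm starts rescue fits
            # that fall into the v/tau trade-off plateau of weakly
            # adapting neurons.
            cands = [fit_model(_model_skeleton("localSTP"), stim, resp,
                               fit_opts, mask=est_mask)]
            for v0 in (0.1, 0.3):
                cand = _warm_from_ln("localSTP", ln.model, v0, tau0=0.1)
                ph1 = refine(cand, stim, resp, fit_opts, mask=est_mask,
                             groups=("stp", "nl"))
                cands.append(refine(ph1.model, stim, resp, fit_opts,
                                    mask=est_mask))
            # axis-aligned candidate: the reweighting stage has a gauge
            # freedom under channel mixing that the linear stage cannot
            # resolve, but band-specific adaptation can only be expressed
            # in an unmixed gauge; starting from identity weights makes
            # that gauge reachable
            from .fit import initialize
            axis = initialize(_model_skeleton("localSTP"),
                              int(ss[3 * n + 2]) % (2 ** 31), resp)
            axis.weights.w[...] = np.eye(axis.weights.n_in, axis.rank)
            axis.stp.v[...] = 0.2
            axis.stp.tau[...] = 0.1
            ph1 = refine(axis, stim, resp, fit_opts, mask=est_mask,
                         groups=("filter", "nl", "stp"))
            cands.append(refine(ph1.model, stim, resp, fit_opts,
                                mask=est_mask))
            # model comparison uses the best-fitting candidate; parameter
            # readout uses the parsimony rule, which matters only where
            # the candidates are statistically indistinguishable (the
            # weak-adaptation v/tau degeneracy)
            costs = [fr.init_costs[fr.best_init] for fr in cands]
            stp = cands[int(np.argmin(costs))]
            stp_params = _select_parsimonious(cands, stim, resp, est_mask)
            pred_ln = predict(ln.model, stim)
            pred_stp = predict(stp.model, stim)
            raster_val = SpikeRaster(raster.counts[:, val], dt=stim.dt)
            row["r_ln"] = noise_corrected_r(pred_ln[val], raster_val).r
            row["r_stp"] = noise_corrected_r(pred_stp[val], raster_val).r
            comp = jackknife_ttest(pred_ln[val], pred_stp[val], resp[val])
            row["stp_significant"] = bool(comp.significant
                                          and comp.r_b > comp.r_a)
            # pair the estimated STP channel with the ground-truth excitatory
            # band (input channel 0): the channel carrying the most
            # consequential band-0 drive (positive normalized weight times
            # kernel-gain magnitude), robust to channel permutation and to
            # junk v values on weakly driven channels
            w = stp_params.model.weights.matrix()
            w = w / np.maximum(np.linalg.norm(w, axis=0), 1e-12)
            kernel_gain = np.abs(channel_gains(stp_params.model).gains)
            exc = int(np.argmax(np.maximum(w[0], 0.0) * kernel_gain))
            row["est_v"] = float(stp_params.model.stp.v[exc])
            row["est_tau"] = float(stp_params.model.stp.tau[exc])
            row["cost_ln"] = ln.init_costs[ln.best_init]
            row["cost_stp"] = stp.init_costs[stp.best_init]
            models[n] = stp.model
        except Exception as exc_info:  # noqa: BLE001 - per-neuron robustness
            warnings.warn(f"neuron {n} failed: {exc_info}")
            row.update(est_v=np.nan, est_tau=np.nan, r_ln=np.nan,
                       r_stp=np.nan, stp_significant=False)
        rows.append(row)
    return RecoveryReport(table=pd.DataFrame(rows), models=models,
                          config=config)


def figure6_analysis(models: dict | list, dt: float = 0.010) -> dict:
    """Excitatory/inhibitory STP asymmetry across fitted local-STP models.

    For each model, the adaptation index is computed for the highest-gain
    (excitatory) and lowest-gain (inhibitory) channels; the population is
    compared with a paired sign test.  Returns the per-neuron table and the
    sign-test p-value.
    """
    if isinstance(models, dict):
        models = list(models.values())
    rows = []
    for m in models:
        if m.architecture != "localSTP":
            continue
        cg = channel_gains(m)
        imin = int(np.argmin(cg.gains))
        rows.append({
            "index_exc": adaptation_index(m.stp.v[cg.excitatory],
                                          m.stp.tau[cg.excitatory], dt),
            "index_inh": adaptation_index(m.stp.v[imin], m.stp.tau[imin], dt),
            "gain_exc": cg.gains[cg.excitatory],
            "gain_inh": cg.gains[imin],
        })
    table = pd.DataFrame(rows)
    p = population_sign_test(table["index_inh"], table["index_exc"])
    return {"table": table,
            "mean_index_exc": float(table["index_exc"].mean()),
            "mean_index_inh": float(table["index_inh"].mean()),
            "p_sign": p,
            "n": len(table)}


def _select_parsimonious(candidates, stim, resp, mask):
    """Choose among fitted STP candidates: lowest estimation cost, with
    ties broken toward the weakest nonlinearity.

    At weak adaptation the cost surface is nearly degenerate along a
    v/tau trade-off (a fast-recovering, strong synapse mimics the
    quasi-static compression of a slow weak one), so candidates whose
    costs differ by less than the cost's own standard error are
    statistically indistinguishable; among those, the candidate with the
    smallest release-probability norm is preferred (continuity with the
    nested linear model).
    """
    costs = [fr.init_costs[fr.best_init] for fr in candidates]
    best = int(np.argmin(costs))
    pred = predict(candidates[best].model, stim)
    mse = float(np.mean((pred[mask] - resp[mask]) ** 2))
    tol = max(costs[best] - mse, 0.0)  # shrinkage term = cost's own SE
    eligible = [fr for fr, c in zip(candidates, costs)
                if c <= costs[best] + tol]
    return min(eligible,
               key=lambda fr: float(np.linalg.norm(fr.model.stp.v)))


def _warm_from_ln(arch: str, ln_model: ModelSpec, v0: float,
                  tau0: float = 0.08) -> ModelSpec:
    """STP-architecture model initialized at a fitted LN solution."""
    import copy
    from .fit import canonicalize_channel_signs
    m = _model_skeleton(arch)
    m.weights.w[...] = ln_model.weights.matrix()
    m.filters = copy.deepcopy(ln_model.filters)
    m.out_nl = copy.deepcopy(ln_model.out_nl)
    canonicalize_channel_signs(m)
    stp = m.stp if arch == "localSTP" else m.global_stp
    stp.v[...] = v0
    stp.tau[...] = tau0
    return m


def _oddball_trials(seed: int, n_trials: int, params: OddballParams):
    """Oddball trials guaranteed to include both standard-band conditions
    (so band preference cancels in the pooled SSA index)."""
    for k in range(1000):
        stims, table = oddball_sequence(replace(params, seed=seed + k),
                                        n_trials)
        if table["condition"].nunique() == 2:
            return stims, table
    raise RuntimeError("could not draw both oddball conditions")


def ssa_experiment(n_neurons: int = 20, seed: int = 0, n_trials: int = 2,
                   v_range: tuple = (0.1, 0.6), tau: float = 0.10,
                   opts: FitOptions = FitOptions(n_random_inits=8,
                                                 max_iterations=300,
                                                 early_stop_frac=0.05,
                                                 seed=0)) -> dict:
    """Compare actual vs model-predicted SSA across a simulated population.

    Noiseless adapting neurons (excitatory-channel release probability
    graded over ``v_range``, recovery time constant fixed at ``tau`` so
    adaptation strength orders with v) respond to oddball sequences; LN,
    global-STP and local-STP models are fit to those responses and their
    predicted SSA indices compared with the actual ones.  Returns the
    per-neuron table and per-architecture SI prediction error summaries.
    """
    params = OddballParams()
    stims, table = _oddball_trials(seed + 100, n_trials, params)
    # concatenated version for fitting
    concat = StimulusMatrix(
        np.concatenate([s.values for s in stims], axis=1), dt=params.dt)
    trial_bins = stims[0].n_bins
    burst_bins = int(round(params.burst_duration / params.dt))
    ss = np.random.SeedSequence(seed).generate_state(2 * n_neurons)
    archs = ("LN", "globalSTP", "localSTP")
    rows = []
    for n in range(n_neurons):
        rng = np.random.default_rng(int(ss[2 * n]))
        v = float(np.linspace(*v_range, n_neurons)[n])
        # both synapses share the neuron's release probability so both
        # bands adapt and the band-pooled SSA index grades cleanly with v
        truth = ground_truth_model(rng, concat, architecture="localSTP",
                                   v_exc=v, tau_exc=tau, v_inh=v,
                                   tau_inh=tau,
                                   second_gain_range=(0.3, 0.5),
                                   spont=1.0, drive_norm="peak")
        # actual (noiseless) response and SSA index
        parts = []
        rates = []
        for t, stim in enumerate(stims):
            rate = predict(truth, stim)
            rates.append(rate)
            parts.append(burst_responses(rate, table, params.dt,
                                         burst_bins=burst_bins, trial=t))
        actual_si = ssa_index(pd.concat(parts, ignore_index=True))
        resp = np.concatenate(rates)
        row = {"neuron": n, "true_v": v, "true_tau": tau,
               "actual_si": actual_si}
        fit_opts = replace(opts, seed=int(ss[2 * n + 1]) % (2 ** 31))
        from .fit import refine
        ln = fit_model(_model_skeleton("LN"), concat, resp, fit_opts)
        # random initializations occasionally plateau on sparse binary
        # burst stimuli; an identity-reweighting start with data-scaled
        # output nonlinearity is a reliable extra candidate
        struct = _model_skeleton("LN")
        struct.weights.w[...] = np.eye(2)
        sd = max(float(resp.std()), 1e-6)
        struct.out_nl = OutputNL(kind="dexp", base=float(resp.mean()),
                                 amplitude=4.0 * sd, slope=-1.0 / sd)
        ln_struct = refine(struct, concat, resp, fit_opts)
        if ln_struct.init_costs[0] < ln.init_costs[ln.best_init]:
            ln = ln_struct
        fits = {"LN": ln}
        # the LN model is a parameter slice of both STP architectures:
        # warm-start them from the fitted LN solution, first letting only
        # the STP stage and output nonlinearity move (so the NL can unwind
        # the adaptation it absorbed), then refining everything jointly
        from .fit import refine
        for arch in ("globalSTP", "localSTP"):
            group1 = ("stp", "nl") if arch == "localSTP" else ("global", "nl")
            # cheap accommodation pass over the v0 grid, then full joint
            # refinement of the two most promising starts
            phase1 = []
            for v0 in (0.1, 0.3, 0.6):
                cand = _warm_from_ln(arch, ln.model, v0)
                phase1.append(refine(cand, concat, resp, fit_opts,
                                     groups=group1))
            phase1.sort(key=lambda fr: fr.init_costs[0])
            best = None
            for ph1 in phase1[:2]:
                fr = refine(ph1.model, concat, resp, fit_opts)
                if best is None or fr.init_costs[0] < best.init_costs[0]:
                    best = fr
            fits[arch] = best
        for arch in archs:
            row[f"si_{arch}"] = predicted_si(fits[arch].model, stims, table,
                                             burst_bins=burst_bins)
        rows.append(row)
    tab = pd.DataFrame(rows)
    from .ssa import si_prediction_error
    errors = {arch: si_prediction_error(tab["actual_si"], tab[f"si_{arch}"])
              for arch in archs}
    return {"table": tab, "errors": errors}


def behavior_experiment(n_neurons: int = 10, seed: int = 0,
                        gain_ratio: float = 1.5, n_trials: int = 20,
                        n_stim_samples: int = 10,
                        opts: FitOptions = RECOVERY_OPTS) -> dict:
    """Recovery of a planted behavior-state gain change.

    Each simulated neuron responds in two states; the active state's output
    nonlinearity amplitude is scaled by ``gain_ratio``, all other
    parameters shared.  The state-split output-nonlinearity model
    (``split_level='NL'``) is compared with the state-independent model on
    held-out data, and the recovered amplitude ratio is reported.
    """
    stim = make_vocmod_stimulus(n_stim_samples, seed=seed + 500)
    est_mask = _block_validation_mask(stim.n_bins)
    val = ~est_mask
    ss = np.random.SeedSequence(seed).generate_state(4 * n_neurons)
    rows = []
    for n in range(n_neurons):
        rng = np.random.default_rng(int(ss[4 * n]))
        truth_passive = ground_truth_model(
            rng, stim, v_exc=float(rng.uniform(0.2, 0.5)),
            tau_exc=float(rng.uniform(0.05, 0.12)))
        truth_active = truth_passive.copy()
        truth_active.out_nl.amplitude *= gain_ratio
        resp = {}
        for state, truth, s in (("passive", truth_passive, ss[4 * n + 1]),
                                ("active", truth_active, ss[4 * n + 2])):
            raster = simulate_neuron(truth, stim, n_trials, seed=int(s))
            resp[state] = psth(raster)
        fit_opts = replace(opts, seed=int(ss[4 * n + 3]) % (2 ** 31))
        split = fit_behavior_dependent(_model_skeleton("localSTP"), stim,
                                       resp, split_level="NL",
                                       opts=fit_opts, mask=est_mask)
        base_model = split.base_result.model
        base_pred = predict(base_model, stim)
        # a pure gain change leaves the prediction correlation untouched
        # (Pearson r is scale-invariant), so held-out error is the metric
        # that can reveal the split model's advantage
        mse_none, mse_split = [], []
        for state in ("passive", "active"):
            pred_s = predict(split.state_models[state], stim)
            mse_none.append(np.mean((base_pred[val] - resp[state][val]) ** 2))
            mse_split.append(np.mean((pred_s[val] - resp[state][val]) ** 2))
        amp = {s: split.state_models[s].out_nl.amplitude
               for s in ("passive", "active")}
        rows.append({
            "neuron": n,
            "true_ratio": gain_ratio,
            "est_ratio": amp["active"] / amp["passive"],
            "mse_none": float(np.mean(mse_none)),
            "mse_split": float(np.mean(mse_split)),
            "stp_v_passive": float(split.state_models["passive"].stp.v[0]),
            "stp_v_active": float(split.state_models["active"].stp.v[0]),
        })
    table = pd.DataFrame(rows)
    p = population_sign_test(table["mse_split"], table["mse_none"])
    return {"table": table,
            "p_split_better": p,
            "n_split_better": int((table["mse_split"]
                                   < table["mse_none"]).sum()),
            "mean_est_ratio": float(table["est_ratio"].mean())}
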