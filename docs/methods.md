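# Methods

`stpstrf` implements a family of spectro-temporal encoding models for
auditory cortical neurons in which short-term synaptic plasticity (STP)
provides spectrally tuned adaptation, together with the stimulus
generators, fitting machinery, evaluation statistics and ground-truth
simulation harnesses needed to exercise every claim of the analysis on
synthetic data.

## Model family

All models map a nonnegative channel x time stimulus matrix (10 ms bins)
to a predicted firing rate through a cascade:

1. **Log compression** `s -> log(1 + s)` (optional; a fixed cochlear-style
   front end, on by default).
2. **Spectral reweighting** `sR(j,t) = sum_i w(i,j) s(i,t)` maps the input
   channels into a rank-J space (J = 1..5 for two-band stimuli).  For
   natural-sound spectrograms the weights can be parameterized as Gaussian
   tuning curves over channel index (mean, sd per output channel, peak 1);
   since the spectrogram channels are log-spaced, channel index stands in
   for log frequency.
3. **Local nonlinearity** (architecture-dependent):
   * *local STP*: each reweighted channel is scaled by its own synaptic
     gain `d(j,t)` (below);
   * *local rectification*: `max(sR - s0(j), 0)` per channel — a
     non-adaptive control for "any nonlinearity before the filter";
   * *LN*: nothing.
4. **Temporal filtering**: per-channel causal FIR over lags 0–150 ms,
   parameterized as a damped oscillator
   `h(u) = G exp(-decay * m(u)) sin(freq * m(u))`, `m(u) = max(u - u0, 0)`,
   with four parameters per channel (gain, latency u0, decay 1/s,
   frequency rad/s); raw kernels are also accepted.
5. **Global STP** (globalSTP architecture only): a single synaptic gain
   driven by the rectified filter output multiplies the summed drive.
6. **Static output nonlinearity**: double-exponential sigmoid
   `r = b + A exp(-exp(kappa (rL - b)))` by default (increasing for
   `kappa < 0`, bounded by `[b, b + A]`), with linear, rectified-linear
   and logistic controls.

### STP dynamics

The synaptic gain follows a two-parameter resource model, updated per
10 ms bin with the bin width explicit so both parameters carry physical
units:

    d[t] = d[t-1] + dt * ( (1 - d[t-1]) / tau  -  v * max(drive[t-1], 0) * d[t-1] )

with `d[0] = 1` and `d` clipped to `[0, 5]`.  `v > 0` produces depression
(`d <= 1`), `v < 0` facilitation, and `tau` (seconds) sets recovery to the
baseline gain of 1.  `v` has units of 1/(second x drive-unit): the
depletion rate is proportional to the instantaneous drive, so the drive's
scale is part of the model definition.  A `verbatim` recursion mode
implements an alternative literal difference form
(`d[t] = d[t-1] + s[t-1](1-d[t-1])v - d[t-1]/tau`) for comparison; it
relaxes toward 0 rather than 1 under silence and is not the default.

Because `v` in the commonly reported range 0.1–0.6 only produces material
adaptation when the drive is of order ten or more, the simulation
harnesses feed the models envelope matrices in native sound-level units
(0–65) with compression disabled; the architecture default for real
spectrograms remains log compression.  The adaptation index (one minus
the output/input ratio of a synapse for a standard test signal, 0.5 s
silence + 0.5 s unit pulse) is computed on the unit scale and is used
only for ordering and sign, both of which are scale-robust.

### Identifiability

The reweighting scale trades off exactly against filter gain, and — less
obviously — against STP strength, since the depletion drive is the
reweighted stimulus.  Fitted model specs therefore normalize each weight
column to unit L2 norm inside prediction (`normalize_weights=True`),
pinning the drive scale so `v` is identifiable.  A second degeneracy is
the sign pair `(w_j, G_j) -> (-w_j, -G_j)`, invisible to any linear
architecture but fatal to the STP stage (a negative-leaning column yields
zero rectified drive and a vanishing gradient in `v`); all fits that
enable a local nonlinear stage from a linear solution first flip each
channel into the positive-drive convention.

## Fitting

The estimation cost is MSE with shrinkage: per-bin squared errors are
split into `n_jack = 10` interleaved subsets and the cost is
`m + s`, the mean subset MSE plus its standard error -- the simplest
form of "MSE scaled by its standard error"; `n_jack = 1` recovers plain
MSE.  Optimization is L-BFGS-B
with numerical gradients in a scaled parameter space (each parameter is
divided by a characteristic magnitude — e.g. 0.2 for `v`, 50 ms for
`tau`, 20 ms for latency — so finite-difference steps and curvature
estimates are commensurable; without this, recovery of `v` and `tau` is
unreliable).  Bounds: `tau > 1 ms`, rectified latency within the lag
window, `sigma_j > 0.1` channels for Gaussian weights.

Fits run from several random initial conditions (10 by default; the
harnesses use 2 with stage-wise initialization, stated below) and the
init with the lowest estimation cost wins, ties toward the lowest index.
Stage-wise fitting first optimizes the linear–nonlinear skeleton with the
local nonlinear stage neutral (v = 0 / s0 = 0), then refines everything
jointly; `refine` additionally supports warm starts, e.g. local STP from
a fitted LN solution plus small `v`, which by nesting can only improve
the cost.  On sparse binary oddball stimuli the LN landscape itself has
wide plateau basins, and roughly one random init in four reaches the good
basin; the SSA harness therefore uses 8 inits with an early-stop rule
(stop drawing inits once less than 5% of the response variance is
unexplained — only meaningful for noiseless targets).

Cross-validation uses interleaved folds over time bins (bin t in fold
`t mod k`, k = 10 by default); each fold fits on its complement and
predicts its held-out bins, and held-out predictions are concatenated in
time order.  Behavior-state fits are nested: a pooled state-independent
fit first, then only the designated groups (output NL; filter + NL; all)
are duplicated per state and refined from the pooled solution with the
remaining parameters frozen — so shared parameters are bit-identical
across states by construction.

## Evaluation

* **PSTH**: trial-mean counts / dt, no smoothing.
* **Noise-corrected correlation**: raw Pearson correlation between
  prediction and PSTH divided by a reliability ceiling,
  `sqrt(2 rhh / (1 + rhh))`, where `rhh` is the mean correlation between
  PSTHs of 100 random half-splits of trials (Spearman–Brown
  extrapolation of half-set reliability).  Other ceiling constructions
  exist; this one is documented and pluggable.  Fewer
  than 4 trials: raw correlation, flagged; non-positive `rhh`: flagged
  unpredictable.
* **Chance test**: the *prediction* is randomly permuted across time
  (1000 times by default), `p = (1 + #{r_shuf >= r}) / (n + 1)`, with
  optional Bonferroni multiplication by the number of models compared.
* **Jackknife model comparison**: correlations on 20 leave-one-subset-out
  interleaved time partitions; significant when the mean difference
  exceeds the sum of the two jackknife standard errors (≈ p < 0.05).
* **Population sign test**: exact two-sided binomial test on paired score
  differences with ties dropped; a Wilcoxon signed-rank variant is
  available since the two names are used interchangeably in the field.
* **Channel gain / E–I labels**: sum of temporal-filter coefficients per
  channel; the largest-gain channel is the excitatory reference and a
  negative smallest-gain channel the inhibitory reference.

## SSA analysis

Burst responses are PSTH integrals over each burst's presentation window
(onset to offset, 100 ms; a latency offset is configurable and 0 by
default since no response-window lag is specified for this analysis).
The SSA index `SI = (r_odd - r_std)/(r_odd + r_std)` pools bursts of both
bands within each role so band preference cancels — provided both
standard-band conditions are represented; the harnesses always generate
condition-balanced trial sets.  The shuffle null permutes role labels
within each band (preserving the 90/10 ratio and band preference),
two-sided.

## Synthetic data

* **Envelopes** emulate vocalization temporal statistics: Gaussian noise
  shaped by a power-law modulation filter (flat below 1 Hz), half-wave
  rectified, smoothed with a 20 ms boxcar, and rescaled to [0, 65].  The
  filter exponent is solved numerically (cached secant iteration against
  a fixed-internal-seed calibration ensemble) so the *measured* ensemble
  attenuation at 10 Hz relative to the 0.5–1 Hz plateau equals the 30 dB
  target after the nonlinear rectification step, which adds a broadband
  distortion floor worth ~3 dB.  Real vocalization envelopes additionally
  carry syllabic rhythm, harmonic structure and cross-channel comodulation
  that this generator does not emulate; passing tests show the pipeline
  recovers what it planted under matched modulation statistics, not that
  it would perform identically on recorded sounds.
* **Oddball sequences**: 20 s trials of 100 ms bursts at 5/s (100 ms
  inter-burst interval, matching the usual tuning-curve timing; both
  durations are parameters), each burst deviant with probability 0.1,
  standard band re-drawn per trial.
* **Spectrograms**: 18 channels mixing shared (groups of 3) and private
  vocalization-like envelopes 50/50, giving the spectral stage
  non-degenerate correlation structure.
* **Ground-truth neurons** have two channels: a strong excitatory channel
  with graded depression and (by default) a weaker inhibitory channel
  with weak depression.  Truth kernels are single-lobed (frequency
  15–35 rad/s over the 150 ms window) so kernel-sum channel gains are
  robustly signed.  Kernel gains are rescaled so the linear drive has
  unit sd (continuous stimuli) or peak 2 (sparse burst trains, whose sd
  normalization would park burst tops in the saturated tail of the
  sigmoid); the output sigmoid (A = 70 spikes/s peak) then yields mean
  evoked rates of ~20–40 spikes/s — a realistic cortical regime.
  Spiking is independent Poisson per bin; rates are clipped at 0 first.

## Experiment harnesses and problem sizes

* **Parameter recovery**: 20 neurons, `v ~ U(0.1, 0.6)`,
  `tau ~ U(0.03, 0.15)` s, 20 Poisson trials of 30 x 3 s two-band
  stimuli; LN and local-STP fits on interleaved 80% estimation blocks
  (0.5 s blocks), scored on the held-out 20%.  The local-STP fit is a
  candidate portfolio: stage-wise random inits, warm starts from the
  fitted LN solution (STP+NL accommodation then joint refinement), and
  an *axis-aligned* start (identity reweighting frozen first) — the
  reweighting stage has a channel-mixing gauge freedom that linear fits
  cannot resolve, but band-specific adaptation is only expressible in an
  unmixed gauge, so that gauge must be explicitly reachable.  Model
  comparison uses the lowest-cost candidate; parameter readout breaks
  ties within the cost's own standard error toward the smallest
  `||v||` (at weak adaptation the cost surface is nearly degenerate
  along a v/tau trade-off, where a fast strong synapse mimics the
  quasi-static compression of a slow weak one).  The estimated
  `v`/`tau` are read from the channel carrying the most consequential
  excitatory-band drive (positive normalized weight x kernel-gain
  magnitude).  Recovery quality: rank correlation(true v, estimated v)
  >= 0.8; `tau` within a factor of 2 for strongly adapting neurons.
* **Model selection**: 10 strongly adapting neurons
  (`v ~ U(0.35, 0.6)`, `tau ~ U(0.08, 0.15)` s, where adaptation carries
  enough response variance to be detectable at 20 trials) and 10 LN
  neurons; local STP must win the jackknife comparison for >= 8/10 of the
  former and <= 2/10 of the latter.  Detectability scales with
  `v * tau` (depth x slowness of adaptation): fast-recovering synapses
  act quasi-statically on these slow envelopes and are largely absorbed
  by the output nonlinearity, which is itself an instructive property of
  the architecture.
* **SSA**: 20 noiseless neurons with `v` graded over [0.1, 0.6] on *both*
  synapses and `tau` fixed at 100 ms (so SI orders with v), responding to
  2 condition-balanced oddball trials; LN is fit from up to 8 random
  inits plus a deterministic identity-weights start, and the STP
  architectures are warm-started from the LN solution (an STP+NL
  accommodation pass over v0 in {0.1, 0.3, 0.6}, then joint refinement
  of the two most promising starts).
* **Behavior**: 10 neurons, planted active-state gain x1.5, 20 trials
  per state; the NL-split model is compared with the pooled model by
  held-out MSE (Pearson correlation is invariant to a pure gain change,
  so error, not correlation, is the metric that can reveal the split's
  advantage).

The harness problem sizes (2 random inits with stage-wise starts instead
of 10, 150–300 L-BFGS-B iterations, 2-trial oddball sets) are the
package's chosen desk-scale defaults; all are plain `FitOptions` fields.

## Known limitations

* Numerical finite-difference gradients make fitting O(#params) predict
  calls per step; fine at rank 2–5, slow for large spectrogram models.
* The fit landscape for STP architectures is multimodal; the shipped
  warm-start and sign-canonicalization heuristics make desk-scale
  recovery reliable but are not global optimizers.
* The noise ceiling assumes exchangeable trials; slow drift across trials
  would bias it.
* `verbatim` STP mode is provided for comparison only; its gain leaks to
  0 under silence.
* The dataset container holds one stimulus per container; recorded
  archives with richer layouts are expected to go through a user-supplied
  adapter that returns a `DatasetContainer`.
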