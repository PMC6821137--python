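"""Behavior-state-dependent gain with stable adaptation.

One neuron is simulated in passive and active listening states whose only
difference is a 1.5x output gain.  A state-split output nonlinearity
(shared filters and short-term plasticity) recovers the gain change while
the adaptation parameters remain identical across states.
"""

import numpy as np

from stpstrf import FitOptions, fit_behavior_dependent
from stpstrf.evaluate import psth
from stpstrf.simulate import (_block_validation_mask, _model_skeleton,
                              ground_truth_model, make_vocmod_stimulus,
                              simulate_neuron)

stim = make_vocmod_stimulus(n_samples=10, seed=500)
rng = np.random.default_rng(0)
passive = ground_truth_model(rng, stim, v_exc=0.4, tau_exc=0.08)
active = passive.copy()
active.out_nl.amplitude *= 1.5

resp = {}
for state, truth, seed in (("passive", passive, 1), ("active", active, 2)):
    resp[state] = psth(simulate_neuron(truth, stim, n_trials=20, seed=seed))

mask = _block_validation_mask(stim.n_bins)
result = fit_behavior_dependent(_model_skeleton("localSTP"), stim, resp,
                                split_level="NL",
                                opts=FitOptions(n_random_inits=2,
                                                max_iterations=150, seed=0),
                                mask=mask)

amp = {s: result.state_models[s].out_nl.amplitude
       for s in ("passive", "active")}
ratio = amp["active"] / amp["passive"]
print(f"recovered output-gain ratio active/passive: {ratio:.2f} "
      "(planted 1.50)")
vp = result.state_models["passive"].stp.v
va = result.state_models["active"].stp.v
print(f"release probabilities passive {np.round(vp, 3)} vs active "
      f"{np.round(va, 3)} -> identical: {np.array_equal(vp, va)} "
      "(adaptation unaffected by behavioral state)")
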