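"""Fitting machinery: cost, initialization, descent and split hierarchies."""

import numpy as np
import pytest

from stpstrf.evaluate import _pearson
from stpstrf.fit import (FitOptions, ParameterMap, canonicalize_channel_signs,
                         crossval_fit, fit_behavior_dependent, fit_model,
                         initialize, refine, shrinkage_cost)
from stpstrf.model import predict
from stpstrf.simulate import (_block_validation_mask, _model_skeleton,
                              ground_truth_model)

FAST = FitOptions(n_random_inits=2, max_iterations=120, seed=0)


class TestShrinkageCost:
    def test_zero_iff_perfect(self, rng):
        x = rng.normal(size=100)
        assert shrinkage_cost(x, x) == 0.0
        assert shrinkage_cost(x, x + 0.1) > 0.0

    def test_homogeneous_errors_reduce_to_mse(self):
        pred = np.zeros(40)
        obs = np.full(40, 2.0)  # every subset has identical MSE of 4
        assert shrinkage_cost(pred, obs, n_jack=10) == pytest.approx(4.0)

    def test_dominates_plain_mse(self, rng):
        pred = rng.normal(size=200)
        obs = rng.normal(size=200)
        mse = np.mean((pred - obs) ** 2)
        assert shrinkage_cost(pred, obs, n_jack=10) >= mse

    def test_single_jackknife_is_plain_mse(self, rng):
        pred, obs = rng.normal(size=50), rng.normal(size=50)
        assert shrinkage_cost(pred, obs, n_jack=1) == pytest.approx(
            np.mean((pred - obs) ** 2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            shrinkage_cost(np.zeros(10), np.zeros(11))


class TestInitialize:
    def test_deterministic_given_seed(self):
        model = _model_skeleton("localSTP")
        resp = np.random.default_rng(0).uniform(0, 30, 100)
        a = ParameterMap(initialize(model, 42, resp)).get_vector()
        b = ParameterMap(initialize(model, 42, resp)).get_vector()
        c = ParameterMap(initialize(model, 43, resp)).get_vector()
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_stp_strength_starts_positive(self):
        for seed in range(5):
            m = initialize(_model_skeleton("localSTP"), seed)
            assert np.all(m.stp.v > 0)
            assert np.all(m.stp.tau > 0)

    def test_weight_columns_distinct(self):
        m = initialize(_model_skeleton("LN", rank=3, n_in=3), 0)
        w = m.weights.matrix()
        for a in range(3):
            for b in range(a + 1, 3):
                assert not np.allclose(w[:, a], w[:, b])


class TestParameterMap:
    def test_round_trip(self):
        m = initialize(_model_skeleton("localSTP"), 3)
        pmap = ParameterMap(m)
        theta = pmap.get_vector()
        pmap.set_vector(theta * 0 + 0.123)
        pmap.set_vector(theta)
        assert np.array_equal(pmap.get_vector(), theta)

    def test_scales_positive_and_aligned(self):
        pmap = ParameterMap(initialize(_model_skeleton("localSTP"), 0))
        scales = pmap.scales()
        assert len(scales) == len(pmap.get_vector())
        assert np.all(scales > 0)

    def test_group_restriction(self):
        m = initialize(_model_skeleton("localSTP"), 1)
        full = ParameterMap(m).get_vector()
        stp_only = ParameterMap(m, groups=("stp",)).get_vector()
        assert len(stp_only) == 4  # 2 channels x (v, tau)
        assert len(full) > len(stp_only)


class TestCanonicalizeChannelSigns:
    def test_prediction_invariant_and_drive_positive(self, rng):
        from stpstrf.simulate import make_vocmod_stimulus
        stim = make_vocmod_stimulus(2, seed=5)
        m = initialize(_model_skeleton("LN"), 7)
        m.weights.w[...] = -np.abs(m.weights.w)
        before = predict(m, stim)
        canonicalize_channel_signs(m)
        assert np.allclose(predict(m, stim), before)
        assert np.all(m.weights.w.sum(axis=0) >= 0)


@pytest.fixture(scope="module")
def ln_truth(short_stim):
    rng = np.random.default_rng(21)
    truth = ground_truth_model(rng, short_stim, architecture="LN")
    return truth, predict(truth, short_stim)


class TestFitModel:
    def test_noiseless_ln_recovery(self, short_stim, ln_truth):
        truth, resp = ln_truth
        mask = _block_validation_mask(short_stim.n_bins)
        fr = fit_model(_model_skeleton("LN"), short_stim, resp,
                       FitOptions(n_random_inits=3, max_iterations=250,
                                  seed=0, early_stop_frac=0.01), mask=mask)
        pred = predict(fr.model, short_stim)
        assert _pearson(pred[~mask], resp[~mask]) > 0.99

    def test_descent_property(self, short_stim, ln_truth):
        _, resp = ln_truth
        fr = fit_model(_model_skeleton("LN"), short_stim, resp, FAST)
        assert fr.cost_trace[-1] <= fr.cost_trace[0] + 1e-9
        assert fr.init_costs[fr.best_init] == min(fr.init_costs)

    def test_more_inits_never_worse(self, short_stim, ln_truth):
        # init seeds are a prefix-consistent stream, so the 3-init run
        # includes the 1-init run's starting point
        _, resp = ln_truth
        opts1 = FitOptions(n_random_inits=1, max_iterations=80, seed=5)
        opts3 = FitOptions(n_random_inits=3, max_iterations=80, seed=5)
        c1 = fit_model(_model_skeleton("localSTP"), short_stim, resp,
                       opts1)
        c3 = fit_model(_model_skeleton("localSTP"), short_stim, resp,
                       opts3)
        assert c3.init_costs[c3.best_init] <= c1.init_costs[c1.best_init]

    def test_nested_model_dominance_via_warm_refine(self, short_stim,
                                                    ln_truth):
        # localSTP contains LN as the v=0 slice: refining from the fitted
        # LN solution plus small v can only improve the estimation cost
        _, resp = ln_truth
        ln = fit_model(_model_skeleton("LN"), short_stim, resp, FAST)
        from stpstrf.simulate import _warm_from_ln
        warm = _warm_from_ln("localSTP", ln.model, 0.02)
        stp = refine(warm, short_stim, resp, FAST)
        assert stp.init_costs[0] <= ln.init_costs[ln.best_init] * 1.02

    def test_response_length_checked(self, short_stim):
        with pytest.raises(ValueError):
            fit_model(_model_skeleton("LN"), short_stim, np.zeros(10), FAST)


class TestCrossValFit:
    def test_partition_and_recovery(self, short_stim, ln_truth):
        _, resp = ln_truth
        opts = FitOptions(n_random_inits=3, max_iterations=250, seed=0,
                          cv_folds=4, early_stop_frac=0.01)
        cv = crossval_fit(_model_skeleton("LN"), short_stim, resp, opts)
        # every bin predicted exactly once, in time order
        assert not np.any(np.isnan(cv.validation_pred))
        assert len(cv.fold_results) == 4
        counts = np.bincount(cv.folds)
        assert counts.sum() == short_stim.n_bins
        assert _pearson(cv.validation_pred, resp) > 0.99


class TestBehaviorDependentFit:
    def test_none_split_matches_pooled_fit(self, short_stim, ln_truth):
        _, resp = ln_truth
        states = {"passive": resp, "active": resp}
        bres = fit_behavior_dependent(_model_skeleton("LN"), short_stim,
                                      states, split_level="none", opts=FAST)
        direct = fit_model(_model_skeleton("LN"), short_stim, resp, FAST)
        assert bres.base_result.init_costs == direct.init_costs

    def test_nl_split_shares_filters_bitwise(self, short_stim, ln_truth):
        _, resp = ln_truth
        states = {"passive": resp, "active": 1.5 * resp}
        bres = fit_behavior_dependent(_model_skeleton("localSTP"),
                                      short_stim, states, split_level="NL",
                                      opts=FAST)
        mp = bres.state_models["passive"]
        ma = bres.state_models["active"]
        assert np.array_equal(mp.weights.w, ma.weights.w)
        assert np.array_equal(mp.stp.v, ma.stp.v)
        assert np.array_equal(mp.stp.tau, ma.stp.tau)
        for fp, fa in zip(mp.filters, ma.filters):
            assert (fp.gain, fp.latency, fp.decay, fp.freq) == \
                (fa.gain, fa.latency, fa.decay, fa.freq)
        assert mp.out_nl.amplitude != ma.out_nl.amplitude

    def test_unknown_split_rejected(self, short_stim, ln_truth):
        _, resp = ln_truth
        with pytest.raises(ValueError):
            fit_behavior_dependent(_model_skeleton("LN"), short_stim,
                                   {"a": resp, "b": resp},
                                   split_level="bogus", opts=FAST)

    def test_single_state_rejected(self, short_stim, ln_truth):
        _, resp = ln_truth
        with pytest.raises(ValueError):
            fit_behavior_dependent(_model_skeleton("LN"), short_stim,
                                   {"a": resp}, split_level="NL", opts=FAST)
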