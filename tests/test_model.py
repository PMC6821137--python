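"""Model stages against brute-force oracles, plus composition identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stpstrf.model import (DampedOscillatorFilter, ModelSpec, OutputNL,
                           RectifierParams, SpectralWeights, STPParams,
                           do_kernel, fir_predict, global_stp, output_nl,
                           predict, rectify_local, reweight, stp_apply,
                           stp_gain)
from stpstrf.stimuli import StimulusMatrix

DT = 0.01


def _stim(values, dt=DT):
    return StimulusMatrix(np.asarray(values, float), dt=dt)


class TestReweight:
    def test_identity(self):
        stim = _stim(np.random.default_rng(0).uniform(0, 1, (3, 20)))
        out = reweight(stim, SpectralWeights(w=np.eye(3)))
        assert np.array_equal(out.values, stim.values)

    def test_channel_sum(self):
        stim = _stim([[1.0, 2.0], [3.0, 4.0]])
        out = reweight(stim, SpectralWeights(w=[[1.0], [1.0]]))
        assert np.array_equal(out.values, [[4.0, 6.0]])

    def test_matches_double_loop_oracle(self, rng):
        stim = _stim(rng.uniform(0, 2, (2, 30)))
        w = rng.normal(size=(2, 5))
        out = reweight(stim, SpectralWeights(w=w))
        oracle = np.zeros((5, 30))
        for j in range(5):
            for t in range(30):
                for i in range(2):
                    oracle[j, t] += w[i, j] * stim.values[i, t]
        assert np.allclose(out.values, oracle, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            reweight(_stim(np.ones((3, 4))), SpectralWeights(w=np.eye(2)))

    def test_gaussian_form_peaks_at_one(self):
        w = SpectralWeights(means=np.array([4.0, 9.0]),
                            sds=np.array([1.5, 2.0]), n_in=18)
        mat = w.matrix()
        assert mat.shape == (18, 2)
        assert np.allclose(mat.max(axis=0), 1.0)
        assert np.argmax(mat[:, 0]) == 4


class TestDampedOscillatorKernel:
    def test_zero_at_and_before_latency(self):
        f = DampedOscillatorFilter(gain=2.0, latency=0.05, decay=10, freq=40)
        k = do_kernel(f, DT)
        assert np.all(k[:6] == 0.0)  # lags 0..50 ms inclusive

    def test_sine_peak(self):
        f = DampedOscillatorFilter(gain=1.0, latency=0.0, decay=0.0,
                                   freq=np.pi / (2 * DT))
        k = do_kernel(f, DT)
        assert k[1] == pytest.approx(1.0)

    def test_kernel_length(self):
        f = DampedOscillatorFilter(n_lags=15)
        assert len(do_kernel(f, DT)) == 15


class TestFirPredict:
    def test_delta_kernel_is_identity(self):
        stim = _stim(np.random.default_rng(2).uniform(0, 1, (1, 50)))
        k = np.zeros((1, 15))
        k[0, 0] = 1.0
        assert np.allclose(fir_predict(stim, k), stim.values[0])

    def test_zero_kernel(self):
        stim = _stim(np.ones((2, 30)))
        assert np.all(fir_predict(stim, np.zeros((2, 10))) == 0)

    def test_matches_triple_loop_oracle(self, rng):
        stim = _stim(rng.uniform(0, 1, (3, 40)))
        kernels = rng.normal(size=(3, 10))
        out = fir_predict(stim, kernels)
        oracle = np.zeros(40)
        for t in range(40):
            for x in range(3):
                for u in range(10):
                    if t - u >= 0:
                        oracle[t] += kernels[x, u] * stim.values[x, t - u]
        assert np.allclose(out, oracle, atol=1e-12)

    def test_kernel_count_mismatch(self):
        with pytest.raises(ValueError):
            fir_predict(_stim(np.ones((2, 10))), np.zeros((3, 5)))


class TestStpGain:
    def test_zero_strength_is_identity_gain(self):
        d = stp_gain(np.random.default_rng(0).uniform(0, 5, 200), 0.0, 0.1,
                     DT)
        assert np.all(d == 1.0)

    def test_recovery_to_baseline_with_silent_drive(self):
        # depress first, then silence: gain must relax back toward 1
        drive = np.concatenate([np.full(100, 20.0), np.zeros(400)])
        d = stp_gain(drive, 0.5, 0.05, DT)
        # equilibrium under drive: (1/tau)/(1/tau + v*s) = 20/30
        assert d[100] == pytest.approx(2 / 3, abs=0.01)
        assert d[-1] == pytest.approx(1.0, abs=1e-3)

    def test_constant_drive_equilibrium(self):
        s, v, tau = 12.0, 0.4, 0.08
        d = stp_gain(np.full(3000, s), v, tau, DT)
        d_star = (1 / tau) / (1 / tau + v * s)
        assert d[-1] == pytest.approx(d_star, rel=1e-2)

    def test_verbatim_recursion_matches_printed_form(self, rng):
        drive = rng.uniform(0, 3, 50)
        v, tau = 0.2, 5.0  # tau in the printed recursion acts per step
        d = stp_gain(drive, v, tau, DT, mode="verbatim")
        expected = np.empty(50)
        expected[0] = 1.0
        for t in range(1, 50):
            expected[t] = (expected[t - 1]
                           + drive[t - 1] * (1 - expected[t - 1]) * v
                           - expected[t - 1] / tau)
            expected[t] = min(max(expected[t], 0.0), 5.0)
        assert np.allclose(d, expected, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(v=st.floats(0.01, 1.5), tau=st.floats(0.02, 0.5),
           seed=st.integers(0, 1000))
    def test_depression_gain_bounded(self, v, tau, seed):
        drive = np.random.default_rng(seed).uniform(0, 65, 300)
        d = stp_gain(drive, v, tau, DT)
        assert np.all(d <= 1.0) and np.all(d >= 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(v=st.floats(-1.5, -0.01), tau=st.floats(0.02, 0.5),
           seed=st.integers(0, 1000))
    def test_facilitation_gain_bounded(self, v, tau, seed):
        drive = np.random.default_rng(seed).uniform(0, 65, 300)
        d = stp_gain(drive, v, tau, DT, d_max=5.0)
        assert np.all(d >= 1.0) and np.all(d <= 5.0)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            stp_gain(np.ones(10), 0.1, 0.0, DT)


class TestStpApply:
    def test_zero_strength_identity(self):
        stim = _stim(np.random.default_rng(1).uniform(0, 5, (3, 50)))
        params = STPParams(v=np.zeros(3), tau=np.full(3, 0.1))
        out = stp_apply(stim, params)
        assert np.array_equal(out.values, stim.values)

    def test_sustained_pulse_decays(self):
        stim = _stim(np.full((1, 200), 30.0))
        out = stp_apply(stim, STPParams(v=[0.4], tau=[0.1]))
        assert np.all(np.diff(out.values[0]) <= 1e-12)
        assert out.values[0, -1] < out.values[0, 0]

    def test_channels_adapt_independently(self, rng):
        stim = _stim(rng.uniform(0, 10, (3, 80)))
        params = STPParams(v=np.array([0.1, 0.3, 0.5]),
                           tau=np.array([0.05, 0.1, 0.2]))
        out = stp_apply(stim, params)
        perm = [2, 0, 1]
        stim_p = _stim(stim.values[perm])
        params_p = STPParams(v=params.v[perm], tau=params.tau[perm])
        out_p = stp_apply(stim_p, params_p)
        assert np.array_equal(out_p.values, out.values[perm])

    def test_channel_count_mismatch(self):
        with pytest.raises(ValueError):
            stp_apply(_stim(np.ones((2, 10))),
                      STPParams(v=[0.1], tau=[0.1]))


class TestGlobalStp:
    def test_zero_strength(self):
        rL = np.random.default_rng(3).normal(size=100)
        assert np.array_equal(global_stp(rL, 0.0, 0.1, DT), rL)

    def test_nonpositive_drive_no_depletion(self):
        rL = -np.random.default_rng(4).uniform(0, 5, 100)
        assert np.allclose(global_stp(rL, 0.5, 0.1, DT), rL)

    def test_common_input_variant_with_identical_drives(self, rng):
        drive = rng.uniform(0, 10, 100)
        rL = rng.normal(size=100)
        single = stp_gain(drive, 0.3, 0.1, DT) * rL
        common = global_stp(rL, 0.3, 0.1, DT,
                            channel_drives=np.stack([drive, drive]))
        assert np.allclose(common, single)


class TestRectifyLocal:
    def test_zero_threshold_identity_on_nonnegative(self):
        stim = _stim(np.random.default_rng(5).uniform(0, 2, (2, 30)))
        out = rectify_local(stim, RectifierParams(s0=np.zeros(2)))
        assert np.array_equal(out.values, stim.values)

    def test_threshold_above_max_zeroes(self):
        stim = _stim(np.ones((1, 10)))
        out = rectify_local(stim, RectifierParams(s0=[5.0]))
        assert np.all(out.values == 0)

    def test_simple_value(self):
        out = rectify_local(_stim([[2.0]]), RectifierParams(s0=[0.5]))
        assert out.values[0, 0] == 1.5


class TestOutputNL:
    def test_dexp_at_inflection(self):
        nl = OutputNL(kind="dexp", base=3.0, amplitude=10.0, slope=-2.0)
        assert output_nl(np.array([3.0]), nl)[0] == pytest.approx(
            3.0 + 10.0 / np.e)

    def test_logistic_at_midpoint(self):
        nl = OutputNL(kind="logistic", base=1.0, amplitude=8.0, slope=0.5,
                      rate_offset=2.0)
        assert output_nl(np.array([1.0]), nl)[0] == pytest.approx(2.0 + 4.0)

    def test_linear_passthrough(self):
        x = np.linspace(-3, 3, 7)
        assert np.array_equal(output_nl(x, OutputNL(kind="linear")), x)

    def test_relu(self):
        nl = OutputNL(kind="relu", base=1.0, rate_offset=0.5)
        assert np.allclose(output_nl(np.array([0.0, 2.0]), nl), [0.5, 1.5])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            OutputNL(kind="softplus")

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(slope=st.floats(-3, 3).filter(lambda s: abs(s) > 1e-3))
    def test_dexp_monotone_direction_set_by_slope_sign(self, slope):
        nl = OutputNL(kind="dexp", base=0.0, amplitude=5.0, slope=slope)
        y = output_nl(np.linspace(-4, 4, 50), nl)
        diffs = np.diff(y)
        if slope < 0:
            assert np.all(diffs >= -1e-12)
        else:
            assert np.all(diffs <= 1e-12)


def _make_localstp_model(rng, rank=2, n_in=2):
    w = rng.normal(size=(n_in, rank))
    filters = [DampedOscillatorFilter(gain=rng.uniform(0.5, 1.5),
                                      latency=rng.uniform(0, 0.03),
                                      decay=rng.uniform(10, 40),
                                      freq=rng.uniform(20, 60))
               for _ in range(rank)]
    return ModelSpec(architecture="localSTP",
                     weights=SpectralWeights(w=w), filters=filters,
                     stp=STPParams(v=rng.uniform(0.1, 0.5, rank),
                                   tau=rng.uniform(0.05, 0.15, rank)),
                     out_nl=OutputNL(kind="dexp", base=1.0, amplitude=30.0,
                                     slope=-1.5),
                     compress=True, dt=DT)


class TestPredict:
    def test_localstp_with_zero_v_equals_ln_bitwise(self, rng):
        stim = _stim(rng.uniform(0, 65, (2, 200)))
        stp_model = _make_localstp_model(rng)
        stp_model.stp.v[...] = 0.0
        ln_model = ModelSpec(architecture="LN", weights=stp_model.weights,
                             filters=stp_model.filters,
                             out_nl=stp_model.out_nl, compress=True, dt=DT)
        assert np.array_equal(predict(stp_model, stim),
                              predict(ln_model, stim))

    def test_zero_stimulus_constant_rate(self, rng):
        model = _make_localstp_model(rng)
        rate = predict(model, _stim(np.zeros((2, 100))))
        expected = output_nl(np.zeros(1), model.out_nl)[0]
        assert np.allclose(rate, expected)

    def test_matches_stage_by_stage_oracle(self, rng):
        stim = _stim(rng.uniform(0, 65, (2, 150)))
        model = _make_localstp_model(rng)
        # independent composition with explicit loops
        x = np.log1p(stim.values)
        w = model.weights.matrix()
        sR = w.T @ x
        adapted = np.empty_like(sR)
        for j in range(sR.shape[0]):
            v, tau = model.stp.v[j], model.stp.tau[j]
            d = np.empty(sR.shape[1])
            d[0] = 1.0
            for t in range(1, sR.shape[1]):
                u = max(sR[j, t - 1], 0.0)
                d[t] = d[t - 1] + DT * ((1 - d[t - 1]) / tau
                                        - v * u * d[t - 1])
                d[t] = min(max(d[t], 0.0), 5.0)
            adapted[j] = d * sR[j]
        rL = np.zeros(sR.shape[1])
        for j, f in enumerate(model.filters):
            k = do_kernel(f, DT)
            for t in range(len(rL)):
                for u in range(len(k)):
                    if t - u >= 0:
                        rL[t] += k[u] * adapted[j, t - u]
        oracle = output_nl(rL, model.out_nl)
        assert np.allclose(predict(model, stim), oracle, atol=1e-10)

    def test_causality_under_truncation(self, rng):
        stim = _stim(rng.uniform(0, 65, (2, 300)))
        model = _make_localstp_model(rng)
        full = predict(model, stim)
        trunc = predict(model, _stim(stim.values[:, :180]))
        assert np.allclose(trunc, full[:180])

    def test_channel_mismatch_rejected(self, rng):
        model = _make_localstp_model(rng)
        with pytest.raises(ValueError):
            predict(model, _stim(np.ones((3, 50))))

    def test_spec_validation(self, rng):
        with pytest.raises(ValueError):
            ModelSpec(architecture="localSTP",
                      weights=SpectralWeights(w=np.eye(2)),
                      filters=[DampedOscillatorFilter(),
                               DampedOscillatorFilter()],
                      out_nl=OutputNL(),
                      stp=STPParams(v=[0.1], tau=[0.1]))  # rank mismatch
        with pytest.raises(ValueError):
            ModelSpec(architecture="bogus",
                      weights=SpectralWeights(w=np.eye(2)),
                      filters=[DampedOscillatorFilter(),
                               DampedOscillatorFilter()],
                      out_nl=OutputNL())
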