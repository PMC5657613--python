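"""The damage ODE: right-hand side, integration, conservation, readouts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msdamage import (
    ModelParams,
    ModelState,
    bv_readout,
    derivatives,
    edss_readout,
    quantize_edss,
    simulate,
    simulate_batch,
)
from msdamage.calibration import derive_scaling


class TestDerivatives:
    def test_healthy_state_is_fixed_point(self):
        s = ModelState(am=1.0, ad=0.0, m=1.0, d=0.0)
        p = ModelParams(km=3.0, kmd=0.0, kd=0.2, q=0.5, delta=0.3)
        d = derivatives(s, p, lam=0.0)
        assert (d.am, d.ad, d.m, d.d) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_evaluated_rhs(self):
        s = ModelState(am=0.8, ad=0.1, m=0.9, d=0.1)
        p = ModelParams(km=1.0, kmd=0.001, kd=0.01, q=0.5, delta=0.1)
        d = derivatives(s, p, lam=0.02)
        assert d.am == pytest.approx(0.0732, abs=1e-12)

    def test_negative_inputs_rejected(self):
        s = ModelState(am=0.5, ad=0.1, m=1.0, d=0.0)
        p = ModelParams(1, 0.001, 0.01, 0.5, 0.1)
        with pytest.raises(ValueError):
            derivatives(s, p, lam=-0.1)

    @given(
        st.tuples(*[st.floats(0, 2) for _ in range(4)]),
        st.tuples(
            st.floats(0, 10),
            st.floats(0, 0.01),
            st.floats(0, 1),
            st.floats(0, 1),
            st.floats(0, 1),
        ),
        st.floats(0, 0.5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_volume_is_conserved_algebraically(self, state, params, lam):
        s = ModelState(*state)
        p = ModelParams(*params)
        d = derivatives(s, p, lam)
        assert d.am + d.ad + d.d == pytest.approx(0.0, abs=1e-12)


class TestSimulate:
    def test_all_rates_zero_gives_constant_trajectory(self):
        t = np.arange(0, 1000.0, 10.0)
        traj = simulate(
            ModelParams(0, 0, 0, 0.5, 0), None, ModelState.healthy(), t, step=1.0
        )
        assert np.all(traj.am == 1.0) and np.all(traj.d == 0.0)

    def test_matches_closed_form_exponential_decay(self):
        # lam=0, km=kd=0: dAm/dt = -kmd*Am has the exact solution
        # Am(t) = exp(-kmd t), D = 1 - Am
        t = np.arange(0, 3650.1, 10.0)
        traj = simulate(
            ModelParams(0, 0.001, 0, 0.5, 0), None, ModelState.healthy(), t, step=0.1
        )
        assert np.max(np.abs(traj.am - np.exp(-0.001 * t))) < 1e-6
        assert np.max(np.abs(traj.d - (1 - np.exp(-0.001 * t)))) < 1e-6

    def test_conservation_under_pulsed_forcing(self, rng):
        from msdamage import archetype_presets, build_lambda, sample_pulse_train

        a = archetype_presets()["SPMS"]
        train = sample_pulse_train(
            a.interval_distribution(), a.amplitude_sampler(), 7300.0, rng,
            amp_scale=a.amp_scale,
        )
        assert train.n_events >= 5
        t = np.arange(0, 7300.1, 10.0)
        traj = simulate(
            ModelParams(1, 0.0005, 0.05, 0.5, 0.3), build_lambda(train),
            ModelState.healthy(0.9), t, step=0.1,
        )
        assert traj.conservation_drift() < 1e-8
        assert np.all(np.diff(traj.d) >= -1e-15)  # D never decreases

    def test_step_halving_converges(self):
        t = np.arange(0, 3650.1, 50.0)
        p = ModelParams(0.05, 1e-4, 0.05, 0.5, 0.02)
        lam = lambda tt: np.full_like(np.asarray(tt, float), 0.002)
        s1 = simulate(p, lam, ModelState.healthy(0.9), t, step=0.2)
        s2 = simulate(p, lam, ModelState.healthy(0.9), t, step=0.1)
        final_diff = np.max(
            np.abs(
                np.array([s1.am[-1], s1.ad[-1], s1.m[-1], s1.d[-1]])
                - np.array([s2.am[-1], s2.ad[-1], s2.m[-1], s2.d[-1]])
            )
        )
        assert final_diff < 1e-6

    def test_edss_bounded_by_initial_volume(self):
        t = np.arange(0, 7300.1, 10.0)
        lam = lambda tt: np.full_like(np.asarray(tt, float), 0.01)
        traj = simulate(
            ModelParams(0.02, 1e-4, 0.1, 0.5, 0.01), lam, ModelState.healthy(0.9), t,
            step=0.5,
        )
        assert np.all(traj.edss_s <= 0.9 + 1e-9)

    def test_divergence_raises_with_time(self):
        t = np.arange(0, 2000.0, 10.0)
        lam = lambda tt: np.full_like(np.asarray(tt, float), 0.5)
        with pytest.raises(FloatingPointError, match="diverged near t="):
            simulate(
                ModelParams(100.0, 0.01, 1.0, 0.0, 1.0), lam,
                ModelState.healthy(), t, step=10.0, max_refine=1,
            )

    def test_step_exceeding_grid_spacing_rejected(self):
        with pytest.raises(ValueError, match="grid spacing"):
            simulate(
                ModelParams(0, 0, 0, 0.5, 0), None, ModelState.healthy(),
                np.array([0.0, 1.0, 2.0]), step=5.0,
            )

    def test_batch_agrees_with_single(self):
        t = np.arange(0, 365.1, 5.0)
        lam = lambda tt: np.where(np.asarray(tt) < 30, 0.01, 0.0)
        params = np.array([[0.05, 1e-4, 0.05, 0.5, 0.02], [0.01, 2e-4, 0.1, 0.3, 0.01]])
        batch = simulate_batch(params, lam, np.array([0.9, 0, 1, 0]), t, step=0.5)
        for i in range(2):
            single = simulate(
                ModelParams.from_array(params[i]), lam, ModelState.healthy(0.9), t,
                step=0.5,
            )
            assert np.allclose(batch[i, :, 0], single.am, atol=1e-12)


class TestReadouts:
    def test_edss_scaling_example(self):
        t = np.array([0.0, 1.0])
        traj = simulate(ModelParams(0, 0, 0, 0.5, 0), None, ModelState.healthy(), t, 1.0)
        traj.ad = np.array([0.2, 0.2])
        traj.d = np.array([0.05, 0.05])
        calib = derive_scaling(bi=-0.05, ci=1.2, ami0=0.9)
        edss = edss_readout(traj, calib)
        assert edss[0] == pytest.approx(10 / 0.9 * 0.2, rel=1e-12)  # 2.2222...
        assert edss_readout(traj, calib, quantize=True)[0] == 2.0

    def test_healthy_trajectory_reads_zero(self):
        t = np.arange(0, 100.0, 10.0)
        traj = simulate(ModelParams(0, 0, 0, 0.5, 0), None, ModelState.healthy(), t, 1.0)
        calib = derive_scaling(-0.05, 1.2, 0.9)
        assert np.all(edss_readout(traj, calib) == 0.0)

    def test_bv_constant_when_kbi_zero(self):
        t = np.arange(0, 100.0, 10.0)
        traj = simulate(
            ModelParams(0, 1e-3, 0, 0.5, 0), None, ModelState.healthy(), t, 1.0
        )
        with pytest.warns(UserWarning):
            calib = derive_scaling(bi=0.0, ci=1.2, ami0=0.9)
        assert np.allclose(bv_readout(traj, calib), calib.vdi)

    def test_bv_nonincreasing_without_remyelination(self, rng):
        from msdamage import build_lambda, PulseTrain

        train = PulseTrain(
            event_times=np.arange(100.0, 3000.0, 400.0),
            amplitudes=np.full(8, 0.005),
        )
        t = np.arange(0, 3000.1, 10.0)
        traj = simulate(
            ModelParams(km=0.0, kmd=1e-4, kd=0.05, q=0.5, delta=0.01),
            build_lambda(train), ModelState.healthy(0.9), t, step=0.5,
        )
        bv = bv_readout(traj, derive_scaling(-0.05, 1.2, 0.9))
        assert np.all(np.diff(bv) <= 1e-12)

    @given(st.floats(0, 12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_quantization_lands_on_half_grid(self, x):
        q = quantize_edss(x)
        assert 0 <= q <= 10
        assert q * 2 == int(q * 2)

    def test_quantization_ties_go_up(self):
        assert quantize_edss(2.25) == 2.5
        assert quantize_edss(2.2222) == 2.0
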