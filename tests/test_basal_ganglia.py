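"""Value computation, dopamine gating, and the STN-GPe oscillator lattice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgreach import basal_ganglia as bgm


class TestValue:
    def test_value_at_target_and_sigma_point(self):
        t = np.array([0.3, 0.35])
        assert np.isclose(bgm.compute_value(t, t, 0.8), 1.0)
        off = t + np.array([0.8, 0.0])
        assert np.isclose(bgm.compute_value(off, t, 0.8), np.exp(-1.0))

    @given(x=st.floats(-1, 1), y=st.floats(-1, 1))
    @settings(max_examples=30, deadline=None)
    def test_value_matches_formula(self, x, y):
        t = np.zeros(2)
        p = np.array([x, y])
        expected = np.exp(-(x * x + y * y) / 0.64)
        assert np.isclose(bgm.compute_value(p, t, 0.8), expected)

    def test_value_difference(self):
        assert bgm.value_difference(1.0, 0.5) == 0.5
        assert bgm.value_difference(0.3, 0.3) == 0.0


class TestGating:
    def test_midpoint_and_saturation(self):
        g = bgm.MSNGating(a_D1=30.0, theta_D1=0.02, theta_D2=0.02)
        l1, l2 = bgm.msn_gating(0.02, g)
        assert np.isclose(l1, 0.5) and np.isclose(l2, 0.5)
        l1, l2 = bgm.msn_gating(5.0, g)
        assert l1 > 0.999 and l2 < 0.001

    @given(delta=st.floats(-1, 1), theta=st.floats(-0.2, 0.2))
    @settings(max_examples=50, deadline=None)
    def test_complementarity_identity(self, delta, theta):
        """With equal thresholds and opposite gains the two gating values
        always sum to one."""
        g = bgm.MSNGating(a_D1=40.0, theta_D1=theta, theta_D2=theta)
        l1, l2 = bgm.msn_gating(delta, g)
        assert np.isclose(l1 + l2, 1.0, atol=1e-12)

    def test_direct_share_monotone_in_dopamine_signal(self):
        g = bgm.MSNGating(a_D1=30.0)
        lams = [bgm.msn_gating(d, g)[0] for d in np.linspace(-0.3, 0.3, 21)]
        assert np.all(np.diff(lams) > 0)


class TestStriatum:
    def test_zero_gating_and_rectification(self):
        x = np.array([[1.0, -2.0], [0.5, -0.1]])
        y1, y2 = bgm.striatal_outputs(x, 0.0, 1.0)
        assert np.allclose(y1, 0.0)
        assert np.allclose(y2, np.maximum(x, 0.0))

    def test_gain_and_saturation(self):
        x = np.array([[2.0]])
        y1, _ = bgm.striatal_outputs(x, 1.0, 0.0, gain_d1=3.0, y_sat=1.0)
        assert np.isclose(y1[0, 0], np.tanh(6.0))  # saturated near 1
        y1u, _ = bgm.striatal_outputs(x, 1.0, 0.0, gain_d1=3.0)
        assert np.isclose(y1u[0, 0], 6.0)


class TestSTNGPe:
    def test_zero_fixed_point(self):
        net = bgm.STNGPeNetwork(N=4, noise_amp=0.0, seed=0)
        net.x_GPe[:] = 0.0
        net.x_STN[:] = 0.0
        bgm.run_stn_gpe_window(net, np.zeros(16), 0.02, 500)
        assert np.allclose(net.x_GPe, 0.0) and np.allclose(net.x_STN, 0.0)

    def test_tanh_bound(self):
        net = bgm.STNGPeNetwork(N=4, eps_s=2.0, noise_amp=0.3, seed=1)
        tr = bgm.run_stn_gpe_window(net, 0.3 * np.ones(16), 0.02, 5000,
                                    record_every=10)
        assert np.all(np.abs(tr) < 1.0)

    def test_single_unit_period_matches_fine_step_oracle(self):
        """A 1x1 network with self-excitation sustains a limit cycle whose
        period agrees with a 100x finer integration within 2%."""

        def period(dt):
            net = bgm.STNGPeNetwork(
                N=1, eps_s=1.2, w_sg=2.5, w_gs=2.5, lambda_STN=3.0,
                tau_GPe=20.0, tau_STN=10.0, tau_jitter=0.0,
                noise_amp=0.0, self_excitation=True, seed=0,
            )
            net.x_GPe[:] = 0.1
            net.x_STN[:] = 0.1
            n_settle = int(200.0 / dt)
            bgm.run_stn_gpe_window(net, np.zeros(1), dt, n_settle)
            n_run = int(400.0 / dt)
            rec = max(int(0.05 / dt), 1)
            tr = bgm.run_stn_gpe_window(net, np.zeros(1), dt, n_run,
                                        record_every=rec)[0]
            ups = np.flatnonzero((tr[1:] > 0) & (tr[:-1] <= 0))
            assert ups.size >= 3, "no sustained oscillation"
            return np.mean(np.diff(ups)) * rec * dt

        p_coarse = period(0.02)
        p_fine = period(0.0002)
        assert abs(p_coarse - p_fine) / p_fine < 0.02

    def test_numpy_and_numba_windows_agree(self):
        import bgreach._fastpath as fp

        if not fp.HAVE_NUMBA:
            pytest.skip("numba unavailable")
        n1 = bgm.STNGPeNetwork(N=4, eps_s=0.5, noise_amp=0.2, seed=7)
        n2 = bgm.STNGPeNetwork(N=4, eps_s=0.5, noise_amp=0.2, seed=7)
        u = 0.1 * np.ones(16)
        r1 = bgm.run_stn_gpe_window(n1, u, 0.02, 1000, record_every=20)
        fp.HAVE_NUMBA = False
        try:
            r2 = bgm.run_stn_gpe_window(n2, u, 0.02, 1000, record_every=20)
        finally:
            fp.HAVE_NUMBA = True
        assert np.allclose(n1.x_STN, n2.x_STN, atol=1e-12)
        assert np.allclose(r1, r2, atol=1e-12)


class TestSynchronyCurve:
    def test_deterministic_under_seed(self):
        eps = np.array([0.3, 1.0])
        s1 = bgm.synchrony_vs_coupling_curve(eps, duration_ms=300.0, seed=4,
                                             noise_amp=0.15)
        s2 = bgm.synchrony_vs_coupling_curve(eps, duration_ms=300.0, seed=4,
                                             noise_amp=0.15)
        assert np.array_equal(s1, s2)

    def test_synchrony_increases_with_coupling(self, cfg):
        s = cfg.bg.stn
        curve = bgm.synchrony_vs_coupling_curve(
            np.array([cfg.eps.eps_map.eps_lo, cfg.eps.eps_map.eps_hi]),
            duration_ms=800.0, seed=0, tau_GPe=s.tau_GPe, tau_STN=s.tau_STN,
            w_sg=s.w_sg, w_gs=s.w_gs, lambda_STN=s.lambda_STN,
            sigma_lat_g=s.sigma_lat_g, sigma_lat_s=s.sigma_lat_s,
            tau_jitter=s.tau_jitter, noise_amp=s.noise_amp,
        )
        assert curve[1] > curve[0]
        assert curve[0] < 0.1 and curve[1] > 0.8

    def test_zero_duration_invalid(self):
        with pytest.raises(ValueError):
            bgm.synchrony_vs_coupling_curve(np.array([1.0]), duration_ms=0.0)


class TestGPi:
    def test_linear_combination(self):
        rng = np.random.default_rng(0)
        d1, stn = rng.random((2, 5, 5))
        assert np.allclose(bgm.gpi_combine(d1, np.zeros_like(stn), 2.0, 1.0),
                           2.0 * d1)
        assert np.allclose(bgm.gpi_combine(np.zeros_like(d1), stn, 2.0, 1.5),
                           -1.5 * stn)
        assert np.allclose(bgm.gpi_combine(d1, stn, 0.7, 0.3),
                           0.7 * d1 - 0.3 * stn)
        with pytest.raises(ValueError):
            bgm.gpi_combine(d1, np.zeros((2, 2)), 1.0, 1.0)
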