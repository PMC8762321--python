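"""Biophysical SNc soma, terminal dopamine turnover, and the pooled
 dopamine read-out."""

import numpy as np
import pytest
from scipy.optimize import brentq

from bgreach import snc_dopamine as snc

P = snc.SNcParams()


def _settled(n=16, seed=3, windows=10, ig=None):
    net = snc.make_network(n, P, seed=seed)
    i0 = snc.gaba_current_from_delta_v(0.0, P) if ig is None else ig
    for _ in range(windows):
        snc.run_snc_window(net, P, i0)
    return net


class TestGabaMap:
    def test_midpoint_anchor(self):
        assert np.isclose(snc.gaba_current_from_delta_v(0.0, P),
                          P.I_gaba_max / 2)

    def test_saturations(self):
        assert snc.gaba_current_from_delta_v(10.0, P) < 1e-6
        assert np.isclose(snc.gaba_current_from_delta_v(-10.0, P), P.I_gaba_max)

    def test_monotone_decreasing(self):
        grid = np.linspace(-0.3, 0.3, 41)
        vals = [snc.gaba_current_from_delta_v(d, P) for d in grid]
        assert np.all(np.diff(vals) < 0)


class TestSoma:
    def test_dead_neuron_clamped(self):
        net = snc.make_network(4, P, seed=0)
        net.alive[:2] = False
        for _ in range(200):
            snc.soma_step(net, P, 10.0, 0.025)
        assert np.all(net.V[:2] == snc.V_DEAD)
        assert np.all(net.Ca[:2] == 0.0)
        assert np.all(net.V[2:] != snc.V_DEAD)

    def test_autonomous_pacemaking_regular(self):
        """Without synaptic input the soma fires a regular rhythm (cycle
        periods constant within 5%)."""
        net = snc.make_network(1, P, seed=1, jitter=0.0)
        vs = []
        for i in range(120000):  # 3 s
            snc.soma_step(net, P, 0.0, 0.025)
            if i % 20 == 0:
                vs.append(net.V[0])
        vs = np.array(vs[len(vs) // 3:])
        ups = np.flatnonzero((vs[1:] > 0) & (vs[:-1] <= 0))
        assert ups.size >= 5
        periods = np.diff(ups)
        assert periods.std() / periods.mean() < 0.05

    def test_inhibition_lowers_calcium(self):
        free = _settled(8, windows=20, ig=0.0)
        inhib = _settled(8, windows=20, ig=P.I_gaba_max)
        assert inhib.Ca.mean() < free.Ca.mean()


class TestReleaseAndSynthesis:
    def test_release_probability_hill_points(self):
        assert snc.release_probability(np.array([0.0]), 0.3)[0] == 0.0
        assert np.isclose(snc.release_probability(np.array([0.3]), 0.3)[0], 0.5)
        assert np.isclose(snc.release_probability(np.array([0.6]), 0.3)[0],
                          16.0 / 17.0)

    def test_release_flux_product(self):
        assert snc.dopamine_release_flux(1.0, np.array([10.0]),
                                         np.array([0.5]))[0] == 5.0
        assert snc.dopamine_release_flux(3.0, np.array([2.0]),
                                         np.array([0.0]))[0] == 0.0

    def test_synthesis_velocity_hill_points(self):
        assert snc.synthesis_velocity(np.array([0.0]), P)[0] == 0.0
        assert np.isclose(snc.synthesis_velocity(np.array([P.K_synt]), P)[0],
                          P.V_synt_max / 2)
        assert np.isclose(snc.synthesis_velocity(np.array([2 * P.K_synt]), P)[0],
                          P.V_synt_max * 16 / 17)

    def test_synthesis_flux_substrate_and_inhibition(self):
        v = np.array([0.01])
        zero = np.zeros(1)
        # huge substrate removes the inhibition factor entirely
        sat = snc.synthesis_flux(v, zero, zero, P, TYR=1e12)
        assert np.isclose(sat[0], 0.01, rtol=1e-6)
        # substrate at its half constant with no dopamine: exactly half
        half = snc.synthesis_flux(v, zero, zero, P, TYR=P.K_TYR)
        assert np.isclose(half[0], 0.005)
        # autoreceptors: flux decreases as extracellular dopamine rises
        j = [snc.synthesis_flux(v, zero, np.array([d]), P)[0]
             for d in (0.0, 100.0, 400.0)]
        assert j[0] > j[1] > j[2]
        with pytest.raises(ValueError):
            snc.synthesis_flux(v, zero, zero, P, TYR=0.0)


class TestExtracellularDA:
    def test_zero_release_stays_zero(self):
        da = snc.extracellular_da_step(np.zeros(3), np.zeros(3), P, 0.25)
        assert np.all(da == 0.0)

    def test_steady_state_matches_root_finding_oracle(self):
        j_rel = 2.0  # nM/ms constant release
        da = np.array([10.0])
        for _ in range(40000):
            da = snc.extracellular_da_step(da, np.array([j_rel]), P, 0.25)
        root = brentq(
            lambda d: j_rel - P.V_DAT * d / (P.K_DAT + d) - P.k_edao * d,
            1e-6, 1e5)
        assert np.isclose(da[0], root, rtol=1e-3)

    def test_stronger_uptake_lowers_steady_state(self):
        from dataclasses import replace

        fast = replace(P, V_DAT=2 * P.V_DAT)
        da1, da2 = np.array([10.0]), np.array([10.0])
        for _ in range(20000):
            da1 = snc.extracellular_da_step(da1, np.array([2.0]), P, 0.25)
            da2 = snc.extracellular_da_step(da2, np.array([2.0]), fast, 0.25)
        assert da2[0] < da1[0]


class TestPooling:
    def test_all_dead_pool_is_zero(self):
        net = snc.make_network(8, P, seed=0)
        net.alive[:] = False
        for arr in (net.DA_e,):
            arr[:] = 0.0
        assert snc.pooled_dopamine(net) == 0.0

    def test_pool_scales_linearly_with_survival(self):
        net = snc.make_network(8, P, seed=0)
        net.DA_e[:] = 100.0
        full = snc.pooled_dopamine(net)
        net.alive[4:] = False
        net.DA_e[4:] = 0.0
        assert np.isclose(snc.pooled_dopamine(net), full / 2)

    def test_window_runner_silences_dead_terminals(self):
        net = _settled(8)
        net.alive[:] = False
        da = snc.run_snc_window(net, P, 10.0)
        assert da == 0.0
        assert np.all(net.DA_e == 0.0)


class TestReadout:
    def test_affine_map_and_floor(self):
        cal = snc.DACalibration(gain=0.001, offset=100.0,
                                delta_min=-0.12, delta_max=0.5)
        assert np.isclose(snc.delta_v_from_dopamine(150.0, cal), 0.05)
        assert snc.delta_v_from_dopamine(0.0, cal) == -0.1
        deep = snc.DACalibration(gain=0.01, offset=100.0, delta_min=-0.12)
        assert snc.delta_v_from_dopamine(0.0, deep) == -0.12  # clipped floor

    def test_monotone_increasing(self):
        cal = snc.DACalibration(gain=0.0009, offset=130.0)
        vals = [snc.delta_v_from_dopamine(d, cal) for d in np.linspace(0, 400, 30)]
        assert np.all(np.diff(vals) >= 0)


def test_numpy_and_numba_snc_windows_agree():
    import bgreach._fastpath as fp

    if not fp.HAVE_NUMBA:
        pytest.skip("numba unavailable")
    n1 = snc.make_network(8, P, seed=5)
    n2 = n1.copy()
    ig = snc.gaba_current_from_delta_v(0.05, P)
    da1 = snc.run_snc_window(n1, P, ig, n_steps=400, plasma_ldopa=2.0)
    da2 = snc.run_snc_window(n2, P, ig, n_steps=400, plasma_ldopa=2.0,
                             use_fastpath=False)
    assert np.isclose(da1, da2, atol=1e-10)
    assert np.allclose(n1.V, n2.V, atol=1e-10)
    assert np.allclose(n1.DA_e, n2.DA_e, atol=1e-10)
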