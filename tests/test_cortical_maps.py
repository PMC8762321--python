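"""SOM response and training, CANN dynamics, and the inter-map projections."""

import numpy as np
import pytest

from bgreach import cortical_maps as cm


def _som(N=6, dim=2, sigma=1.0, seed=0):
    rng = np.random.default_rng(seed)
    return cm.SOMNetwork(W=rng.random((N, N, dim)), sigma_resp=sigma)


class TestSOMActivation:
    def test_zero_distance_gives_unit_activation(self):
        som = _som()
        x = som.W[3, 3]
        assert np.isclose(cm.som_activation(x, som)[3, 3], 1.0)

    def test_unit_distance_gives_inverse_e(self):
        som = cm.SOMNetwork(W=np.zeros((3, 3, 1)), sigma_resp=2.0)
        u = cm.som_activation(np.array([2.0]), som)  # ||x-W||^2 == sigma^2
        assert np.allclose(u, np.exp(-1.0))

    def test_matches_elementwise_gaussian(self):
        som = _som(seed=3)
        x = np.array([0.2, 0.7])
        expected = np.exp(-((som.W - x) ** 2).sum(axis=2) / som.sigma_resp**2)
        assert np.allclose(cm.som_activation(x, som), expected)
        assert np.all(cm.som_activation(x, som) > 0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            cm.som_activation(np.array([1.0, 2.0, 3.0]), _som(dim=2))


class TestSOMTraining:
    def test_single_sample_collapses_all_weights(self):
        som = _som(N=5)
        target = np.array([0.4, 0.6])
        trained = cm.train_som(som, np.tile(target, (50, 1)), n_epochs=40, seed=1)
        assert np.max(np.abs(trained.W - target)) < 0.05

    def test_quantization_error_decreases(self):
        rng = np.random.default_rng(7)
        samples = rng.random((1000, 2))
        som = cm.SOMNetwork(W=rng.random((10, 10, 2)), sigma_resp=0.2)
        qe0 = cm.quantization_error(som, samples)
        done = cm.train_som(som, samples, n_epochs=10, seed=2)
        qe2 = cm.quantization_error(done, samples)
        more = cm.train_som(done, samples, n_epochs=10, seed=3)
        qe3 = cm.quantization_error(more, samples)
        assert qe2 < qe0 and qe3 <= qe2

    def test_topology_preserved(self):
        rng = np.random.default_rng(7)
        samples = rng.random((800, 2))
        som = cm.train_som(cm.SOMNetwork(W=rng.random((8, 8, 2)),
                                         sigma_resp=0.2), samples,
                           n_epochs=8, seed=2)
        # neighbouring nodes end closer in feature space than random pairs
        neigh = np.linalg.norm(np.diff(som.W, axis=0), axis=2).mean()
        flat = som.W.reshape(-1, 2)
        far = np.linalg.norm(flat[None, :, :] - flat[:, None, :], axis=2).mean()
        assert neigh < far

    def test_empty_samples_raise(self):
        with pytest.raises(ValueError):
            cm.train_som(_som(), np.empty((0, 2)))


class TestKernels:
    def test_excite_inhibit_centre_and_asymptote(self):
        k = cm.make_gaussian_kernel(15, A=1.3, sigma=1.0, K=0.2)
        assert np.isclose(k[0, 0], 1.3 - 0.2)
        assert np.isclose(k[7, 7], -0.2, atol=1e-6)  # far field -> -K

    def test_gauss_form_centre_and_decay(self):
        k = cm.make_gaussian_kernel(15, sigma=1.0, form="gauss")
        assert np.isclose(k[0, 0], 1.0)
        assert k[7, 7] < 1e-10
        assert np.isclose(k[0, 1], np.exp(-1.0))

    def test_invalid_form_and_sigma(self):
        with pytest.raises(ValueError):
            cm.make_gaussian_kernel(5, form="box")
        with pytest.raises(ValueError):
            cm.make_gaussian_kernel(5, sigma=0.0)


class TestCANN:
    def test_quiescent_fixed_point(self):
        net = cm.CANNNetwork(N=10, tau=100.0)
        G = cm.cann_step(net, np.zeros((10, 10)), 50.0)
        assert np.allclose(G, 0.0) and np.allclose(net.g, 0.0)

    def test_bump_persists_after_input_removal(self):
        # strong-recurrence regime: a transient localized input leaves a
        # self-sustained bump (attractor property)
        net = cm.CANNNetwork(N=16, tau=50.0, A_lat=3.0, sigma_lat=1.5,
                             K=0.05, b=0.5)
        stim = np.zeros((16, 16))
        stim[8, 8] = 1.0
        for _ in range(40):
            cm.cann_step(net, stim, 25.0)
        for _ in range(60):
            G = cm.cann_step(net, np.zeros((16, 16)), 25.0)
        assert G.max() > 0.05
        assert np.unravel_index(np.argmax(G), G.shape) == (8, 8)

    def test_divisive_normalization_bound(self):
        net = cm.CANNNetwork(N=12, b=2.0)
        net.g = np.random.default_rng(0).random((12, 12)) * 5
        G = cm.cann_output(net)
        ceiling = net.N**2 / (2 * np.pi * net.b)
        assert G.sum() <= ceiling + 1e-9

    def test_blowup_guard(self):
        net = cm.CANNNetwork(N=6)
        net.g = np.full((6, 6), np.inf)
        with pytest.raises(ArithmeticError):
            cm.cann_step(net, np.ones((6, 6)), 50.0)


class TestProjections:
    def test_mc_total_input_is_weighted_sum(self):
        rng = np.random.default_rng(0)
        a, b, c = rng.random((3, 4, 4))
        gains = cm.ProjectionGains(A_PC=2.0, A_PFC=0.5, A_BG=3.0)
        out = cm.mc_total_input(a, b, c, gains)
        assert np.allclose(out, 2 * a + 0.5 * b + 3 * c)
        with pytest.raises(ValueError):
            cm.mc_total_input(a, b, np.zeros((3, 3)), gains)

    def test_pfc_drive_identity_and_zero(self):
        u = np.random.default_rng(1).random((3, 3))
        assert np.allclose(cm.pfc_drive(u, np.eye(9)), u)
        assert np.allclose(cm.pfc_drive(u, np.zeros((9, 9))), 0.0)

    def test_train_pfc_to_mc_converged_and_zero_rate(self):
        W = np.random.default_rng(2).random((9, 9))
        u = np.random.default_rng(3).random(9)
        target = W @ u
        assert np.allclose(cm.train_pfc_to_mc(W, u, target, W @ u, 0.5), W)
        assert np.allclose(cm.train_pfc_to_mc(W, u, target + 1, W @ u, 0.0), W)

    def test_train_pfc_to_mc_outer_product_small_case(self):
        W = np.zeros((2, 2))
        u = np.array([1.0, 2.0])
        err = np.array([0.5, -0.5])  # target - prediction
        out = cm.train_pfc_to_mc(W, u, err, np.zeros(2), 0.1)
        assert np.allclose(out, 0.1 * np.outer(err, u))

    def test_mn_activation_population_decode(self):
        W = np.random.default_rng(4).random((4, 9))
        g = np.random.default_rng(5).random((3, 3))
        phi = cm.mn_activation(g, W, 1.0)
        assert phi.shape == (4,) and phi.min() >= 0 and phi.max() <= 1
        # normalized decode is amplitude invariant
        assert np.allclose(phi, cm.mn_activation(10 * g, W, 1.0))
        assert np.allclose(cm.mn_activation(np.zeros((3, 3)), W, 1.0), 0.0)

    def test_train_mc_to_mn_delta_rule(self):
        W = np.zeros((4, 9))
        g = np.arange(9.0)
        err = np.array([1.0, 0.0, -1.0, 0.5])
        out = cm.train_mc_to_mn(W, err, np.zeros(4), g, 0.2)
        assert np.allclose(out, 0.2 * np.outer(err, g))
        same = cm.train_mc_to_mn(W, np.ones(4), np.ones(4), g, 0.2)
        assert np.allclose(same, W)
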