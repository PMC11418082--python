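"""Flow correctness: analytic identities, invertibility, density training."""

import numpy as np
import pytest

from latsr import generator_models as gm
from latsr import normalizing_flow as nf
from latsr._autodiff import Tensor

from conftest import perturbed_flow

LOG_2PI = np.log(2 * np.pi)


class TestIdentityFlow:
    def test_forward_is_permutation_with_zero_logdet(self):
        flow = nf.identity_flow(5, n_blocks=1)
        w = np.arange(5.0)
        u, ld = nf.flow_forward(w, flow)
        np.testing.assert_array_equal(u, w[::-1])
        assert ld == 0.0
        # two reversals compose to the identity
        flow2 = nf.identity_flow(5, n_blocks=2)
        u2, ld2 = nf.flow_forward(w, flow2)
        np.testing.assert_array_equal(u2, w)
        assert ld2 == 0.0

    def test_log_density_closed_forms(self):
        flow = nf.identity_flow(2)
        assert abs(nf.log_density(np.zeros(2), flow) + LOG_2PI) < 1e-10
        assert abs(nf.log_density(np.array([1.0, 0.0]), flow)
                   + LOG_2PI + 0.5) < 1e-10

    def test_inverse_is_inverse_permutation(self):
        flow = nf.identity_flow(4, n_blocks=1)
        u = np.array([3.0, 1.0, -2.0, 0.5])
        np.testing.assert_allclose(nf.flow_inverse(u, flow), u[::-1], atol=1e-12)

    def test_determinism(self):
        flow = nf.identity_flow(4)
        w = np.random.default_rng(0).standard_normal(4)
        a = nf.flow_forward(w, flow)
        b = nf.flow_forward(w, flow)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_non_finite_input_rejected(self):
        flow = nf.identity_flow(3)
        with pytest.raises(ValueError):
            nf.flow_forward(np.array([1.0, np.nan, 0.0]), flow)


class TestChangeOfVariables:
    def test_logdet_matches_fd_jacobian(self):
        flow = perturbed_flow(d=4, seed=3)
        w = np.random.default_rng(1).standard_normal(4)
        _, ld = nf.flow_forward(w, flow)
        eps = 1e-5
        J = np.zeros((4, 4))
        for j in range(4):
            wp, wm = w.copy(), w.copy()
            wp[j] += eps
            wm[j] -= eps
            J[:, j] = (nf.flow_forward(wp, flow)[0]
                       - nf.flow_forward(wm, flow)[0]) / (2 * eps)
        ld_num = np.log(abs(np.linalg.det(J)))
        assert abs(ld - ld_num) / abs(ld_num) < 1e-4

    def test_density_decomposition_identity(self):
        flow = perturbed_flow(d=6, seed=9)
        w = np.random.default_rng(2).standard_normal((10, 6))
        u, ld = nf.flow_forward(w, flow)
        base = -0.5 * np.sum(u**2, axis=1) - 3 * LOG_2PI
        np.testing.assert_allclose(nf.log_density(w, flow), base + ld, atol=1e-12)

    def test_roundtrip_on_perturbed_flow(self):
        flow = perturbed_flow(d=8, n_blocks=3, seed=4)
        w = np.random.default_rng(5).standard_normal((100, 8))
        u, _ = nf.flow_forward(w, flow)
        back = nf.flow_inverse(u, flow)
        assert np.max(np.abs(back - w)) < 1e-4

    def test_roundtrip_on_trained_flow(self, flow16_trained):
        w = np.random.default_rng(6).standard_normal((100, 16)) * 0.3
        u, _ = nf.flow_forward(w, flow16_trained)
        back = nf.flow_inverse(u, flow16_trained)
        assert np.max(np.abs(back - w)) < 1e-4

    def test_gradient_of_log_density(self):
        flow = perturbed_flow(d=4, seed=7)
        w0 = np.random.default_rng(3).standard_normal((1, 4))
        t = Tensor(w0, requires_grad=True)
        nf.log_density_t(t, flow).sum().backward()
        eps = 1e-6
        for j in range(4):
            wp, wm = w0.copy(), w0.copy()
            wp[0, j] += eps
            wm[0, j] -= eps
            fd = (nf.log_density(wp[0], flow) - nf.log_density(wm[0], flow)) / (2 * eps)
            assert abs(t.grad[0, j] - fd) < 1e-5 * max(1, abs(fd))


class TestOneDimensionalAffine:
    def test_inverse_matches_hand_inverted_map(self):
        flow = nf.FlowModel(d=1, n_blocks=1, hidden_dim=4, alpha_clamp=0.0)
        flow.params[0]["bm"] = np.array([0.7])  # shift
        flow.params[0]["ba"] = np.array([0.3])  # log-scale
        x = np.array([2.0])
        u, ld = nf.flow_forward(x, flow)
        np.testing.assert_allclose(u, (x - 0.7) * np.exp(-0.3), atol=1e-12)
        assert abs(ld + 0.3) < 1e-12
        np.testing.assert_allclose(nf.flow_inverse(u, flow), x, atol=1e-10)


class TestTraining:
    def test_standard_normal_nll_near_entropy(self):
        rng = np.random.default_rng(0)
        samples = rng.standard_normal((4000, 4))
        cfg = nf.FlowTrainConfig(n_blocks=2, hidden_dim=32, n_samples=4000,
                                 epochs=15, batch_size=256, learning_rate=2e-3,
                                 seed=0)
        flow = nf.train_flow(samples, cfg)
        entropy_per_dim = 0.5 * np.log(2 * np.pi * np.e)
        assert abs(flow.final_nll / 4 - entropy_per_dim) < 0.1

    def test_shifted_normal_is_recentered(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(3.0, 1.0, size=(4000, 2))
        cfg = nf.FlowTrainConfig(n_blocks=2, hidden_dim=32, n_samples=4000,
                                 epochs=30, batch_size=256, learning_rate=2e-3,
                                 seed=1)
        flow = nf.train_flow(samples, cfg)
        u, _ = nf.flow_forward(samples, flow)
        assert np.linalg.norm(u.mean(axis=0)) < 0.2

    def test_zero_epochs_returns_identity_model(self):
        samples = np.random.default_rng(2).standard_normal((500, 3))
        cfg = nf.FlowTrainConfig(n_blocks=2, hidden_dim=16, n_samples=500,
                                 epochs=0, batch_size=128, seed=0)
        flow = nf.train_flow(samples, cfg)
        w = np.array([0.0, 0.0, 0.0])
        assert abs(nf.log_density(w, flow) + 1.5 * LOG_2PI) < 1e-10

    def test_density_integrates_to_one_2d(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((6000, 2))
        samples = np.stack([base[:, 0],
                            0.5 * base[:, 1] + 0.3 * base[:, 0] ** 2], axis=1)
        cfg = nf.FlowTrainConfig(n_blocks=3, hidden_dim=32, n_samples=6000,
                                 epochs=40, batch_size=256, learning_rate=2e-3,
                                 seed=2)
        flow = nf.train_flow(samples, cfg)
        span = np.linspace(-8, 8, 161)
        xx, yy = np.meshgrid(span, span)
        grid = np.stack([xx.ravel(), yy.ravel()], axis=1)
        dens = np.exp(nf.log_density(grid, flow))
        integral = dens.sum() * (span[1] - span[0]) ** 2
        assert abs(integral - 1.0) < 1e-2

    def test_too_few_samples_rejected(self):
        cfg = nf.FlowTrainConfig(n_blocks=1, hidden_dim=8, n_samples=10,
                                 epochs=1, batch_size=64)
        with pytest.raises(ValueError):
            nf.train_flow(np.zeros((10, 2)), cfg)


class TestGaussianizationReport:
    def test_chi_squared_moments_for_gaussian_styles(self):
        # linear oracle: w = z is exactly standard normal
        gen = gm.make_linear_oracle(16, (1, 8, 8), seed=0)
        rep = nf.gaussianization_report(None, gen, n=5000, seed=3)
        assert abs(rep.mean_sq_norm - 16) < 3 * np.sqrt(32 / 5000) * 16
        assert abs(rep.var_sq_norm - 32) / 32 < 0.2
        assert rep.reference_mean == 16.0
        assert rep.reference_var == 32.0

    def test_trained_flow_improves_over_untransformed(self, mini_gen32,
                                                      flow16_trained):
        raw = nf.gaussianization_report(None, mini_gen32, n=2000, seed=4)
        fl = nf.gaussianization_report(flow16_trained, mini_gen32, n=2000, seed=4)
        d = 16.0
        assert abs(fl.mean_sq_norm - d) < abs(raw.mean_sq_norm - d)
        assert abs(fl.var_sq_norm - 2 * d) < abs(raw.var_sq_norm - 2 * d)


class TestCheckpoint:
    def test_roundtrip_preserves_density_and_inverse(self, tmp_path,
                                                     flow16_trained):
        path = tmp_path / "flow.npz"
        nf.save_flow(path, flow16_trained)
        loaded = nf.load_flow(path)
        w = np.random.default_rng(8).standard_normal((20, 16)) * 0.3
        np.testing.assert_array_equal(nf.log_density(w, flow16_trained),
                                      nf.log_density(w, loaded))
        u, _ = nf.flow_forward(w, loaded)
        np.testing.assert_allclose(nf.flow_inverse(u, loaded), w, atol=1e-6)
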