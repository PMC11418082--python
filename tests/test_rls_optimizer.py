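"""Objective assembly, closed-form oracle agreement, search behavior."""

import warnings

import numpy as np
import pytest

from latsr import degradation as dg
from latsr import generator_models as gm
from latsr import normalizing_flow as nf
from latsr import rls_optimizer as rls

LOG_2PI = np.log(2 * np.pi)


def quiet_cfg(**kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rls.RLSConfig(**kw)


class TestPriorTerms:
    def test_flow_term_at_origin_identity_flow(self):
        flow = nf.identity_flow(2)
        assert abs(rls.prior_flow_term(np.zeros((1, 2)), flow) - LOG_2PI) < 1e-10

    def test_flow_term_averages_identical_copies(self):
        flow = nf.identity_flow(3)
        w = np.array([0.3, -0.5, 1.0])
        single = rls.prior_flow_term(w[None], flow)
        stacked = rls.prior_flow_term(np.tile(w, (5, 1)), flow)
        assert abs(single - stacked) < 1e-12

    def test_flow_term_increases_with_norm(self):
        flow = nf.identity_flow(4)
        vals = [rls.prior_flow_term(c * np.ones((1, 4)), flow)
                for c in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(vals) > 0)

    def test_pairwise_examples(self):
        assert rls.prior_pairwise_term(np.tile([1.0, 2.0], (4, 1))) == 0.0
        assert abs(rls.prior_pairwise_term(
            np.array([[0.0, 0.0], [1.0, 1.0]])) - 2.0) < 1e-12
        assert abs(rls.prior_pairwise_term(
            np.array([[0.0], [1.0], [2.0]])) - 2.0) < 1e-12
        assert rls.prior_pairwise_term(np.ones((1, 3))) == 0.0

    def test_pairwise_matches_brute_force(self):
        rng = np.random.default_rng(0)
        wp = rng.standard_normal((6, 5))
        brute = np.mean([np.sum((wp[i] - wp[j]) ** 2)
                         for i in range(6) for j in range(i + 1, 6)])
        assert abs(rls.prior_pairwise_term(wp) - brute) < 1e-10
        brute_u = np.mean([np.linalg.norm(wp[i] - wp[j])
                           for i in range(6) for j in range(i + 1, 6)])
        assert abs(rls.prior_pairwise_term(wp, squared=False) - brute_u) < 1e-6


class TestObjective:
    @pytest.fixture()
    def setup(self):
        gen = gm.make_linear_oracle(6, (1, 8, 8), seed=2)
        op = dg.downscale_operator(2)
        flow = nf.identity_flow(6)
        return gen, op, flow

    def test_perfect_fit_is_zero(self, setup):
        gen, op, flow = setup
        w = np.random.default_rng(1).standard_normal(6)
        lr_img = dg.apply_operator(op, gm.synthesize(w, gen))
        cfg = quiet_cfg(lambda1=0.0, lambda2=0.0)
        total, terms = rls.objective(w[None], lr_img, gen, op, flow, cfg)
        assert abs(total) < 1e-12 and abs(terms[0]) < 1e-12

    def test_constant_offset_gives_l1_delta(self, setup):
        gen, op, flow = setup
        w = np.random.default_rng(2).standard_normal(6)
        lr_img = dg.apply_operator(op, gm.synthesize(w, gen)) + 0.07
        cfg = quiet_cfg(lambda1=0.0, lambda2=0.0)
        total, _ = rls.objective(w[None], lr_img, gen, op, flow, cfg)
        assert abs(total - 0.07) < 1e-12

    def test_total_is_sum_of_terms(self, setup):
        gen, op, flow = setup
        w = np.random.default_rng(3).standard_normal(6)
        lr_img = np.random.default_rng(4).uniform(-1, 1, (1, 4, 4))
        cfg = quiet_cfg(lambda1=1e-4, lambda2=0.01)
        total, (data, p1, p2) = rls.objective(w[None], lr_img, gen, op, flow, cfg)
        assert abs(total - (data + cfg.lambda1 * p1 + cfg.lambda2 * p2)) < 1e-10

    def test_shape_mismatch_raises(self, setup):
        gen, op, flow = setup
        with pytest.raises(ValueError):
            rls.objective(np.zeros((1, 6)), np.zeros((1, 3, 3)), gen, op, flow,
                          quiet_cfg())


class TestClosedForm:
    def test_exact_interpolation_square_system(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((16, 4))
        op = dg.downscale_operator(2)
        Dmat = rls.flat_operator_matrix(op, (1, 4, 4))
        w_true = rng.standard_normal(4)
        y = Dmat @ A @ w_true
        w = rls.closed_form_linear_map(y, A, Dmat, 0.0)
        np.testing.assert_allclose(w, w_true, atol=1e-8)

    def test_ridge_limit_shrinks_to_zero(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((16, 4))
        y = rng.standard_normal(16)
        w = rls.closed_form_linear_map(y, A, np.eye(16), 1e8)
        assert np.linalg.norm(w) < 1e-5

    def test_dominates_random_search(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((16, 4))
        y = rng.standard_normal(16)
        lam = 0.1
        w = rls.closed_form_linear_map(y, A, np.eye(16), lam)

        def loss(v):
            return np.sum((A @ v - y) ** 2) / 16 + lam * np.sum(v**2)

        best_random = min(loss(rng.standard_normal(4)) for _ in range(1000))
        assert loss(w) <= best_random + 1e-12


class TestSuperresolve:
    @pytest.fixture(scope="class")
    def problem(self, mini_gen32):
        flow = nf.identity_flow(16)
        op = dg.downscale_operator(4)
        rng = np.random.default_rng(9)
        w_star = gm.map_latent(rng.standard_normal(16), mini_gen32)
        hr = gm.synthesize(w_star, mini_gen32)
        return mini_gen32, flow, op, dg.apply_operator(op, hr)

    def test_zero_iterations_returns_initialization(self, problem):
        gen, flow, op, lr_img = problem
        cfg = quiet_cfg(iterations=0, init_samples=200, seed=3)
        res = rls.superresolve(lr_img, gen, op, flow, cfg)
        w0 = gm.mean_latent(gen, 200, 3)
        np.testing.assert_array_equal(res.wplus, np.tile(w0, (gen.L, 1)))
        np.testing.assert_array_equal(res.sr_image, gm.synthesize(res.wplus, gen))
        assert len(res.loss_trace) == 1

    def test_search_reduces_objective_and_is_reproducible(self, problem):
        gen, flow, op, lr_img = problem
        cfg = quiet_cfg(iterations=40, learning_rate=0.2, lr_schedule="cosine",
                        init_samples=500, seed=1)
        res1 = rls.superresolve(lr_img, gen, op, flow, cfg)
        res2 = rls.superresolve(lr_img, gen, op, flow, cfg)
        assert res1.converged_value < res1.loss_trace[0]
        assert res1.converged_value == min(res1.loss_trace)
        np.testing.assert_array_equal(res1.wplus, res2.wplus)
        assert len(res1.loss_trace) == 41
        assert res1.term_trace.shape == (41, 3)

    def test_sr_image_matches_best_latent(self, problem):
        gen, flow, op, lr_img = problem
        cfg = quiet_cfg(iterations=20, learning_rate=0.2, init_samples=200, seed=2)
        res = rls.superresolve(lr_img, gen, op, flow, cfg)
        np.testing.assert_array_equal(res.sr_image, gm.synthesize(res.wplus, gen))

    def test_adam_matches_closed_form_ridge(self):
        """L2 data term + Gaussian (identity-flow) prior on the linear
        generator has a normal-equations solution the search must find."""
        gen = gm.make_linear_oracle(8, (1, 16, 16), seed=4)
        op = dg.downscale_operator(4)
        flow = nf.identity_flow(8)
        rng = np.random.default_rng(11)
        lr_img = dg.apply_operator(
            op, gm.synthesize(rng.standard_normal(8), gen)) \
            + 0.03 * rng.standard_normal((1, 4, 4))
        lam1 = 0.02
        cfg = quiet_cfg(lambda1=lam1, lambda2=0.0, data_norm="L2",
                        iterations=200, learning_rate=0.3, lr_schedule="cosine",
                        use_pairwise_prior=False, init_samples=100, seed=0)
        res = rls.superresolve(lr_img, gen, op, flow, cfg)
        Dmat = rls.flat_operator_matrix(op, gen.output_shape)
        w_cf = rls.closed_form_linear_map(lr_img.ravel(), gm.oracle_matrix(gen),
                                          Dmat, lam1 / 2)
        rel = np.linalg.norm(res.wplus[0] - w_cf) / np.linalg.norm(w_cf)
        assert rel < 1e-3


class TestAblation:
    def test_variants_share_initialization_and_ordering(self, mini_gen32,
                                                        flow16_trained):
        gen, flow = mini_gen32, flow16_trained
        op = dg.downscale_operator(4)
        rng = np.random.default_rng(21)
        hr = gm.synthesize(gm.map_latent(rng.standard_normal(16), gen), gen)
        lr_img = dg.apply_operator(op, hr)
        cfg = quiet_cfg(iterations=50, learning_rate=0.2, lr_schedule="cosine",
                        init_samples=500, seed=5)
        out = rls.run_ablation_suite(lr_img, gen, op, flow, cfg)
        assert set(out) == {"rls", "wo_p1", "wo_p2", "wo_regu"}
        init_data = [out[k].result.term_trace[0, 0] for k in out]
        assert np.ptp(init_data) < 1e-12
        # the regularizers' defining effect on the recovered latents: denser
        # (lower NLL) with the flow prior, densest with both priors
        assert out["rls"].flow_nll <= out["wo_p2"].flow_nll
        assert out["wo_p2"].flow_nll <= out["wo_regu"].flow_nll
        # copies stay coherent only under the pairwise prior
        assert (out["rls"].pairwise_spread
                <= out["wo_p2"].pairwise_spread)
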