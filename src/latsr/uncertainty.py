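"""Posterior sampling around the MAP latent: multiple plausible SR solutions.

Super-resolution stays ill-posed even with priors: several HR images can be
consistent with one LR observation.  To expose that, K latent codes are drawn
from an isotropic Gaussian N(w_MAP, sigma^2 I) per W+ copy, where the scale
sigma carries an inverse-gamma prior and is itself estimated by 1-D MAP: the
Laplace log-likelihood of the residual at the MAP latent (with scale sigma)
plus the inverse-gamma log-prior.  Each sampled latent is optionally refined
for a few gradient steps on the full objective so samples stay consistent
with the LR observation; the per-pixel standard deviation across the K
synthesized images summarizes the reconstruction uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ._autodiff import Adam, Tensor
from . import degradation as dg
from . import generator_models as gm
from . import normalizing_flow as nf
from . import rls_optimizer as rls


@dataclass
class UncertaintyConfig:
    K: int = 5  # number of SR samples
    alpha: float = 1.0  # inverse-gamma shape
    beta: float = 1.0  # inverse-gamma scale
    refine_iters: int = 60  # per-sample refinement steps (0 = pure prior samples)
    refine_lr: float = 0.02  # gentle step size so refinement re-imposes data
    # consistency without washing out the sampled perturbation; the step
    # decays to zero (cosine) so the iterates settle instead of oscillating
    sigma_override: float | None = None  # force sigma (diagnostics)
    data_tolerance: float = 2.0  # flag samples with data term > tol * MAP data term
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")


@dataclass
class SRSampleSet:
    images: np.ndarray  # (K, C, H, W)
    latents: np.ndarray  # (K, L, d)
    sigma_hat: float
    pixel_std: np.ndarray = field(repr=False)  # (C, H, W)
    data_terms: np.ndarray = field(default=None, repr=False)  # (K,)
    flagged: np.ndarray = field(default=None, repr=False)  # (K,) bool


def estimate_sigma(result: rls.RLSResult, cfg: UncertaintyConfig,
                   n_obs: int | None = None) -> float:
    """MAP estimate of the posterior scale sigma.

    Maximizes  -m*E/sigma - m*log(2*sigma) + log InvGamma(sigma; alpha, beta)
    over sigma by bounded 1-D search, where E is the MAP data term (mean
    absolute LR residual) and m the number of LR observations.  A zero
    residual is degenerate (the likelihood carries no scale information);
    the prior mode beta/(alpha+1) is returned in that case.
    """
    E = result.data_term
    if E < 1e-12:
        return cfg.beta / (cfg.alpha + 1.0)
    m = float(n_obs) if n_obs is not None else 1.0

    def neg_log_post(sigma):
        if sigma <= 0:
            return np.inf
        loglik = -m * E / sigma - m * np.log(2.0 * sigma)
        logprior = -(cfg.alpha + 1.0) * np.log(sigma) - cfg.beta / sigma
        return -(loglik + logprior)

    res = minimize_scalar(neg_log_post, bounds=(1e-6, 100.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def sample_sr(lr_img: np.ndarray, result: rls.RLSResult, gen: gm.StyleGenerator,
              op: dg.ForwardOperator, flow: nf.FlowModel,
              rls_cfg: rls.RLSConfig, unc_cfg: UncertaintyConfig | None = None
              ) -> SRSampleSet:
    """Draw K plausible SR solutions around the MAP latent.

    Reproducible given ``unc_cfg.seed``; samples whose refined data term
    exceeds ``data_tolerance`` times the MAP data term are flagged (never
    dropped).  With sigma forced to 0 the set degenerates to K copies of the
    MAP reconstruction.
    """
    unc_cfg = unc_cfg or UncertaintyConfig()
    lr_img = np.asarray(lr_img, dtype=np.float64)
    det_mats, _ = dg.deterministic_matrices(op, gen.output_shape)
    if unc_cfg.sigma_override is not None:
        sigma = float(unc_cfg.sigma_override)
    else:
        sigma = estimate_sigma(result, unc_cfg, n_obs=lr_img.size)
    K, L, d = unc_cfg.K, gen.L, gen.d
    map_img = result.sr_image

    if sigma == 0.0:
        images = np.repeat(map_img[None], K, axis=0)
        latents = np.repeat(result.wplus[None], K, axis=0)
        data_terms = np.full(K, result.data_term)
        return SRSampleSet(images=images, latents=latents, sigma_hat=0.0,
                           pixel_std=np.zeros_like(map_img),
                           data_terms=data_terms,
                           flagged=np.zeros(K, dtype=bool))

    rng = np.random.default_rng(unc_cfg.seed)
    images = np.empty((K,) + gen.output_shape)
    latents = np.empty((K, L, d))
    data_terms = np.empty(K)
    for k in range(K):
        w_k = result.wplus + sigma * rng.standard_normal((L, d))
        if unc_cfg.refine_iters > 0:
            param = Tensor(w_k, requires_grad=True)
            opt = Adam([param], lr=unc_cfg.refine_lr, betas=rls_cfg.betas)
            n_ref = unc_cfg.refine_iters
            for it in range(n_ref):
                total_t, _terms = rls._objective_t(param, lr_img, gen, det_mats,
                                                   None, flow, rls_cfg)
                total_t.backward()
                opt.step(lr=unc_cfg.refine_lr * 0.5 * (1 + np.cos(np.pi * it / n_ref)))
            w_k = param.data
        latents[k] = w_k
        images[k] = gm.synthesize(w_k, gen)
        _, (data_k, _, _) = rls.objective(w_k, lr_img, gen, op, flow, rls_cfg)
        data_terms[k] = data_k
    pixel_std = images.std(axis=0, ddof=0)
    flagged = data_terms > unc_cfg.data_tolerance * max(result.data_term, 1e-12)
    return SRSampleSet(images=images, latents=latents, sigma_hat=sigma,
                       pixel_std=pixel_std, data_terms=data_terms,
                       flagged=flagged)
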