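"""Regularized latent search: MAP super-resolution over W+.

Given an LR observation y, a frozen generator G, a known forward operator D
and a flow-based density model p(w) of the style space, the HR estimate is
G(W+*) where W+* minimizes

    E(W+) = |D(G(W+)) - y|_1  +  lambda1 * P1(W+)  +  lambda2 * P2(W+)

The L1 data term is the negative log-likelihood under Laplace observation
noise (its scale is absorbed into the lambdas, only the ratios matter).  P1
is the flow-density prior, averaged over the L per-layer copies: it keeps
each copy in a high-density region of the style distribution.  P2 is the
pairwise Euclidean consistency prior over the copies (mean squared pairwise
distance by default): it keeps W+ close to the trained W manifold, where all
copies coincide.  Search variable is W+ itself (the flow only scores it);
optimization is Adam with the study defaults (200 iterations, learning rate
0.5, initialization at the mean of 10,000 mapped latents), and the iterate
with the lowest recorded total is returned (robust to late oscillation at a
large learning rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._autodiff import Adam, Tensor
from . import degradation as dg
from . import generator_models as gm
from . import normalizing_flow as nf


@dataclass
class RLSConfig:
    """Search hyperparameters (defaults are the study settings)."""

    lambda1: float = 5e-5
    lambda2: float = 0.01
    iterations: int = 200
    learning_rate: float = 0.5
    init_samples: int = 10000
    data_norm: str = "L1"  # "L1" (Laplace noise) | "L2" (Gaussian; oracle mode)
    use_flow_prior: bool = True
    use_pairwise_prior: bool = True
    pairwise_squared: bool = True
    lr_schedule: str = "constant"  # "constant" | "cosine"
    betas: tuple = (0.9, 0.999)
    seed: int = 0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambdas must be >= 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.data_norm not in ("L1", "L2"):
            raise ValueError("data_norm must be 'L1' or 'L2'")
        # empirically validated ranges; outside them the search still runs
        if self.use_flow_prior and self.lambda1 > 0 and not (1e-6 <= self.lambda1 <= 5e-4):
            warnings.warn("lambda1 outside the validated range [1e-6, 5e-4]",
                          stacklevel=2)
        if self.use_pairwise_prior and self.lambda2 > 0 and not (0.005 <= self.lambda2 <= 0.05):
            warnings.warn("lambda2 outside the validated range [0.005, 0.05]",
                          stacklevel=2)


@dataclass
class RLSResult:
    """Outcome of a latent search."""

    wplus: np.ndarray  # (L, d) best-so-far extended latent
    sr_image: np.ndarray  # G(wplus), internal [-1, 1] range
    loss_trace: np.ndarray  # (iterations + 1,) total objective per iteration
    term_trace: np.ndarray = field(repr=False)  # (iterations + 1, 3): data, P1, P2
    converged_value: float = 0.0

    @property
    def data_term(self) -> float:
        """Data term of the returned (best) iterate."""
        return float(self.term_trace[np.argmin(self.loss_trace), 0])


class RLSDivergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# objective terms
# ---------------------------------------------------------------------------

def prior_flow_term(wplus: np.ndarray, flow: nf.FlowModel) -> float:
    """Average negative flow log-density over the L copies (lower = denser)."""
    wp = np.atleast_2d(np.asarray(wplus, dtype=np.float64))
    return float(-np.mean(nf.log_density(wp, flow)))


def prior_pairwise_term(wplus: np.ndarray, squared: bool = True) -> float:
    """Mean pairwise (squared) Euclidean distance over the copies; 0 if L=1."""
    wp = np.atleast_2d(np.asarray(wplus, dtype=np.float64))
    L = wp.shape[0]
    if L < 2:
        return 0.0
    vals = []
    for i in range(L):
        for j in range(i + 1, L):
            d2 = float(np.sum((wp[i] - wp[j]) ** 2))
            vals.append(d2 if squared else np.sqrt(d2))
    return float(np.mean(vals))


def _pairwise_t(w: Tensor, L: int, squared: bool) -> Tensor:
    if L < 2:
        return Tensor(0.0)
    if squared:
        # mean_{i<j} |w_i - w_j|^2 = (L * sum_i |w_i|^2 - |sum_i w_i|^2) / (L(L-1)/2)
        sum_sq = (w * w).sum()
        col_sum = Tensor(np.ones((1, L))) @ w  # (1, d)
        total = sum_sq * float(L) - (col_sum * col_sum).sum()
        return total * (2.0 / (L * (L - 1)))
    terms = None
    for i in range(L):
        for j in range(i + 1, L):
            sel = np.zeros((1, L))
            sel[0, i], sel[0, j] = 1.0, -1.0
            diff = Tensor(sel) @ w
            dist = ((diff * diff).sum() + 1e-12).sqrt()
            terms = dist if terms is None else terms + dist
    return terms * (2.0 / (L * (L - 1)))


def _objective_t(w: Tensor, lr_img: np.ndarray, gen: gm.StyleGenerator,
                 det_mats: list, out_shape: tuple, flow: nf.FlowModel,
                 cfg: RLSConfig):
    """Differentiable objective; returns (total Tensor, (data, p1, p2) floats)."""
    y = gm.synthesize_t(w, gen)
    for mh, mw in det_mats:
        y = y.sep_apply(mh, mw)
    if y.data.shape != lr_img.shape:
        raise ValueError(f"operator output {y.data.shape} does not match the "
                         f"LR image {lr_img.shape}")
    resid = y - Tensor(lr_img)
    if cfg.data_norm == "L1":
        data = resid.abs().mean()
    else:
        data = (resid * resid).mean()
    total = data
    p1_val = 0.0
    if cfg.use_flow_prior and cfg.lambda1 > 0:
        p1 = -log_density_rows_mean(w, flow)
        p1_val = p1.item()
        total = total + p1 * cfg.lambda1
    p2_val = 0.0
    if cfg.use_pairwise_prior and cfg.lambda2 > 0 and gen.L > 1:
        p2 = _pairwise_t(w, gen.L, cfg.pairwise_squared)
        p2_val = p2.item()
        total = total + p2 * cfg.lambda2
    return total, (data.item(), p1_val, p2_val)


def log_density_rows_mean(w: Tensor, flow: nf.FlowModel) -> Tensor:
    """Mean flow log-density over the rows of an (L, d) Tensor."""
    return nf.log_density_t(w, flow).mean()


def objective(wplus: np.ndarray, lr_img: np.ndarray, gen: gm.StyleGenerator,
              op: dg.ForwardOperator, flow: nf.FlowModel, cfg: RLSConfig):
    """Evaluate the full objective; returns (total, (data, p1, p2)).

    The reported prior terms are unweighted; the total applies the lambdas
    and the ablation flags.
    """
    wp = gm._as_wplus(wplus, gen)
    det_mats, out_shape = dg.deterministic_matrices(op, gen.output_shape)
    total, terms = _objective_t(Tensor(wp), np.asarray(lr_img, dtype=np.float64),
                                gen, det_mats, out_shape, flow, cfg)
    return total.item(), terms


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def superresolve(lr_img: np.ndarray, gen: gm.StyleGenerator,
                 op: dg.ForwardOperator, flow: nf.FlowModel,
                 cfg: RLSConfig | None = None) -> RLSResult:
    """Run the regularized latent search on one LR image.

    All L copies start at the mean of ``cfg.init_samples`` mapped latents;
    the returned iterate is the best-so-far by total objective.  Fully
    reproducible given ``cfg.seed``.
    """
    cfg = cfg or RLSConfig()
    lr_img = np.asarray(lr_img, dtype=np.float64)
    det_mats, out_shape = dg.deterministic_matrices(op, gen.output_shape)
    if out_shape[1:] != lr_img.shape[1:] or lr_img.shape[0] != gen.output_shape[0]:
        raise ValueError(f"LR image shape {lr_img.shape} incompatible with the "
                         f"operator output {out_shape}")
    w0 = gm.mean_latent(gen, cfg.init_samples, cfg.seed)
    param = Tensor(np.tile(w0, (gen.L, 1)), requires_grad=True)
    opt = Adam([param], lr=cfg.learning_rate, betas=cfg.betas)

    totals = np.empty(cfg.iterations + 1)
    terms = np.empty((cfg.iterations + 1, 3))
    best_val = np.inf
    best_w = param.data.copy()
    for k in range(cfg.iterations + 1):
        total_t, term_vals = _objective_t(param, lr_img, gen, det_mats,
                                          out_shape, flow, cfg)
        val = total_t.item()
        if not np.isfinite(val):
            raise RLSDivergenceError(
                f"non-finite objective at iteration {k}: terms={term_vals}")
        totals[k] = val
        terms[k] = term_vals
        if val < best_val:
            best_val = val
            best_w = param.data.copy()
        if k == cfg.iterations:
            break
        total_t.backward()
        if cfg.lr_schedule == "cosine":
            lr_k = cfg.learning_rate * 0.5 * (1 + np.cos(np.pi * k / cfg.iterations))
        else:
            lr_k = cfg.learning_rate
        opt.step(lr=lr_k)

    return RLSResult(wplus=best_w, sr_image=gm.synthesize(best_w, gen),
                     loss_trace=totals, term_trace=terms,
                     converged_value=float(best_val))


# ---------------------------------------------------------------------------
# closed-form oracle (linear generator, L2 data term, quadratic prior)
# ---------------------------------------------------------------------------

def closed_form_linear_map(lr_vec: np.ndarray, A: np.ndarray, Dmat: np.ndarray,
                           lam: float) -> np.ndarray:
    """argmin_w |D A w - y|^2 / m + lam |w|^2 via the normal equations."""
    y = np.asarray(lr_vec, dtype=np.float64).ravel()
    DA = np.asarray(Dmat) @ np.asarray(A)
    m = DA.shape[0]
    lhs = DA.T @ DA / m + lam * np.eye(DA.shape[1])
    rhs = DA.T @ y / m
    if lam == 0 and np.linalg.matrix_rank(DA) < DA.shape[1]:
        raise np.linalg.LinAlgError("singular system with lam=0")
    return np.linalg.solve(lhs, rhs)


def flat_operator_matrix(op: dg.ForwardOperator, in_shape: tuple) -> np.ndarray:
    """Dense matrix of the deterministic operator on flattened (C,H,W) images."""
    C, H, W = in_shape
    det_mats, (Co, Ho, Wo) = dg.deterministic_matrices(op, in_shape)
    D = np.eye(C * H * W)
    h, w = H, W
    for mh, mw in det_mats:
        ho, wo = mh.shape[0], mw.shape[0]
        block = np.kron(mh, mw)  # acts on one flattened channel
        D = np.kron(np.eye(C), block) @ D
        h, w = ho, wo
    return D


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

VARIANTS = {
    "rls": {},
    "wo_p1": {"use_flow_prior": False},
    "wo_p2": {"use_pairwise_prior": False},
    "wo_regu": {"use_flow_prior": False, "use_pairwise_prior": False},
}


@dataclass
class AblationOutcome:
    result: RLSResult
    flow_nll: float  # P1 of the recovered latents
    pairwise_spread: float  # P2 (squared) of the recovered latents


def run_ablation_suite(lr_img: np.ndarray, gen: gm.StyleGenerator,
                       op: dg.ForwardOperator, flow: nf.FlowModel,
                       cfg: RLSConfig | None = None) -> dict:
    """Run the four prior-ablation variants with identical initialization.

    Returns {variant: AblationOutcome} for "rls" (full), "wo_p1" (no flow
    prior), "wo_p2" (no pairwise prior) and "wo_regu" (no priors).
    """
    cfg = cfg or RLSConfig()
    out = {}
    for name, flags in VARIANTS.items():
        res = superresolve(lr_img, gen, op, flow, replace(cfg, **flags))
        out[name] = AblationOutcome(
            result=res,
            flow_nll=prior_flow_term(res.wplus, flow),
            pairwise_spread=prior_pairwise_term(res.wplus, squared=True))
    return out
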