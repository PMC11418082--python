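"""Masked autoregressive flow (MAF) over the style space W.

The style distribution produced by a generator's mapping network is not
Gaussian, which breaks regularizers that assume it is.  A normalizing flow
f: W -> U learns an invertible map such that u = f(w) is standard normal; the
change-of-variables formula then gives the exact log-density of w:

    log p(w) = log N(f(w); 0, I) + log |det J_f(w)|

Each flow block is a MADE-style affine autoregressive transform
u_i = (x_i - mu_i(x_{<i})) * exp(-alpha_i(x_{<i})) whose conditioner is a
two-hidden-layer masked MLP with sequential degree assignment; blocks are
separated by a fixed reversal permutation.  The density-evaluation direction
is a single parallel pass (so both training and the prior gradient are cheap);
inversion is sequential, one dimension per pass.

The flow is defined on W (d dimensions); the per-copy handling of the
extended latent lives in the optimizer.  Conditioner output layers are
initialized to zero, so a fresh flow is exactly the identity (up to the
permutations) with zero log-determinant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import (Adam, Tensor, radial_quantile_inverse,
                        radial_quantile_map)
from . import generator_models as gm
from . import io as _io

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class FlowTrainConfig:
    """Training hyperparameters; full-scale defaults follow the study setup
    (5 blocks, hidden 1024, 100k samples); the desk scale keeps 5 blocks but
    shrinks to hidden 64 on 20k samples (``pipelines.DESK_FLOW_CONFIG``)."""

    n_blocks: int = 5
    hidden_dim: int = 1024
    n_samples: int = 100000
    epochs: int = 40
    batch_size: int = 256
    learning_rate: float = 1e-3
    activation: str = "tanh"  # conditioner hidden activation: "tanh" | "relu"
    weight_decay: float = 0.05  # decoupled L2 decay; tames tail extrapolation
    alpha_clamp: float = 3.0  # soft bound on per-block log-scale (0 = unbounded)
    noise_rel: float = 0.05  # training-sample jitter, relative to per-dim std
    val_fraction: float = 0.1  # held-out fraction (calibration / early stop)
    early_stop: bool = False  # keep the best-validation-NLL epoch
    calibrate: bool = True  # final per-dim affine layer z-scored on clean
    # held-out latents (constant log-det)
    radial_calibrate: bool = True  # quantile-match the radius distribution of
    # f(w) to the chi(d) law on the held-out latents (radial Gaussianization)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_blocks", "hidden_dim", "n_samples", "epochs",
                     "batch_size", "learning_rate"):
            if getattr(self, name) < 0 or (name not in ("epochs",) and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")


@dataclass
class GaussianizationReport:
    """Squared-norm diagnostic: ||f(w)||^2 should be chi-squared with d dof,
    i.e. mean d and variance 2d."""

    n: int
    sq_norms: np.ndarray = field(repr=False)
    mean_sq_norm: float
    var_sq_norm: float
    reference_mean: float
    reference_var: float

    def to_dict(self) -> dict:
        return {"n": self.n, "mean_sq_norm": self.mean_sq_norm,
                "var_sq_norm": self.var_sq_norm,
                "reference_mean": self.reference_mean,
                "reference_var": self.reference_var}


class FlowModel:
    """Stack of masked affine autoregressive blocks with reversal permutations."""

    def __init__(self, d: int, n_blocks: int, hidden_dim: int, seed: int = 0,
                 activation: str = "tanh", alpha_clamp: float = 3.0):
        if d < 1 or n_blocks < 1 or hidden_dim < 1:
            raise ValueError("d, n_blocks and hidden_dim must be >= 1")
        if activation not in ("tanh", "relu"):
            raise ValueError("activation must be 'tanh' or 'relu'")
        self.d = d
        self.n_blocks = n_blocks
        self.hidden_dim = hidden_dim
        self.activation = activation
        self.alpha_clamp = float(alpha_clamp)
        # optional final affine calibration layer (identity by default)
        self.calib_shift = np.zeros(d)
        self.calib_scale = np.ones(d)
        # optional radial quantile-matching layer (off by default): maps the
        # radius distribution onto the chi(d) law of a standard normal
        self.radial_r: np.ndarray | None = None
        self.radial_t: np.ndarray | None = None
        self.final_nll: float | None = None
        self.history: list[float] = []
        rng = np.random.default_rng(seed)
        self.masks = self._build_masks(d, hidden_dim)
        self.params: list[dict[str, np.ndarray]] = []
        h = hidden_dim
        for _ in range(n_blocks):
            blk = {
                "W1": rng.standard_normal((d, h)) * np.sqrt(2.0 / d),
                "b1": np.zeros(h),
                "W2": rng.standard_normal((h, h)) * np.sqrt(2.0 / h),
                "b2": np.zeros(h),
                # zero-initialized output layers -> identity transform
                "Wm": np.zeros((h, d)), "bm": np.zeros(d),
                "Wa": np.zeros((h, d)), "ba": np.zeros(d),
            }
            self.params.append(blk)

    @staticmethod
    def _build_masks(d: int, h: int):
        in_deg = np.arange(1, d + 1)
        hid_deg = (np.arange(h) % max(1, d - 1)) + 1
        if d == 1:
            hid_deg = np.zeros(h, dtype=int)  # outputs become pure constants
        m1 = (hid_deg[None, :] >= in_deg[:, None]).astype(float)  # (d, h)
        m2 = (hid_deg[None, :] >= hid_deg[:, None]).astype(float)  # (h, h)
        mout = (in_deg[None, :] > hid_deg[:, None]).astype(float)  # (h, d)
        return {"M1": m1, "M2": m2, "Mout": mout}

    # -- conditioner ------------------------------------------------------
    def _conditioner_t(self, x: Tensor, blk: dict, as_tensor: bool) -> tuple:
        """Masked MLP: returns (mu, alpha) for a batch x of shape (n, d)."""
        M1, M2, Mout = self.masks["M1"], self.masks["M2"], self.masks["Mout"]
        wrap = (lambda a: Tensor.as_tensor(a)) if as_tensor else (lambda a: a)
        W1, b1 = wrap(blk["W1"] * M1), wrap(blk["b1"])
        W2, b2 = wrap(blk["W2"] * M2), wrap(blk["b2"])
        Wm, bm = wrap(blk["Wm"] * Mout), wrap(blk["bm"])
        Wa, ba = wrap(blk["Wa"] * Mout), wrap(blk["ba"])
        if as_tensor:
            act = (lambda t: t.tanh()) if self.activation == "tanh" else (lambda t: t.relu())
        else:
            act = np.tanh if self.activation == "tanh" else (lambda t: np.maximum(t, 0.0))
        h1 = act(x @ W1 + b1)
        h2 = act(h1 @ W2 + b2)
        mu = h2 @ Wm + bm
        alpha = h2 @ Wa + ba
        c = self.alpha_clamp
        if c > 0:
            alpha = (alpha * (1.0 / c)).tanh() * c if as_tensor else c * np.tanh(alpha / c)
        return mu, alpha

    def _conditioner_params_t(self, x: Tensor, tens: dict) -> tuple:
        """Conditioner with parameters given as Tensors (training path)."""
        M1, M2, Mout = self.masks["M1"], self.masks["M2"], self.masks["Mout"]
        act = (lambda t: t.tanh()) if self.activation == "tanh" else (lambda t: t.relu())
        h1 = act(x @ (tens["W1"] * Tensor(M1)) + tens["b1"])
        h2 = act(h1 @ (tens["W2"] * Tensor(M2)) + tens["b2"])
        mu = h2 @ (tens["Wm"] * Tensor(Mout)) + tens["bm"]
        alpha = h2 @ (tens["Wa"] * Tensor(Mout)) + tens["ba"]
        if self.alpha_clamp > 0:
            alpha = (alpha * (1.0 / self.alpha_clamp)).tanh() * self.alpha_clamp
        return mu, alpha

    # -- forward / density ------------------------------------------------
    def forward_t(self, x: Tensor, param_tensors: list | None = None):
        """Tensor path of f; returns (u, logdet) with logdet shape (n,)."""
        logdet = None
        for b, blk in enumerate(self.params):
            x = x.flip(axis=-1)
            if param_tensors is None:
                mu, alpha = self._conditioner_t(x, blk, as_tensor=True)
            else:
                mu, alpha = self._conditioner_params_t(x, param_tensors[b])
            x = (x - mu) * (-alpha).exp()
            contrib = (-alpha).sum(axis=1)
            logdet = contrib if logdet is None else logdet + contrib
        if not np.allclose(self.calib_scale, 1.0) or np.any(self.calib_shift):
            inv_scale = 1.0 / self.calib_scale
            if isinstance(x, Tensor):
                x = (x - Tensor(self.calib_shift)) * Tensor(inv_scale)
            else:
                x = (x - self.calib_shift) * inv_scale
            const = float(np.sum(np.log(inv_scale)))
            logdet = logdet + const
        if self.radial_r is not None:
            xt = x if isinstance(x, Tensor) else Tensor(x)
            x, ld = radial_quantile_map(xt, self.radial_r, self.radial_t)
            logdet = logdet + ld
        return x, logdet


def _batchify(w: np.ndarray, d: int):
    w = np.asarray(w, dtype=np.float64)
    if not np.all(np.isfinite(w)):
        raise ValueError("flow input contains non-finite values")
    single = w.ndim == 1
    wb = w[None] if single else w
    if wb.shape[1] != d:
        raise ValueError(f"input dimension {wb.shape[1]} != flow d={d}")
    return wb, single


def flow_forward(w: np.ndarray, flow: FlowModel):
    """u = f(w) plus the log |det Jacobian| of f at w.

    Accepts a single vector (d,) or a batch (n, d); returns matching shapes.
    """
    wb, single = _batchify(w, flow.d)
    u, logdet = flow.forward_t(Tensor(wb))
    u, logdet = u.data, logdet.data
    return (u[0], float(logdet[0])) if single else (u, logdet)


def flow_inverse(u: np.ndarray, flow: FlowModel) -> np.ndarray:
    """Invert f sequentially (one conditioner pass per dimension per block)."""
    ub, single = _batchify(u, flow.d)
    if flow.radial_r is not None:
        ub = radial_quantile_inverse(ub, flow.radial_r, flow.radial_t)
    x = ub * flow.calib_scale + flow.calib_shift
    for blk in reversed(flow.params):
        y = np.zeros_like(x)
        for _ in range(flow.d):
            mu, alpha = flow._conditioner_t(y, blk, as_tensor=False)
            y = x * np.exp(alpha) + mu
        x = y[:, ::-1]
    return x[0] if single else x


def log_density_t(w: Tensor, flow: FlowModel) -> Tensor:
    """Differentiable log p(w) per row; shape (n,)."""
    u, logdet = flow.forward_t(w)
    base = (u * u).sum(axis=1) * (-0.5) + (-0.5 * flow.d * _LOG_2PI)
    return base + logdet


def log_density(w: np.ndarray, flow: FlowModel):
    """Exact log-density of w under the flow (change of variables)."""
    wb, single = _batchify(w, flow.d)
    ld = log_density_t(Tensor(wb), flow).data
    return float(ld[0]) if single else ld


def sample(flow: FlowModel, n: int, seed: int = 0) -> np.ndarray:
    """Draw samples by inverting the flow on base-normal draws."""
    u = np.random.default_rng(seed).standard_normal((n, flow.d))
    return flow_inverse(u, flow)


def identity_flow(d: int, n_blocks: int = 2, hidden_dim: int = 8) -> FlowModel:
    """An untrained (identity) flow: log p is the standard normal density."""
    return FlowModel(d=d, n_blocks=n_blocks, hidden_dim=hidden_dim, seed=0)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_flow(samples: np.ndarray, cfg: FlowTrainConfig, d: int | None = None,
               verbose: bool = False) -> FlowModel:
    """Fit a MAF to ``samples`` (n x d) by stochastic gradient ascent on the
    average log-density (Adam, gradient-norm clipping); reproducible from
    ``cfg.seed``.  The fitted model carries ``final_nll`` (nats per sample)
    and a per-epoch NLL ``history``."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2:
        raise ValueError("samples must be a 2-D (n, d) array")
    n, d_data = samples.shape
    if d is not None and d != d_data:
        raise ValueError("d does not match the sample dimension")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples contain non-finite values")
    if cfg.epochs > 0 and n < cfg.batch_size:
        raise ValueError("need at least one full batch of samples")
    flow = FlowModel(d=d_data, n_blocks=cfg.n_blocks,
                     hidden_dim=cfg.hidden_dim, seed=cfg.seed,
                     activation=cfg.activation, alpha_clamp=cfg.alpha_clamp)
    tensors = [{k: Tensor(v, requires_grad=True) for k, v in blk.items()}
               for blk in flow.params]
    flat = [t for blk in tensors for t in blk.values()]
    opt = Adam(flat, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)

    # held-out split for early stopping; jitter scale for density smoothing
    n_val = int(round(cfg.val_fraction * n)) if cfg.epochs > 0 else 0
    perm = rng.permutation(n)
    val_set, train_set = samples[perm[:n_val]], samples[perm[n_val:]]
    n_train = len(train_set)
    per_dim_std = samples.std(axis=0)

    def _sync_params():
        for blk, tblk in zip(flow.params, tensors):
            for k in blk:
                blk[k] = tblk[k].data.copy()

    best_val, best_params = np.inf, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_train)
        epoch_nll = 0.0
        n_batches = 0
        for start in range(0, n_train - cfg.batch_size + 1, cfg.batch_size):
            xb = train_set[order[start:start + cfg.batch_size]]
            if cfg.noise_rel > 0:
                xb = xb + cfg.noise_rel * per_dim_std * rng.standard_normal(xb.shape)
            x = Tensor(xb)
            u, logdet = flow.forward_t(x, param_tensors=tensors)
            ld = (u * u).sum(axis=1) * (-0.5) + (-0.5 * d_data * _LOG_2PI) + logdet
            nll = -ld.mean()
            val = nll.item()
            if not np.isfinite(val):
                raise RuntimeError(
                    f"flow training diverged (NaN/inf NLL) at epoch {epoch}")
            nll.backward()
            opt.step(grad_clip=50.0)
            if cfg.weight_decay > 0:
                decay = 1.0 - cfg.learning_rate * cfg.weight_decay
                for blk in tensors:
                    for k in ("W1", "W2", "Wm", "Wa"):
                        blk[k].data *= decay
            epoch_nll += val
            n_batches += 1
        flow.history.append(epoch_nll / max(1, n_batches))
        if cfg.early_stop and n_val > 0 and (epoch % 5 == 4 or epoch == cfg.epochs - 1):
            _sync_params()
            val_nll = float(-np.mean(log_density(val_set, flow)))
            if val_nll < best_val:
                best_val = val_nll
                best_params = [{k: v.copy() for k, v in blk.items()}
                               for blk in flow.params]
        if verbose:
            print(f"epoch {epoch}: nll/sample = {flow.history[-1]:.4f}")
    if best_params is not None:
        flow.params = best_params
    else:
        _sync_params()

    if cfg.calibrate and cfg.epochs > 0:
        # final affine layer: per-dim z-score of f(w) on clean held-out
        # latents (training points are biased by the fit itself)
        calib_set = val_set if n_val > 0 else samples
        u_cal, _ = flow_forward(calib_set, flow)
        flow.calib_shift = u_cal.mean(axis=0)
        flow.calib_scale = u_cal.std(axis=0) + 1e-12
        if cfg.radial_calibrate:
            from scipy.stats import chi

            u_cal2, _ = flow_forward(calib_set, flow)
            radii = np.sort(np.sqrt(np.sum(u_cal2**2, axis=1)))
            n_knots = int(min(100, max(10, len(radii) // 20)))
            q = (np.arange(n_knots) + 0.5) / n_knots
            knots_r = np.quantile(radii, q)
            knots_t = chi.ppf(q, df=d_data)
            # enforce strict monotonicity for the interpolation
            eps = 1e-9
            knots_r = np.maximum.accumulate(knots_r + eps * np.arange(n_knots))
            flow.radial_r = knots_r
            flow.radial_t = knots_t
    flow.final_nll = float(-np.mean(log_density(samples[:min(n, 8192)], flow)))
    return flow


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def gaussianization_report(flow: FlowModel | None, gen: "gm.StyleGenerator",
                           n: int = 5000, seed: int = 0) -> GaussianizationReport:
    """Squared-norm diagnostic of the transformed style distribution.

    Draws n noise vectors, maps them through the generator's mapping network
    and through the flow (pass ``flow=None`` to diagnose the untransformed
    style vectors), then compares the squared-norm statistics with the
    chi-squared(d) references (mean d, variance 2d).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, gen.d))
    w = gm.map_latent(z, gen)
    u = w if flow is None else flow_forward(w, flow)[0]
    sq = np.sum(u**2, axis=1)
    return GaussianizationReport(
        n=n, sq_norms=sq, mean_sq_norm=float(sq.mean()),
        var_sq_norm=float(sq.var(ddof=1)),
        reference_mean=float(gen.d), reference_var=float(2 * gen.d))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_flow(path, flow: FlowModel) -> None:
    header = {"kind": "maf", "d": flow.d, "n_blocks": flow.n_blocks,
              "hidden_dim": flow.hidden_dim, "activation": flow.activation,
              "alpha_clamp": flow.alpha_clamp,
              "final_nll": flow.final_nll if flow.final_nll is not None else float("nan")}
    arrays = {"calib/shift": flow.calib_shift, "calib/scale": flow.calib_scale}
    if flow.radial_r is not None:
        arrays["calib/radial_r"] = flow.radial_r
        arrays["calib/radial_t"] = flow.radial_t
    for b, blk in enumerate(flow.params):
        for k, v in blk.items():
            arrays[f"block{b}/{k}"] = v
    _io.save_checkpoint(path, header, arrays)


def load_flow(path) -> FlowModel:
    header, arrays = _io.load_checkpoint(path)
    if header.get("kind") != "maf":
        raise ValueError(f"not a flow checkpoint: kind={header.get('kind')}")
    flow = FlowModel(d=int(header["d"]), n_blocks=int(header["n_blocks"]),
                     hidden_dim=int(header["hidden_dim"]),
                     activation=header.get("activation", "tanh"),
                     alpha_clamp=float(header.get("alpha_clamp", 3.0)))
    for b in range(flow.n_blocks):
        for k in flow.params[b]:
            flow.params[b][k] = arrays[f"block{b}/{k}"]
    if "calib/shift" in arrays:
        flow.calib_shift = arrays["calib/shift"]
        flow.calib_scale = arrays["calib/scale"]
    if "calib/radial_r" in arrays:
        flow.radial_r = arrays["calib/radial_r"]
        flow.radial_t = arrays["calib/radial_t"]
    nll = header.get("final_nll")
    flow.final_nll = None if nll is None or np.isnan(nll) else float(nll)
    return flow
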