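"""Style-based generator contract and two desk-scale instances.

A style-based generator is a pair (F, G): a mapping network F that turns
standard-normal noise z into a style vector w living in the intermediate
style space W, and a synthesis network G that renders an image from one style
vector per synthesis layer.  Feeding a different copy of w to every layer
extends the search space to W+ (an L x d matrix of per-layer styles), which is
what the latent search optimizes over.

Two generator kinds are provided:

``style_mini``
    A miniature frozen-weight style generator: 3-layer mapping MLP with leaky
    ReLU, and a synthesis stack of 8 style-modulated (and demodulated) 3x3
    convolutions with nearest-neighbour upsampling, a 1x1 to-RGB projection and
    a final tanh bounding the output to [-1, 1].  Weights are drawn once from
    a seed and never trained: the contribution under test is the latent
    search, not the generator weights.  The constant-Jacobian simplification
    used when the flow prior is written on w rather than on the image assumes
    a generator trained with a path-length penalty; no such penalty is applied
    here and the assumption is carried over as-is.

``linear_oracle``
    G(w) = reshape(A @ w) with a full-column-rank matrix A and F = identity.
    Linearity gives closed-form least-squares inverses, which makes this the
    independent oracle for optimizer tests.  Its output is unbounded
    (``bounded`` is False).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from . import io as _io

_LRELU_SLOPE = 0.2
# variance-restoring gain after leaky ReLU, He-style
_LRELU_GAIN = float(np.sqrt(2.0 / (1.0 + _LRELU_SLOPE**2)))


@dataclass
class StyleGenerator:
    """Frozen generator: mapping F: Z->W plus synthesis G: W+ -> image."""

    d: int
    L: int
    output_shape: tuple  # (C, H, W)
    kind: str  # "style_mini" | "linear_oracle"
    params: dict = field(repr=False)
    bounded: bool = True  # output in [-1, 1] via final tanh

    # layer index -> whether a 2x upsample precedes the conv (style_mini only)
    @property
    def upsample_before(self):
        return self.params.get("_ups")


def _check_latent(z: np.ndarray, d: int, name: str = "z") -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    if z.shape[-1] != d:
        raise ValueError(f"{name} has dimension {z.shape[-1]}, generator expects d={d}")
    if not np.all(np.isfinite(z)):
        raise ValueError(f"{name} contains non-finite entries")
    return z


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def make_style_mini(d: int = 16, size: int = 64, channels: int = 16,
                    seed: int = 0) -> StyleGenerator:
    """Build the miniature style generator with fixed random weights.

    ``size`` must be a power of two >= 4.  The synthesis stack always has
    L = 8 style-modulated convolutions; 2x upsamplings are interleaved to walk
    from the 4x4 learned constant up to ``size``.
    """
    n_ups = int(np.log2(size / 4))
    if 4 * 2**n_ups != size or n_ups < 0:
        raise ValueError("size must be a power of two >= 4")
    L = 8
    if n_ups > L - 1:
        raise ValueError("size too large for the 8-layer stack")
    rng = np.random.default_rng(seed)
    C = channels
    params: dict = {"const": rng.standard_normal((C, 4, 4))}
    # place the upsamples at odd layer indices (1, 3, 5, 7, ...)
    ups = [False] * L
    for k in range(n_ups):
        ups[2 * k + 1] = True
    params["_ups"] = np.array(ups)
    # mapping: 3 dense layers d -> d
    for i in range(3):
        params[f"map_w{i}"] = rng.standard_normal((d, d)) / np.sqrt(d)
        params[f"map_b{i}"] = 0.1 * rng.standard_normal(d)
    for l in range(L):
        params[f"style_a{l}"] = rng.standard_normal((d, C)) / np.sqrt(d)
        params[f"style_b{l}"] = np.ones(C)
        params[f"conv_w{l}"] = rng.standard_normal((C, C, 3, 3))
        params[f"conv_b{l}"] = 0.1 * rng.standard_normal(C)
    params["rgb_w"] = rng.standard_normal((3, C)) / np.sqrt(C)
    params["rgb_b"] = np.zeros(3)
    return StyleGenerator(d=d, L=L, output_shape=(3, size, size),
                          kind="style_mini", params=params, bounded=True)


def make_linear_oracle(d: int, output_shape: tuple, seed: int = 0,
                       max_retries: int = 10) -> StyleGenerator:
    """Linear generator G(w) = reshape(A @ w) with full-column-rank A."""
    output_shape = tuple(int(s) for s in output_shape)
    n_pix = int(np.prod(output_shape))
    if d > n_pix:
        raise ValueError(f"d={d} exceeds pixel count {n_pix}")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        A = rng.standard_normal((n_pix, d)) / np.sqrt(d)
        if np.linalg.matrix_rank(A) == d:
            return linear_oracle_from_matrix(A, output_shape)
    raise RuntimeError("could not draw a full-column-rank matrix")


def linear_oracle_from_matrix(A: np.ndarray, output_shape: tuple) -> StyleGenerator:
    """Wrap an explicit (n_pixels x d) matrix as a linear oracle generator."""
    A = np.asarray(A, dtype=np.float64)
    n_pix = int(np.prod(output_shape))
    if A.shape[0] != n_pix:
        raise ValueError("matrix rows must equal the pixel count")
    return StyleGenerator(d=A.shape[1], L=1, output_shape=tuple(output_shape),
                          kind="linear_oracle", params={"A": A}, bounded=False)


def oracle_matrix(gen: StyleGenerator) -> np.ndarray:
    """Expose A for closed-form computations (linear_oracle only)."""
    if gen.kind != "linear_oracle":
        raise ValueError("oracle_matrix is only defined for linear_oracle generators")
    return gen.params["A"]


# ---------------------------------------------------------------------------
# mapping network
# ---------------------------------------------------------------------------

def map_latent(z: np.ndarray, gen: StyleGenerator) -> np.ndarray:
    """Map noise z (shape (d,) or (n, d)) to style vector(s) w = F(z)."""
    z = _check_latent(z, gen.d)
    single = z.ndim == 1
    zb = z[None] if single else z
    if gen.kind == "linear_oracle":
        w = zb
    else:
        # pixel-norm then 3 dense + leaky ReLU layers
        h = zb / np.sqrt(np.mean(zb**2, axis=1, keepdims=True) + 1e-8)
        for i in range(3):
            h = h @ gen.params[f"map_w{i}"] + gen.params[f"map_b{i}"]
            h = np.where(h > 0, h, _LRELU_SLOPE * h)
        w = h
    return w[0] if single else w


def mean_latent(gen: StyleGenerator, n: int = 10000, seed: int = 0) -> np.ndarray:
    """Mean of ``n`` mapped latents F(z_i), z_i ~ N(0, I); the search init."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    total = np.zeros(gen.d)
    remaining = n
    while remaining > 0:
        batch = min(remaining, 65536)
        total += map_latent(rng.standard_normal((batch, gen.d)), gen).sum(axis=0)
        remaining -= batch
    return total / n


# ---------------------------------------------------------------------------
# synthesis network
# ---------------------------------------------------------------------------

def _as_wplus(wplus, gen: StyleGenerator) -> np.ndarray:
    wp = np.asarray(wplus if not isinstance(wplus, Tensor) else wplus.data)
    if wp.ndim == 1:
        wp = np.tile(wp, (gen.L, 1))
    if wp.shape != (gen.L, gen.d):
        raise ValueError(f"W+ must have shape ({gen.L}, {gen.d}), got {wp.shape}")
    return wp


def synthesize_t(wplus: Tensor, gen: StyleGenerator) -> Tensor:
    """Differentiable synthesis G(W+); ``wplus`` is an (L, d) Tensor."""
    if wplus.data.shape != (gen.L, gen.d):
        raise ValueError(f"W+ must have shape ({gen.L}, {gen.d}), got {wplus.data.shape}")
    p = gen.params
    if gen.kind == "linear_oracle":
        A = Tensor(p["A"])
        w_row = wplus.reshape(gen.d, 1)
        return (A @ w_row).reshape(gen.output_shape)
    x = Tensor(p["const"])
    C = p["const"].shape[0]
    for l in range(gen.L):
        if p["_ups"][l]:
            x = x.upsample2x()
        w_l = wplus.reshape(gen.L, gen.d)  # keep graph simple; slice via matmul
        sel = np.zeros((1, gen.L))
        sel[0, l] = 1.0
        wl = (Tensor(sel) @ w_l)  # (1, d)
        s = wl @ Tensor(p[f"style_a{l}"]) + Tensor(p[f"style_b{l}"])  # (1, C)
        wmod = Tensor(p[f"conv_w{l}"]) * s.reshape(1, C, 1, 1)
        denom = (wmod * wmod).sum(axis=(1, 2, 3), keepdims=True) + 1e-8
        wdem = wmod * denom.pow(-0.5)
        x = x.conv3x3(wdem) + Tensor(p[f"conv_b{l}"].reshape(C, 1, 1))
        x = x.leaky_relu(_LRELU_SLOPE) * _LRELU_GAIN
    _, H, W = gen.output_shape
    flat = x.reshape(C, H * W)
    rgb = (Tensor(p["rgb_w"]) @ flat) + Tensor(p["rgb_b"].reshape(3, 1))
    return rgb.reshape(3, H, W).tanh()


def synthesize(wplus, gen: StyleGenerator) -> np.ndarray:
    """Render an image from an extended latent (L x d) or a single w (d,).

    Deterministic given (wplus, generator); style_mini output lies in [-1, 1].
    """
    wp = _as_wplus(wplus, gen)
    return synthesize_t(Tensor(wp), gen).data


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_generator(path, gen: StyleGenerator) -> None:
    header = {"kind": gen.kind, "d": gen.d, "L": gen.L,
              "output_shape": list(gen.output_shape), "bounded": gen.bounded}
    _io.save_checkpoint(path, header, {k: v for k, v in gen.params.items()})


def load_generator(path) -> StyleGenerator:
    header, arrays = _io.load_checkpoint(path)
    if header["kind"] not in ("style_mini", "linear_oracle"):
        raise ValueError(f"not a generator checkpoint: kind={header['kind']}")
    if "_ups" in arrays:
        arrays["_ups"] = arrays["_ups"].astype(bool)
    return StyleGenerator(d=int(header["d"]), L=int(header["L"]),
                          output_shape=tuple(header["output_shape"]),
                          kind=header["kind"], params=arrays,
                          bounded=bool(header["bounded"]))
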