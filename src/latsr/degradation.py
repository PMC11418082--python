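"""Forward degradation operators relating HR to LR images.

The reconstruction problem assumes a known, non-invertible forward operator D
mapping the HR image to the observed LR image.  The canonical D is antialiased
bicubic downscaling; for robustness experiments the observed LR image can
additionally be corrupted with Gaussian noise, salt-and-pepper noise or
Gaussian blur (corruptions are applied AFTER the downscale, i.e. to the LR
observation).

Bicubic dialect (fixed so the data term is bit-reproducible): Keys kernel with
a = -0.5 (Catmull-Rom), kernel support stretched by the scale factor on
downscale (antialiasing), half-sample symmetric boundary handling, rows
normalized to sum to one.  Downscaling is linear in the image and is exposed
to the optimizer as two constant factor matrices (one per axis), which makes
it exactly differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ALLOWED = {"bicubic_downscale", "gaussian_noise", "salt_pepper", "gaussian_blur"}


@dataclass
class ForwardOperator:
    """Ordered list of degradation steps; at most one downscale."""

    steps: list = field(default_factory=list)

    def __post_init__(self):
        kinds = [k for k, _ in self.steps]
        unknown = set(kinds) - _ALLOWED
        if unknown:
            raise ValueError(f"unknown degradation steps: {sorted(unknown)}")
        if kinds.count("bicubic_downscale") > 1:
            raise ValueError("at most one downscale step is allowed")
        for k, p in self.steps:
            if k == "bicubic_downscale":
                f = int(p["factor"])
                if f < 1 or (f & (f - 1)) != 0 or f > 32:
                    raise ValueError("downscale factor must be a power of 2 in 1..32")

    @property
    def factor(self) -> int:
        for k, p in self.steps:
            if k == "bicubic_downscale":
                return int(p["factor"])
        return 1


def downscale_operator(factor: int) -> ForwardOperator:
    return ForwardOperator([("bicubic_downscale", {"factor": int(factor)})])


def parse_operator(spec: str) -> ForwardOperator:
    """Parse e.g. ``"bicubic:16,gauss:0.05,sp:0.02,blur:1.0"``.

    Noise steps accept an optional seed: ``gauss:0.05:7``.
    """
    steps = []
    for tok in spec.split(","):
        if not tok.strip():
            continue
        parts = tok.strip().split(":")
        name, args = parts[0], parts[1:]
        if name in ("bicubic", "down"):
            steps.append(("bicubic_downscale", {"factor": int(args[0])}))
        elif name in ("gauss", "gaussian"):
            steps.append(("gaussian_noise", {"sigma": float(args[0]),
                                             "seed": int(args[1]) if len(args) > 1 else 0}))
        elif name in ("sp", "salt_pepper"):
            steps.append(("salt_pepper", {"p": float(args[0]),
                                          "seed": int(args[1]) if len(args) > 1 else 0}))
        elif name == "blur":
            steps.append(("gaussian_blur", {"sigma": float(args[0])}))
        else:
            raise ValueError(f"unknown degradation token: {tok!r}")
    return ForwardOperator(steps)


# ---------------------------------------------------------------------------
# kernels and factor matrices
# ---------------------------------------------------------------------------

def keys_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """The Keys cubic interpolation kernel (support |t| < 2)."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(t)
    m1 = t <= 1
    out[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    m2 = (t > 1) & (t < 2)
    out[m2] = a * t[m2] ** 3 - 5 * a * t[m2] ** 2 + 8 * a * t[m2] - 4 * a
    return out


def _fold_reflect(idx: np.ndarray, n: int) -> np.ndarray:
    """Half-sample symmetric index folding (... 1 0 | 0 1 ... n-1 | n-1 ...)."""
    idx = np.asarray(idx)
    period = 2 * n
    idx = np.mod(idx, period)
    return np.where(idx >= n, period - 1 - idx, idx)


def downscale_matrix(n: int, factor: int) -> np.ndarray:
    """(n/factor x n) antialiased bicubic downscale matrix for one axis."""
    if n % factor != 0:
        raise ValueError(f"size {n} not divisible by factor {factor}")
    m = n // factor
    M = np.zeros((m, n))
    for i in range(m):
        c = (i + 0.5) * factor - 0.5
        j0 = int(np.ceil(c - 2 * factor))
        j1 = int(np.floor(c + 2 * factor))
        js = np.arange(j0, j1 + 1)
        w = keys_kernel((js - c) / factor) / factor
        np.add.at(M[i], _fold_reflect(js, n), w)
        M[i] /= M[i].sum()
    return M


def upscale_matrix(n: int, factor: int) -> np.ndarray:
    """(n*factor x n) bicubic interpolation matrix (no antialiasing)."""
    m = n * factor
    M = np.zeros((m, n))
    for i in range(m):
        c = (i + 0.5) / factor - 0.5
        js = np.arange(int(np.floor(c)) - 1, int(np.floor(c)) + 3)
        w = keys_kernel(js - c)
        np.add.at(M[i], _fold_reflect(js, n), w)
        M[i] /= M[i].sum()
    return M


def blur_matrix(n: int, sigma: float) -> np.ndarray:
    """(n x n) Gaussian blur matrix, radius ceil(3*sigma), reflect padding."""
    if sigma <= 0:
        return np.eye(n)
    r = int(np.ceil(3 * sigma))
    offs = np.arange(-r, r + 1)
    k = np.exp(-0.5 * (offs / sigma) ** 2)
    k /= k.sum()
    M = np.zeros((n, n))
    for i in range(n):
        np.add.at(M[i], _fold_reflect(i + offs, n), k)
    return M


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def bicubic_downscale(img: np.ndarray, factor: int) -> np.ndarray:
    """Antialiased bicubic downscale of a (C, H, W) image by ``factor``."""
    img = np.asarray(img, dtype=np.float64)
    factor = int(factor)
    if factor == 1:
        return img.copy()
    _, H, W = img.shape
    Mh = downscale_matrix(H, factor)
    Mw = downscale_matrix(W, factor)
    return np.einsum("ij,cjk,lk->cil", Mh, img, Mw, optimize=True)


def bicubic_upscale(img: np.ndarray, factor: int) -> np.ndarray:
    """Plain bicubic upsampling; the baseline comparator, not the inverse of D."""
    img = np.asarray(img, dtype=np.float64)
    if factor == 1:
        return img.copy()
    _, H, W = img.shape
    return np.einsum("ij,cjk,lk->cil", upscale_matrix(H, factor), img,
                     upscale_matrix(W, factor), optimize=True)


def add_gaussian_noise(img: np.ndarray, sigma: float, seed: int = 0,
                       clip: bool = True) -> np.ndarray:
    """Additive pixelwise N(0, sigma^2) noise, clipped to [-1, 1] by default."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = np.asarray(img, dtype=np.float64)
    if sigma == 0:
        return img.copy()
    out = img + np.random.default_rng(seed).normal(0.0, sigma, size=img.shape)
    return np.clip(out, -1.0, 1.0) if clip else out


def add_salt_pepper(img: np.ndarray, p: float, seed: int = 0) -> np.ndarray:
    """Replace each element by -1 or +1 (equal odds) with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    img = np.asarray(img, dtype=np.float64)
    rng = np.random.default_rng(seed)
    hit = rng.random(img.shape) < p
    salt = rng.random(img.shape) < 0.5
    return np.where(hit, np.where(salt, 1.0, -1.0), img)


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur, kernel radius ceil(3*sigma), reflect padding."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = np.asarray(img, dtype=np.float64)
    if sigma == 0:
        return img.copy()
    _, H, W = img.shape
    return np.einsum("ij,cjk,lk->cil", blur_matrix(H, sigma), img,
                     blur_matrix(W, sigma), optimize=True)


def apply_operator(op: ForwardOperator, img: np.ndarray) -> np.ndarray:
    """Apply all steps in order (corruptions act on the downscaled image)."""
    out = np.asarray(img, dtype=np.float64).copy()
    for kind, p in op.steps:
        if kind == "bicubic_downscale":
            out = bicubic_downscale(out, p["factor"])
        elif kind == "gaussian_noise":
            out = add_gaussian_noise(out, p["sigma"], p.get("seed", 0),
                                     p.get("clip", True))
        elif kind == "salt_pepper":
            out = add_salt_pepper(out, p["p"], p.get("seed", 0))
        elif kind == "gaussian_blur":
            out = gaussian_blur(out, p["sigma"])
    return out


def deterministic_matrices(op: ForwardOperator, in_shape: tuple):
    """Factor matrices for the deterministic steps (downscale, blur).

    Stochastic corruption steps model unknown acquisition noise on the LR
    observation; they are not part of the reconstruction forward model and are
    skipped here.  Returns a list of (Mh, Mw) pairs plus the output shape.
    """
    C, H, W = in_shape
    mats = []
    for kind, p in op.steps:
        if kind == "bicubic_downscale":
            f = int(p["factor"])
            if f > 1:
                mats.append((downscale_matrix(H, f), downscale_matrix(W, f)))
                H, W = H // f, W // f
        elif kind == "gaussian_blur":
            if p["sigma"] > 0:
                mats.append((blur_matrix(H, p["sigma"]), blur_matrix(W, p["sigma"])))
    return mats, (C, H, W)
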