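"""End-to-end experiment drivers.

These functions assemble the package's modules into the studied workflows:
flow training on mapped style vectors, self-inversion benchmarks on in-range
targets, prior-ablation and robustness sweeps, and the two-step
"super-resolve then quantify" assay.  The CLI, the test suite and the
reproduction script all call these, so every reported number comes from one
code path.

For the two-step assay the generator must be able to render phenotypes, which
a frozen random-weight generator cannot.  ``build_image_basis_generator``
therefore fits an orthonormal linear basis (uncentered PCA, columns rescaled
to unit coefficient RMS) to a set of rendered cells and wraps it as a
linear-oracle generator: its range spans phenotype-bearing images, in-range
HR targets are the rank-d projections, and the flow is trained on the
projection coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import degradation as dg
from . import generator_models as gm
from . import io as _io
from . import normalizing_flow as nf
from . import quantify as qt
from . import rls_optimizer as rls
from . import synthetic_microscopy as sm

DESK_FLOW_CONFIG = nf.FlowTrainConfig(n_blocks=5, hidden_dim=64,
                                      n_samples=20000, epochs=120,
                                      batch_size=256, learning_rate=1e-3)

DESK_RLS_CONFIG = rls.RLSConfig(learning_rate=0.2, lr_schedule="cosine")


def train_style_flow(gen: gm.StyleGenerator,
                     cfg: nf.FlowTrainConfig | None = None,
                     seed: int = 0) -> nf.FlowModel:
    """Train a flow on style vectors mapped from seeded normal noise."""
    cfg = cfg or replace(DESK_FLOW_CONFIG, seed=seed)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((cfg.n_samples, gen.d))
    w = gm.map_latent(z, gen)
    return nf.train_flow(w, cfg)


# ---------------------------------------------------------------------------
# self-inversion benchmark (in-range targets)
# ---------------------------------------------------------------------------

@dataclass
class InversionTrial:
    psnr_sr: float
    psnr_bicubic: float
    data_term: float
    initial_total: float
    final_total: float
    ms_ssim_sr: float = float("nan")


def self_inversion_trial(gen: gm.StyleGenerator, flow: nf.FlowModel,
                         factor: int, seed: int,
                         rls_cfg: rls.RLSConfig | None = None,
                         with_ms_ssim: bool = False) -> InversionTrial:
    """One in-range target: HR = G(w*), LR = bicubic downscale, then RLS.

    The SR image is compared against the ground-truth HR in PSNR; plain
    bicubic upsampling of the LR image is the baseline.
    """
    rls_cfg = replace(rls_cfg or rls.RLSConfig(), seed=seed)
    rng = np.random.default_rng(seed)
    w_star = gm.map_latent(rng.standard_normal(gen.d), gen)
    hr = gm.synthesize(w_star, gen)
    op = dg.downscale_operator(factor)
    lr = dg.apply_operator(op, hr)
    res = rls.superresolve(lr, gen, op, flow, rls_cfg)
    hr01 = _io.from_internal(hr)
    sr01 = _io.from_internal(res.sr_image)
    up01 = _io.from_internal(dg.bicubic_upscale(lr, factor))
    return InversionTrial(
        psnr_sr=qt.psnr(hr01, sr01), psnr_bicubic=qt.psnr(hr01, up01),
        data_term=res.data_term, initial_total=float(res.loss_trace[0]),
        final_total=float(res.loss_trace.min()),
        ms_ssim_sr=qt.ms_ssim(hr01, sr01) if with_ms_ssim else float("nan"))


def self_inversion_experiment(gen: gm.StyleGenerator, flow: nf.FlowModel,
                              factor: int, n_trials: int = 20, seed: int = 0,
                              rls_cfg: rls.RLSConfig | None = None) -> dict:
    trials = [self_inversion_trial(gen, flow, factor, seed + 1000 * (i + 1), rls_cfg)
              for i in range(n_trials)]
    return {
        "trials": trials,
        "median_psnr_sr": float(np.median([t.psnr_sr for t in trials])),
        "median_psnr_bicubic": float(np.median([t.psnr_bicubic for t in trials])),
        "median_data_term": float(np.median([t.data_term for t in trials])),
    }


# ---------------------------------------------------------------------------
# robustness to LR corruptions
# ---------------------------------------------------------------------------

CORRUPTIONS = {
    "gaussian_noise": ("gaussian_noise", {"sigma": 0.05}),
    "salt_pepper": ("salt_pepper", {"p": 0.02}),
    "gaussian_blur": ("gaussian_blur", {"sigma": 1.0}),
}


def robustness_experiment(gen: gm.StyleGenerator, flow: nf.FlowModel,
                          factor: int, n_targets: int = 8, seed: int = 0,
                          rls_cfg: rls.RLSConfig | None = None) -> dict:
    """Reconstruct in-range targets from corrupted LR observations.

    Corruptions are applied to the bicubic-downscaled observation; the
    reconstruction forward model remains the clean downscale.  Fidelity is
    measured as the L1 error between D(SR) and the CLEAN LR image, and the
    per-corruption medians are reported as ratios to the uncorrupted case.
    """
    base_cfg = rls_cfg or rls.RLSConfig()
    op = dg.downscale_operator(factor)
    clean_terms = []
    corr_terms: dict[str, list] = {k: [] for k in CORRUPTIONS}
    for i in range(n_targets):
        s = seed + 1000 * (i + 1)
        rng = np.random.default_rng(s)
        hr = gm.synthesize(gm.map_latent(rng.standard_normal(gen.d), gen), gen)
        lr_clean = dg.apply_operator(op, hr)

        def clean_data_term(res):
            return float(np.mean(np.abs(
                dg.bicubic_downscale(res.sr_image, factor) - lr_clean)))

        res0 = rls.superresolve(lr_clean, gen, op, flow, replace(base_cfg, seed=s))
        clean_terms.append(clean_data_term(res0))
        for name, (kind, pars) in CORRUPTIONS.items():
            step_op = dg.ForwardOperator([(kind, dict(pars, seed=s))]
                                         if kind != "gaussian_blur"
                                         else [(kind, dict(pars))])
            lr_corr = dg.apply_operator(step_op, lr_clean)
            res = rls.superresolve(lr_corr, gen, op, flow, replace(base_cfg, seed=s))
            corr_terms[name].append(clean_data_term(res))
    med_clean = float(np.median(clean_terms))
    return {
        "median_clean_term": med_clean,
        "median_corrupted_terms": {k: float(np.median(v)) for k, v in corr_terms.items()},
        "ratios": {k: float(np.median(v)) / med_clean for k, v in corr_terms.items()},
    }


# ---------------------------------------------------------------------------
# prior ablations
# ---------------------------------------------------------------------------

def ablation_experiment(gen: gm.StyleGenerator, flow: nf.FlowModel,
                        factor: int, n_trials: int = 20, seed: int = 0,
                        rls_cfg: rls.RLSConfig | None = None) -> dict:
    """Median per-variant flow NLL of recovered latents over fixed-seed trials."""
    base_cfg = rls_cfg or rls.RLSConfig()
    op = dg.downscale_operator(factor)
    nlls: dict[str, list] = {k: [] for k in rls.VARIANTS}
    data_terms: dict[str, list] = {k: [] for k in rls.VARIANTS}
    init_data_spread = 0.0
    for i in range(n_trials):
        s = seed + 1000 * (i + 1)
        rng = np.random.default_rng(s)
        hr = gm.synthesize(gm.map_latent(rng.standard_normal(gen.d), gen), gen)
        lr = dg.apply_operator(op, hr)
        out = rls.run_ablation_suite(lr, gen, op, flow, replace(base_cfg, seed=s))
        init_terms = [out[k].result.term_trace[0, 0] for k in out]
        init_data_spread = max(init_data_spread,
                               float(np.ptp(init_terms)))
        for k, o in out.items():
            nlls[k].append(o.flow_nll)
            data_terms[k].append(o.result.data_term)
    return {
        "median_flow_nll": {k: float(np.median(v)) for k, v in nlls.items()},
        "median_data_term": {k: float(np.median(v)) for k, v in data_terms.items()},
        "max_init_data_spread": init_data_spread,
    }


# ---------------------------------------------------------------------------
# two-step workflow: render -> basis generator -> RLS -> quantify -> classify
# ---------------------------------------------------------------------------

def build_image_basis_generator(images01: np.ndarray, d: int):
    """Fit an orthogonal linear basis to images and wrap it as a generator.

    ``images01``: (N, C, H, W) in [0, 1].  Returns (generator, coefficients)
    where coefficients is the (N, d) matrix of per-image latents in the
    whitened basis (unit coefficient RMS per dimension).
    """
    X = _io.to_internal(images01).reshape(len(images01), -1)  # (N, P)
    U, s, _ = np.linalg.svd(X.T, full_matrices=False)
    if d > U.shape[1]:
        raise ValueError(f"d={d} exceeds the available rank {U.shape[1]}")
    A = U[:, :d]
    coeff = X @ A  # (N, d)
    scale = np.sqrt(np.mean(coeff**2, axis=0)) + 1e-12
    A_whitened = A * scale[None, :]
    w = coeff / scale[None, :]
    gen = gm.linear_oracle_from_matrix(A_whitened, images01.shape[1:])
    return gen, w


@dataclass
class TwoStepResult:
    assay: str
    accuracy_hr: float
    accuracy_sr: float
    threshold_hr: float
    threshold_sr: float
    features_hr: dict = field(repr=False, default_factory=dict)
    features_sr: dict = field(repr=False, default_factory=dict)
    n_failed: int = 0


def _feature_fn(assay: str):
    if assay == "translocation":
        return lambda img01: qt.translocation_ratio(img01).value
    return lambda img01: qt.mean_spot_area(img01).value


def two_step_experiment(assay: str = "translocation", n_per_condition: int = 100,
                        size: int = 64, factor: int = 4, basis_dim: int = 48,
                        seed: int = 0, rls_cfg: rls.RLSConfig | None = None,
                        flow_cfg: nf.FlowTrainConfig | None = None) -> TwoStepResult:
    """The headline workflow: SR by latent search, then interpretable features.

    Renders ``n_per_condition`` negative- and positive-control cells, builds
    the image-basis generator, takes the rank-d projections as in-range HR
    targets, downscales them, reconstructs with RLS, and measures the assay
    feature on both HR and SR images.  Reports the two-condition
    threshold-classification balanced accuracy from HR and from SR features.
    """
    if assay == "translocation":
        neg, pos = sm.DMSO_TRANSLOCATION, sm.TREATED_TRANSLOCATION
    elif assay == "golgi":
        neg, pos = sm.DMSO_GOLGI, sm.TREATED_GOLGI
    else:
        raise ValueError("assay must be 'translocation' or 'golgi'")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for cond, preset in (("dmso", neg), ("treated", pos)):
        for _ in range(n_per_condition):
            p = replace(preset, seed=int(rng.integers(0, 2**31 - 1)))
            img, _ = sm.render_cell(p, size=size)
            images.append(img)
            labels.append(cond)
    images = np.asarray(images)
    labels = np.asarray(labels)

    gen, w_all = build_image_basis_generator(images, basis_dim)
    flow_cfg = flow_cfg or nf.FlowTrainConfig(
        n_blocks=2, hidden_dim=64, n_samples=len(w_all), epochs=80,
        batch_size=min(32, len(w_all)), learning_rate=1e-3, seed=seed)
    flow = nf.train_flow(w_all, flow_cfg)
    base_cfg = rls_cfg or replace(rls.RLSConfig(), iterations=80)
    op = dg.downscale_operator(factor)
    fam = _feature_fn(assay)

    feats_hr: dict[str, list] = {"dmso": [], "treated": []}
    feats_sr: dict[str, list] = {"dmso": [], "treated": []}
    n_failed = 0
    for i, (w_i, cond) in enumerate(zip(w_all, labels)):
        hr = gm.synthesize(w_i, gen)  # rank-d in-range target, internal range
        lr = dg.apply_operator(op, hr)
        res = rls.superresolve(lr, gen, op, flow,
                               replace(base_cfg, seed=seed + i))
        hr01 = _io.from_internal(hr)
        sr01 = _io.from_internal(res.sr_image)
        try:
            feats_hr[cond].append(fam(hr01))
            feats_sr[cond].append(fam(sr01))
        except ValueError:
            n_failed += 1
    thr_hr, acc_hr = qt.threshold_classify(feats_hr["dmso"], feats_hr["treated"])
    thr_sr, acc_sr = qt.threshold_classify(feats_sr["dmso"], feats_sr["treated"])
    return TwoStepResult(assay=assay, accuracy_hr=acc_hr, accuracy_sr=acc_sr,
                         threshold_hr=thr_hr, threshold_sr=thr_sr,
                         features_hr=feats_hr, features_sr=feats_sr,
                         n_failed=n_failed)
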