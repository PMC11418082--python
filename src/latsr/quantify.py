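"""Interpretable feature extraction and reference image metrics.

This is the "second step" of the two-step workflow: after super-resolution,
phenotypes are quantified with handcrafted, auditable measurements rather
than a learned classifier.

* ``translocation_ratio`` — nucleocytoplasmic reporter ratio.  The nucleus is
  segmented from the DNA channel (Otsu on the smoothed channel, largest
  component, holes filled); the cytoplasm is a morphological ring around it.
* ``mean_spot_area`` — mean connected-component area of the thresholded
  reporter channel within the cell mask; reports Golgi scattering (many small
  spots vs one large blob).
* ``psnr`` / ``ms_ssim`` — standard reference metrics on [0, 1] images.
* ``threshold_classify`` — a transparent two-condition rule: threshold at the
  midpoint of the class medians, scored by balanced accuracy.

Segmentation recipes (smoothing sigma, ring width, minimum spot area) are
deliberate, fixed defaults exposed as keyword arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_fill_holes, gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk


@dataclass
class FeatureResult:
    value: float
    n_objects: int = 0
    masks_used: dict = field(default_factory=dict, repr=False)


@dataclass
class MetricPair:
    psnr_db: float
    ms_ssim: float
    l1: float


# ---------------------------------------------------------------------------
# segmentation helpers
# ---------------------------------------------------------------------------

def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab = label(mask, connectivity=2)
    if lab.max() == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == np.argmax(sizes)


def _segment_nucleus(dna: np.ndarray, smooth_sigma: float) -> np.ndarray:
    sm = gaussian_filter(dna, smooth_sigma)
    if sm.max() - sm.min() < 1e-6:
        return np.zeros_like(sm, dtype=bool)
    mask = sm > threshold_otsu(sm)
    return binary_fill_holes(_largest_component(mask))


# ---------------------------------------------------------------------------
# interpretable features
# ---------------------------------------------------------------------------

def translocation_ratio(img: np.ndarray, ring_width: int = 4,
                        smooth_sigma: float = 1.0, eps: float = 1e-6) -> FeatureResult:
    """Nucleocytoplasmic reporter ratio of a 3-channel image.

    Channel 0 is the DNA stain, channel 1 the reporter.  Ratio > 1 indicates
    nuclear accumulation (treated-like), < 1 cytoplasmic retention.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[0] < 2:
        raise ValueError("expected a (C>=2, H, W) image")
    nucleus = _segment_nucleus(img[0], smooth_sigma)
    if not nucleus.any():
        raise ValueError("no nucleus detected")
    ring = binary_dilation(nucleus, structure=disk(ring_width)) & ~nucleus
    reporter = img[1]
    value = (reporter[nucleus].mean() + eps) / (reporter[ring].mean() + eps)
    return FeatureResult(value=float(value), n_objects=1,
                         masks_used={"nucleus": nucleus, "cytoplasm": ring})


def mean_spot_area(img: np.ndarray, min_area: int = 2,
                   smooth_sigma: float = 0.0) -> FeatureResult:
    """Mean connected-component area (px) of the reporter channel spots.

    Channel 1 is thresholded at its Otsu level within the cell mask (derived
    from channel 2); components with 8-connectivity below ``min_area`` pixels
    are discarded.  An empty reporter yields value 0 with 0 objects.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[0] < 3:
        raise ValueError("expected a (C>=3, H, W) image")
    cell = binary_fill_holes(_largest_component(
        img[2] > threshold_otsu(img[2]))) if np.ptp(img[2]) > 1e-6 else None
    reporter = gaussian_filter(img[1], smooth_sigma) if smooth_sigma > 0 else img[1]
    region = reporter[cell] if cell is not None else reporter.ravel()
    if region.size == 0 or region.max() - region.min() < 1e-6:
        return FeatureResult(value=0.0, n_objects=0)
    thr = threshold_otsu(region)
    bw = reporter > thr
    if cell is not None:
        bw &= cell
    lab = label(bw, connectivity=2)
    areas = [p.area for p in regionprops(lab) if p.area >= min_area]
    if not areas:
        return FeatureResult(value=0.0, n_objects=0, masks_used={"labels": lab})
    return FeatureResult(value=float(np.mean(areas)), n_objects=len(areas),
                         masks_used={"labels": lab})


# ---------------------------------------------------------------------------
# reference metrics ([0, 1] images)
# ---------------------------------------------------------------------------

def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB (range 1), capped at 100 dB."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((a - b) ** 2))
    if mse < 1e-10:
        return 100.0
    return float(10.0 * np.log10(1.0 / mse))


_MS_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])
_WIN = 11
_WIN_SIGMA = 1.5


def _gauss_win() -> np.ndarray:
    ax = np.arange(_WIN) - _WIN // 2
    g = np.exp(-0.5 * (ax / _WIN_SIGMA) ** 2)
    g /= g.sum()
    return np.outer(g, g)


def _filter2(x: np.ndarray, win: np.ndarray) -> np.ndarray:
    from scipy.ndimage import correlate

    return correlate(x, win, mode="reflect")


def _ssim_cs(x: np.ndarray, y: np.ndarray, k1=0.01, k2=0.03):
    c1, c2 = (k1 * 1.0) ** 2, (k2 * 1.0) ** 2
    win = _gauss_win()
    mx, my = _filter2(x, win), _filter2(y, win)
    sxx = _filter2(x * x, win) - mx * mx
    syy = _filter2(y * y, win) - my * my
    sxy = _filter2(x * y, win) - mx * my
    cs_map = (2 * sxy + c2) / (sxx + syy + c2)
    ssim_map = ((2 * mx * my + c1) / (mx * mx + my * my + c1)) * cs_map
    return float(ssim_map.mean()), float(cs_map.mean())


def _downsample2(x: np.ndarray) -> np.ndarray:
    h, w = x.shape[0] // 2 * 2, x.shape[1] // 2 * 2
    return x[:h, :w].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def ms_ssim(a: np.ndarray, b: np.ndarray, max_scales: int = 5) -> float:
    """Multi-scale SSIM on [0, 1] images (Gaussian 11x11 window, sigma 1.5,
    standard scale weights, dyadic downsampling).

    For small images the number of scales is reduced so the coarsest scale
    still fits the window, and the weights are renormalized.  Per-scale
    contrast terms are floored at 0 before the weighted geometric mean, so
    the score lies in [0, 1] and equals 1 iff the inputs are identical.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if a.ndim == 3:
        return float(np.mean([ms_ssim(a[c], b[c], max_scales) for c in range(a.shape[0])]))
    side = min(a.shape)
    scales = min(max_scales, int(np.floor(np.log2(side / _WIN))) + 1)
    if scales < 1:
        raise ValueError(f"image side {side} smaller than the {_WIN}px window")
    weights = _MS_WEIGHTS[:scales] / _MS_WEIGHTS[:scales].sum()
    vals = []
    x, y = a, b
    for j in range(scales):
        s, cs = _ssim_cs(x, y)
        vals.append(s if j == scales - 1 else cs)
        if j < scales - 1:
            x, y = _downsample2(x), _downsample2(y)
    vals = np.maximum(np.asarray(vals), 0.0)
    return float(np.prod(vals**weights))


def compare(a: np.ndarray, b: np.ndarray) -> MetricPair:
    """PSNR / MS-SSIM / mean-absolute-error between two [0, 1] images."""
    return MetricPair(psnr_db=psnr(a, b), ms_ssim=ms_ssim(a, b),
                      l1=float(np.mean(np.abs(np.asarray(a) - np.asarray(b)))))


# ---------------------------------------------------------------------------
# two-condition threshold classification
# ---------------------------------------------------------------------------

def threshold_classify(values_a, values_b):
    """Midpoint-of-medians threshold rule scored by balanced accuracy.

    Returns (threshold, balanced_accuracy) of the rule induced on the given
    samples; class b is predicted on the side of its median.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both classes must be nonempty")
    med_a, med_b = np.median(a), np.median(b)
    thr = 0.5 * (med_a + med_b)
    if med_b >= med_a:
        acc = 0.5 * (np.mean(a <= thr) + np.mean(b > thr))
    else:
        acc = 0.5 * (np.mean(a > thr) + np.mean(b <= thr))
    return float(thr), float(acc)
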