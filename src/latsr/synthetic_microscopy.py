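"""Synthetic cell-painting-style single-cell crops with controllable phenotypes.

Generates 3-channel fluorescence crops centered on a nucleus, emulating the
kind of drug-treatment single-cell data the method targets: channel 0 is the
DNA stain (a soft-edged nuclear ellipse), channel 1 a phenotype reporter and
channel 2 the cell body stain.  Two assays are parameterized:

``translocation``
    The reporter redistributes between cytoplasm and nucleus with fraction
    ``t``: t=0 is fully cytoplasmic (untreated-like), t=1 fully nuclear
    (cytokine-treated-like).  The true nuclear/cytoplasmic contrast is
    strictly monotone in t when noise is off.

``golgi``
    The reporter is ``n_spots`` perinuclear discs of radius ``spot_radius``:
    one large compact blob mimics an intact Golgi, many small discs mimic
    drug-induced scattering into ministacks.

Noise follows the standard fluorescence camera model: Poisson shot noise at
``photon_scale`` photons per unit intensity, then additive Gaussian read
noise.  Set ``photon_scale=0`` (and ``read_noise=0``) for noiseless renders.
Everything is deterministic given the seed.  Images are written/returned in
[0, 1] (file-boundary convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter


@dataclass
class PhenotypeParams:
    assay: str = "translocation"  # "translocation" | "golgi"
    t: float = 0.5  # translocation fraction in [0, 1]
    n_spots: int = 1
    spot_radius: float = 5.0
    nucleus_radius: float = 8.0
    cell_radius: float = 22.0
    jitter: float = 2.0  # px, random offset of the cell center
    photon_scale: float = 200.0  # photons per unit intensity; 0 disables shot noise
    read_noise: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.assay not in ("translocation", "golgi"):
            raise ValueError("assay must be 'translocation' or 'golgi'")
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("t must be in [0, 1]")
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError("nucleus_radius must be < cell_radius")


@dataclass
class SceneTruth:
    """Exact rendered geometry, for feature-extractor tests."""

    nucleus_mask: np.ndarray = field(repr=False)
    cell_mask: np.ndarray = field(repr=False)
    spot_centers: list = field(default_factory=list)
    spot_areas: list = field(default_factory=list)


# condition presets mirroring the negative/positive controls of the assays
DMSO_TRANSLOCATION = PhenotypeParams(assay="translocation", t=0.1)
TREATED_TRANSLOCATION = PhenotypeParams(assay="translocation", t=0.9)
DMSO_GOLGI = PhenotypeParams(assay="golgi", n_spots=1, spot_radius=5.0)
TREATED_GOLGI = PhenotypeParams(assay="golgi", n_spots=8, spot_radius=1.5)


def _ellipse_mask(size: int, center, radii, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - center[0], xx - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return (u / radii[1]) ** 2 + (v / radii[0]) ** 2 <= 1.0


def _disc_mask(size: int, center, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def render_cell(params: PhenotypeParams, size: int = 64):
    """Render one cell; returns (image (3, size, size) in [0, 1], SceneTruth)."""
    import warnings as _warnings

    # radii jitter up to 1.1x and centers up to `jitter` px, so the cell needs
    # about 2.4x its nominal radius of canvas to stay clear of the border
    if size < 2.4 * params.cell_radius:
        _warnings.warn("canvas smaller than 2.4x cell_radius; cell may clip",
                       stacklevel=2)
    rng = np.random.default_rng(params.seed)
    center = np.array([size / 2.0, size / 2.0]) + params.jitter * rng.uniform(-1, 1, 2)
    cell_radii = params.cell_radius * (1.0 + 0.10 * rng.uniform(-1, 1, 2))
    cell_theta = rng.uniform(0, np.pi)
    nuc_offset = 0.15 * params.nucleus_radius * rng.uniform(-1, 1, 2)
    nuc_center = center + nuc_offset
    nuc_radii = params.nucleus_radius * (1.0 + 0.15 * rng.uniform(-1, 1, 2))
    nuc_theta = rng.uniform(0, np.pi)

    cell_mask = _ellipse_mask(size, center, cell_radii, cell_theta)
    nucleus_mask = _ellipse_mask(size, nuc_center, nuc_radii, nuc_theta) & cell_mask
    cyto_mask = cell_mask & ~nucleus_mask

    soft_nuc = gaussian_filter(nucleus_mask.astype(float), 1.0)
    soft_cell = gaussian_filter(cell_mask.astype(float), 1.0)
    soft_cyto = gaussian_filter(cyto_mask.astype(float), 1.0)

    texture = gaussian_filter(rng.standard_normal((size, size)), 3.0)
    texture = 1.0 + 0.25 * texture / (np.abs(texture).max() + 1e-9)

    dna = 0.9 * soft_nuc
    body = 0.6 * soft_cell * texture

    spot_centers: list = []
    spot_areas: list = []
    if params.assay == "translocation":
        reporter = 0.8 * (params.t * soft_nuc + (1.0 - params.t) * soft_cyto)
    else:
        spots = np.zeros((size, size), dtype=bool)
        nuc_r_eff = float(np.mean(nuc_radii))
        min_sep = 2.0 * params.spot_radius + 2.0
        for _ in range(params.n_spots):
            placed = False
            for _try in range(200):
                ang = rng.uniform(0, 2 * np.pi)
                rad = nuc_r_eff + params.spot_radius + rng.uniform(1.0, 6.0)
                c = nuc_center + rad * np.array([np.sin(ang), np.cos(ang)])
                disc = _disc_mask(size, c, params.spot_radius)
                inside = disc & cyto_mask
                if disc.sum() == 0 or inside.sum() < disc.sum():
                    continue  # spot clipped by nucleus/cell boundary
                if any(np.hypot(c[0] - pc[0], c[1] - pc[1]) < min_sep
                       for pc in spot_centers):
                    continue
                spots |= disc
                spot_centers.append((float(c[0]), float(c[1])))
                spot_areas.append(int(disc.sum()))
                placed = True
                break
            if not placed:
                raise RuntimeError("could not place all spots in the "
                                   "perinuclear cytoplasm (geometry too tight)")
        reporter = 0.85 * gaussian_filter(spots.astype(float), 0.7) + 0.05 * soft_cyto

    img = np.stack([dna, reporter, body])
    img = np.clip(img, 0.0, 1.0)

    if params.photon_scale > 0:
        img = rng.poisson(img * params.photon_scale) / params.photon_scale
    if params.read_noise > 0:
        img = img + rng.normal(0.0, params.read_noise, img.shape)
    img = np.clip(img, 0.0, 1.0)
    truth = SceneTruth(nucleus_mask=nucleus_mask, cell_mask=cell_mask,
                       spot_centers=spot_centers, spot_areas=spot_areas)
    return img, truth


def two_condition_sampler(negative: PhenotypeParams, positive: PhenotypeParams,
                          p_positive: float = 0.5):
    """Sampler drawing each cell from the negative or positive control preset."""

    def sampler(rng: np.random.Generator):
        pos = rng.random() < p_positive
        base = positive if pos else negative
        return replace(base, seed=int(rng.integers(0, 2**31 - 1))), \
            ("treated" if pos else "dmso")

    return sampler


def make_dataset(n: int, sampler, seed: int, out_dir, size: int = 64) -> pd.DataFrame:
    """Render ``n`` cells into multi-channel TIFFs plus a CSV manifest.

    ``sampler(rng) -> (PhenotypeParams, condition_label)``.  Reproducible
    (byte-identical) given the seed.  Returns the manifest frame; the CSV is
    written as ``manifest.csv`` in ``out_dir``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        params, condition = sampler(rng)
        img, _truth = render_cell(params, size=size)
        fname = f"cell_{i:04d}.tif"
        arr16 = np.round(img * 65535).astype(np.uint16)
        tifffile.imwrite(out_dir / fname, np.moveaxis(arr16, 0, -1))
        rows.append({"filename": fname, "assay": params.assay,
                     "condition": condition, "t": params.t,
                     "n_spots": params.n_spots,
                     "spot_radius": params.spot_radius, "seed": params.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
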