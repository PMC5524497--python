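"""Synthetic bark-like background population with known ground truth.

Real background-matching studies photograph a population of natural
backgrounds (here: tree bark) and sample patches from each.  This module
replaces the photographs with a controllable generative model so every
downstream stage — calibration, feature extraction, typicality ranking,
stimulus selection — can be tested against known population parameters.

Each synthetic "tree" is rendered as spatially correlated noise:

* a tree-level mean colour drawn from a population Gaussian
  (between-tree covariance), modulated by a smooth within-tree colour field
  (within-tree covariance);
* an achromatic texture field synthesized in the frequency domain, with the
  power spectrum shaped so each octave band carries a prescribed fraction
  of the total energy (the tree's "band weights") with a 1/f^beta falloff
  inside each band.

The linear image is gamma-encoded to emulate nonlinear camera output; the
linear truth and the generating parameters are kept alongside for recovery
tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from PIL import Image
from scipy import fft as sp_fft
from scipy import ndimage

from ._spectral import band_index_grid, radial_frequency_grid

__all__ = [
    "PopulationParams",
    "SyntheticImage",
    "generate_tree_image",
    "generate_population",
    "render_colour_standard",
    "write_image",
    "write_ground_truth",
]


def _correlated_cov(sd: float, corr: float, k: int = 3) -> np.ndarray:
    c = np.full((k, k), corr)
    np.fill_diagonal(c, 1.0)
    return sd * sd * c


@dataclass(frozen=True)
class PopulationParams:
    """Ground-truth parameters of the synthetic background population.

    Colour values are linear reflectances in [0, 1].  Band weights are
    fractions of achromatic spectral energy per octave (coarse to fine);
    per-tree weights are drawn log-normally around ``band_weight_mean`` with
    log-scale covariance ``band_weight_cov`` and renormalized.
    """

    colour_mean: np.ndarray = field(
        default_factory=lambda: np.array([0.30, 0.25, 0.18])
    )
    colour_cov_tree: np.ndarray = field(
        default_factory=lambda: _correlated_cov(0.05, 0.8)
    )
    colour_cov_patch: np.ndarray = field(
        default_factory=lambda: _correlated_cov(0.03, 0.8)
    )
    spectrum_exponent: float = 1.0
    band_weight_mean: np.ndarray = field(
        default_factory=lambda: np.array([0.26, 0.22, 0.18, 0.14, 0.11, 0.09])
    )
    band_weight_cov: np.ndarray = field(default_factory=lambda: np.eye(6) * 0.09)
    image_size: tuple[int, int] = (1500, 1200)
    gamma: float = 2.2
    texture_rms: float = 0.35
    colour_field_scale: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("colour_mean", "band_weight_mean"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        for name in ("colour_cov_tree", "colour_cov_patch", "band_weight_cov"):
            cov = np.asarray(getattr(self, name), float)
            if not np.allclose(cov, cov.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")
            object.__setattr__(self, name, cov)
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        w = self.band_weight_mean
        if np.any(w <= 0):
            raise ValueError("band_weight_mean entries must be positive")
        object.__setattr__(self, "band_weight_mean", w / w.sum())

    @property
    def n_bands(self) -> int:
        return self.band_weight_mean.size

    def with_seed(self, seed: int) -> "PopulationParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SyntheticImage:
    """One rendered tree: nonlinear camera pixels plus linear ground truth."""

    pixels: np.ndarray  # H x W x 3, gamma-encoded, [0, 1]
    linear_truth: np.ndarray  # H x W x 3, linear, [0, 1]
    tree_id: int
    true_colour: np.ndarray  # generating tree-level mean colour (3,)
    true_band_weights: np.ndarray  # generating octave energy fractions


def _sqrt_psd(cov: np.ndarray) -> np.ndarray:
    # Cholesky-like factor tolerant of semi-definite covariances
    vals, vecs = np.linalg.eigh(cov)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


@lru_cache(maxsize=8)
def _band_filter(shape: tuple[int, int], n_bands: int, beta: float):
    """Per-cell band index and band-normalized 1/f^beta power template.

    The template is scaled so the total power in band b equals the tree's
    weight w_b once multiplied by ``w[bands]``.  Computed on the full FFT
    grid, cached per image geometry.
    """
    bands = band_index_grid(shape, n_bands)
    f = radial_frequency_grid(shape)
    with np.errstate(divide="ignore"):
        falloff = np.where(f > 0, f, np.inf) ** (-beta)
    norm = np.zeros(shape)
    for b in range(n_bands):
        in_b = bands == b
        z = falloff[in_b].sum()
        if z > 0:
            norm[in_b] = falloff[in_b] / z
    return np.maximum(bands, 0), norm


def _texture_field(rng: np.random.Generator, shape: tuple[int, int],
                   weights: np.ndarray, beta: float) -> np.ndarray:
    """Unit-variance field whose octave-band power fractions equal `weights`."""
    bands, norm = _band_filter(tuple(shape), weights.size, float(beta))
    amplitude = np.sqrt(weights[bands] * norm)[:, : shape[1] // 2 + 1]
    spectrum = sp_fft.rfft2(rng.standard_normal(shape))
    fieldv = sp_fft.irfft2(spectrum * amplitude, s=shape)
    sd = fieldv.std()
    return fieldv / sd if sd > 0 else fieldv


def _colour_field(rng: np.random.Generator, shape: tuple[int, int],
                  cov: np.ndarray, cell: int) -> np.ndarray:
    """Smooth zero-mean 3-channel field with per-pixel channel covariance ~cov."""
    h = max(shape[0] // cell, 2) + 2
    w = max(shape[1] // cell, 2) + 2
    low = rng.standard_normal((h, w, 3))
    for c in range(3):
        low[..., c] = ndimage.gaussian_filter(low[..., c], sigma=1.0, mode="wrap")
        sd = low[..., c].std()
        if sd > 0:
            low[..., c] /= sd
    low = low @ _sqrt_psd(cov).T
    out = np.empty(shape + (3,))
    zoom = (shape[0] / h, shape[1] / w)
    for c in range(3):
        out[..., c] = ndimage.zoom(low[..., c], zoom, order=1, mode="grid-wrap")
    return out


def _rng_for_tree(params: PopulationParams, tree_id: int) -> np.random.Generator:
    # per-tree stream: populations are extensible without reshuffling
    return np.random.default_rng(np.random.SeedSequence([int(params.seed), int(tree_id)]))


def generate_tree_image(params: PopulationParams, tree_id: int) -> SyntheticImage:
    """Render one synthetic tree; deterministic given (params.seed, tree_id)."""
    rng = _rng_for_tree(params, tree_id)
    shape = tuple(params.image_size)

    tree_colour = rng.multivariate_normal(params.colour_mean, params.colour_cov_tree)
    tree_colour = np.clip(tree_colour, 1e-3, 1.0)
    log_w = rng.multivariate_normal(np.log(params.band_weight_mean),
                                    params.band_weight_cov)
    weights = np.exp(log_w)
    weights /= weights.sum()

    tex = _texture_field(rng, shape, weights, params.spectrum_exponent)
    colour = tree_colour[None, None, :] + _colour_field(
        rng, shape, params.colour_cov_patch, params.colour_field_scale
    )
    linear = np.clip(colour * (1.0 + params.texture_rms * tex[..., None]), 0.0, 1.0)
    pixels = linear ** (1.0 / params.gamma)
    return SyntheticImage(
        pixels=pixels,
        linear_truth=linear,
        tree_id=tree_id,
        true_colour=tree_colour,
        true_band_weights=weights,
    )


def generate_population(params: PopulationParams, n_trees: int) -> list[SyntheticImage]:
    """Independent tree-level draws; tree ids run 0..n_trees-1."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    return [generate_tree_image(params, t) for t in range(n_trees)]


# nominal linear reflectances of the rendered chart: a 6-step achromatic
# (grey) series spanning dark to near-white, plus 4 chromatic patches
ACHROMATIC_SERIES = np.array([0.03, 0.09, 0.19, 0.36, 0.59, 0.90])
CHROMATIC_PATCHES = np.array([
    [0.45, 0.32, 0.26],
    [0.36, 0.47, 0.30],
    [0.28, 0.34, 0.58],
    [0.62, 0.58, 0.24],
])


def render_colour_standard(
    params: PopulationParams, patch_px: int = 40
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a grey-series + chromatic colour standard, gamma-encoded.

    Returns the chart image (H x W x 3 in [0, 1]) and a table of nominal
    linear values with the pixel box of each patch
    (columns row0/row1/col0/col1, half-open extents).
    """
    nominal = np.vstack([np.repeat(ACHROMATIC_SERIES[:, None], 3, axis=1),
                         CHROMATIC_PATCHES])
    n = nominal.shape[0]
    img_lin = np.empty((patch_px, patch_px * n, 3))
    rows = []
    for i in range(n):
        c0, c1 = i * patch_px, (i + 1) * patch_px
        img_lin[:, c0:c1, :] = nominal[i]
        rows.append({
            "patch": i,
            "kind": "achromatic" if i < ACHROMATIC_SERIES.size else "chromatic",
            "nominal_r": nominal[i, 0],
            "nominal_g": nominal[i, 1],
            "nominal_b": nominal[i, 2],
            "row0": 0, "row1": patch_px, "col0": c0, "col1": c1,
        })
    return img_lin ** (1.0 / params.gamma), pd.DataFrame(rows)


def write_image(image: np.ndarray, path: str) -> None:
    """Write an [0,1] RGB array as 8-bit PNG or 16-bit TIFF by extension."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".png":
        arr = np.clip(np.round(image * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path)
    elif ext in (".tif", ".tiff"):
        import tifffile

        arr = np.clip(np.round(image * 65535), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, arr, photometric="rgb")
    else:
        raise ValueError(f"unsupported image extension {ext!r}")


def write_ground_truth(images: list[SyntheticImage], path: str) -> None:
    """Ground-truth table: tree_id, generating colour, generating band weights."""
    rows = []
    for im in images:
        row = {"tree_id": im.tree_id}
        row.update({f"colour_{c}": im.true_colour[i] for i, c in enumerate("rgb")})
        row.update({f"band_{b}": w for b, w in enumerate(im.true_band_weights)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
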