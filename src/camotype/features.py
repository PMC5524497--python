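"""Prey-scale patch sampling and colour/texture descriptors.

Camouflage is a property of the background *at the spatial scale of the
prey*: the unit of analysis is a rectangular patch the size of the printed
target, not the whole image.  Each patch is summarized by

* **colour** — the arithmetic mean of each receptor channel (linear units),
  the minimal descriptor of a patch's position in colour space; and
* **texture** — the granularity spectrum: the fraction of achromatic
  spectral energy in each of ``n_bands`` octave-spaced radial frequency
  bands (coarse to fine), computed from a Hann-windowed 2-D Fourier
  transform after mean subtraction.  Orientation is pooled out radially.

Patches are sampled at uniform-random, pairwise non-overlapping positions.
Coordinates are 0-based, row-major, top-left origin, half-open extents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy.signal.windows import hann

from ._spectral import band_energy_fractions, band_index_grid

__all__ = [
    "SamplingError",
    "Patch",
    "FeatureVector",
    "Target",
    "sample_patches",
    "colour_features",
    "texture_features",
    "extract_features",
    "render_target",
    "features_to_frame",
    "frame_to_features",
    "PATCH_DIMS",
    "target_footprint_px",
]

log = logging.getLogger(__name__)

# footprint of a 5 cm x 2.5 cm printed target at 300 dpi (see render_target)
PATCH_DIMS = (296, 591)


class SamplingError(RuntimeError):
    """No non-overlapping patch configuration found within the budget."""


@dataclass(frozen=True)
class Patch:
    """A prey-scale rectangular sample of a background image."""

    pixels: np.ndarray  # (h, w, channels), linear receptor space
    tree_id: int
    offset: tuple[int, int]  # (row, col) of the top-left corner
    dims: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != tuple(self.dims):
            raise ValueError("pixel block does not match declared dims")


@dataclass(frozen=True)
class FeatureVector:
    """Colour + texture description of one patch.

    ``texture`` entries are energy fractions (non-negative, summing to 1)
    unless ``standardized`` is set by the typicality stage.
    """

    colour: np.ndarray
    texture: np.ndarray
    tree_id: int
    patch_id: int
    standardized: bool = False

    def __post_init__(self) -> None:
        if not self.standardized:
            if np.any(self.colour < 0):
                raise ValueError("colour entries must be >= 0")
            if np.any(self.texture < 0) or abs(self.texture.sum() - 1.0) > 1e-9:
                raise ValueError("texture entries must be >= 0 and sum to 1")

    @property
    def provenance(self) -> tuple[int, int]:
        return (self.tree_id, self.patch_id)


def _overlaps(a: tuple[int, int], b: tuple[int, int], dims: tuple[int, int]) -> bool:
    return (abs(a[0] - b[0]) < dims[0]) and (abs(a[1] - b[1]) < dims[1])


def sample_patches(
    image,
    n: int,
    dims: tuple[int, int] = PATCH_DIMS,
    seed: int | np.random.Generator = 0,
    max_restarts: int = 200,
) -> list[Patch]:
    """Draw ``n`` uniform-random, pairwise non-overlapping patches.

    ``image`` is either an (H, W, C) array or a
    :class:`camotype.synth.SyntheticImage` (its linear truth is used).
    Patches are placed sequentially, each position drawn uniformly over the
    exact set of offsets still compatible with the patches already placed;
    a partial configuration that blocks all remaining offsets triggers a
    restart from scratch.  Raises :class:`SamplingError` when the restart
    budget is exhausted (the requested packing is infeasible or vanishingly
    improbable).
    """
    tree_id = getattr(image, "tree_id", -1)
    pixels = getattr(image, "linear_truth", image)
    h, w = pixels.shape[:2]
    dh, dw = dims
    if h < dh or w < dw:
        raise SamplingError(f"image {h}x{w} smaller than patch dims {dh}x{dw}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_rows, n_cols = h - dh + 1, w - dw + 1
    for _ in range(max_restarts):
        feasible = np.ones((n_rows, n_cols), dtype=bool)
        placed: list[tuple[int, int]] = []
        while len(placed) < n:
            open_offsets = np.flatnonzero(feasible)
            if open_offsets.size == 0:
                break  # dead end; restart
            pick = int(open_offsets[rng.integers(open_offsets.size)])
            r, c = divmod(pick, n_cols)
            placed.append((r, c))
            feasible[max(0, r - dh + 1): r + dh, max(0, c - dw + 1): c + dw] = False
        if len(placed) == n:
            return [
                Patch(
                    pixels=pixels[r: r + dh, c: c + dw],
                    tree_id=tree_id,
                    offset=(r, c),
                    dims=(dh, dw),
                )
                for r, c in placed
            ]
    raise SamplingError(
        f"could not place {n} non-overlapping {dh}x{dw} patches in a {h}x{w} "
        f"image (tree {tree_id}) within {max_restarts} restarts"
    )


def colour_features(patch: Patch) -> np.ndarray:
    """Per-channel arithmetic mean of the patch (linear units)."""
    return patch.pixels.reshape(-1, patch.pixels.shape[-1]).mean(axis=0)


def texture_features(patch: Patch, n_bands: int = 6) -> np.ndarray:
    """Granularity spectrum: octave-band energy fractions, coarse to fine.

    The achromatic channel (mean over receptor channels) is mean-subtracted,
    Hann-windowed, Fourier-transformed, and its power integrated over
    octave-spaced radial frequency bands.  A constant (zero-energy) patch
    yields the uniform vector 1/n_bands with a warning, keeping downstream
    distances finite.
    """
    h, w = patch.dims
    if min(h, w) < 2 ** n_bands:
        raise ValueError(
            f"patch {h}x{w} too small for {n_bands} octave bands "
            f"(needs >= {2 ** n_bands} px in the smaller dimension)"
        )
    achro = patch.pixels.mean(axis=-1)
    mean_level = achro.mean()
    achro = achro - mean_level
    if achro.std() > 1e-10 * (abs(mean_level) + 1.0):
        window = np.outer(hann(h, sym=False), hann(w, sym=False))
        power = np.abs(sp_fft.fft2(achro * window)) ** 2
        bands = band_index_grid((h, w), n_bands)
        return band_energy_fractions(power, bands, n_bands)
    log.warning(
        "constant patch (tree %s, offset %s): texture undefined, "
        "falling back to the uniform spectrum", patch.tree_id, patch.offset
    )
    return np.full(n_bands, 1.0 / n_bands)


def extract_features(
    images,
    n_patches: int = 5,
    dims: tuple[int, int] = PATCH_DIMS,
    n_bands: int = 6,
    seed: int = 0,
) -> list[FeatureVector]:
    """Sample patches from every image and extract both descriptors."""
    rng = np.random.default_rng(seed)
    out = []
    for image in images:
        for j, patch in enumerate(sample_patches(image, n_patches, dims, rng)):
            out.append(
                FeatureVector(
                    colour=colour_features(patch),
                    texture=texture_features(patch, n_bands),
                    tree_id=patch.tree_id,
                    patch_id=j,
                )
            )
    return out


@dataclass(frozen=True)
class Target:
    """Triangular prey image cropped from a patch, with transparency mask."""

    pixels: np.ndarray  # (h, w, channels)
    mask: np.ndarray  # (h, w) bool, True inside the triangle
    source: tuple[int, int]  # provenance (tree_id, patch_id or -1)


def target_footprint_px(base_cm: float = 5.0, height_cm: float = 2.5,
                        dpi: float = 300.0) -> tuple[int, int]:
    """Printed footprint in pixels: (height, width).

    Width rounds half-up, height rounds up, so the default 5 x 2.5 cm
    triangle at 300 dpi occupies exactly 296 x 591 px — the patch dims.
    """
    width = int(np.floor(base_cm / 2.54 * dpi + 0.5))
    height = int(np.ceil(height_cm / 2.54 * dpi))
    return height, width


def render_target(
    patch: Patch,
    base_cm: float = 5.0,
    height_cm: float = 2.5,
    dpi: float = 300.0,
    patch_id: int = -1,
) -> Target:
    """Cut an apex-up isoceles triangle from the patch centre.

    The triangle's base spans the bottom edge of its bounding box and its
    apex sits at the top centre; pixels outside it are masked transparent.
    """
    th, tw = target_footprint_px(base_cm, height_cm, dpi)
    ph, pw = patch.dims
    if ph < th or pw < tw:
        raise ValueError(f"patch {ph}x{pw} smaller than target footprint {th}x{tw}")
    r0, c0 = (ph - th) // 2, (pw - tw) // 2
    block = patch.pixels[r0: r0 + th, c0: c0 + tw]
    rows = (np.arange(th)[:, None] + 0.5) / th  # 0 at apex row, 1 at base
    cols = (np.arange(tw)[None, :] + 0.5) / tw - 0.5  # centred
    mask = np.abs(cols) <= rows / 2.0
    return Target(pixels=block, mask=mask, source=(patch.tree_id, patch_id))


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    """One row per patch: tree_id, patch_id, colour_1..c, texture_1..b."""
    rows = []
    for f in features:
        row = {"tree_id": f.tree_id, "patch_id": f.patch_id}
        row.update({f"colour_{i + 1}": v for i, v in enumerate(f.colour)})
        row.update({f"texture_{i + 1}": v for i, v in enumerate(f.texture)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_features(frame: pd.DataFrame) -> list[FeatureVector]:
    colour_cols = [c for c in frame.columns if c.startswith("colour_")]
    texture_cols = [c for c in frame.columns if c.startswith("texture_")]
    return [
        FeatureVector(
            colour=row[colour_cols].to_numpy(float),
            texture=row[texture_cols].to_numpy(float),
            tree_id=int(row["tree_id"]),
            patch_id=int(row["patch_id"]),
        )
        for _, row in frame.iterrows()
    ]
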